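# volnet

Graph-theoretic analysis of the **volitional network** — the structural
connectivity network of brain regions that carry voluntary movement from
its motivation through planning, timing, decision and execution to the
sense of agency.

The network has 82 nodes: Brainnetome-Atlas sub-areas in both hemispheres,
each assigned to one or more of eight movement processes (Motivation,
Modulation of Motivation, Planning, Timing, Decision, Execution, Agency,
Modulation of Agency). Its anatomical connectivity is an undirected,
unweighted graph supplied by the user (edge-list TSV or labelled 0/1
adjacency CSV); the atlas connectivity itself is not redistributable, so
the package also ships seeded generators that emulate the network's
statistical regime for testing every stage offline.

The pipeline computes, for any such graph *G* with *n* nodes and *m*
undirected edges:

- **descriptive statistics** — ordered-pair density `2m/(n(n-1))`, hop-count
  diameter and mean shortest path, local clustering coefficients
  `C_i = 2t_i/(k_i(k_i-1))` and global transitivity, and degree
  assortativity *r* (Pearson correlation of degrees across edge endpoints);
- **six centrality measures** per node — degree, Brandes betweenness
  (unnormalized, each unordered pair once), closeness `(n-1)/Σ_j d(i,j)`,
  eigenvector, hubs and authorities (power iteration; on an undirected
  graph the last three coincide) — each with a max-normalized twin in
  [0, 1] for the connectogram heat rings;
- **small-worldness** — `γ = C/⟨C_r⟩`, `λ = L/⟨L_r⟩`, `σ = γ/λ`, where
  `⟨C_r⟩, ⟨L_r⟩` are means over an ensemble of degree-preserving
  double-edge-swap rewirings of *G* (default 1000); σ > 1 indicates a
  small-world network;
- **Walktrap communities** — agglomeration on t-step lazy random-walk
  profiles (default t = 6), dendrogram cut at maximal Newman modularity
  `Q = Σ_c [m_c/m − (d_c/2m)²]`, plus community composition by hemisphere
  and by movement process;
- **per-process subnetworks and Circos export** — edges incident to (or
  induced by) each process's seed nodes, written as plain-text Circos
  karyotype/link/heatmap files with the six normalized centrality rings.

## Worked example

```sh
python examples/03_communities.py
```

```
communities: 4   modularity Q = 0.3883

nodes per community x hemisphere:
           LEFT  RIGHT
community
0            21     13
1             0     14
2            20      0
3             0     14

hemisphere spread: right touches 3 communities, left touches 2
(planted truth: 4 blocks; block 0 is bilateral with 34 nodes)
```

The generated 82-node network plants four communities with a hemispheric
asymmetry (one bilateral community, two right-only, one left-only);
Walktrap with six steps recovers them exactly, and the composition table
shows the right hemisphere spread over three communities and the left over
two — the asymmetry the analysis is designed to expose. The other
examples (`examples/01…04`) walk through roster construction and
descriptive metrics, the σ statistic on Watts–Strogatz vs Erdős–Rényi
graphs, and the centrality/connectogram export.

The same pipeline runs from the shell:

```sh
volnet simulate volitional --seed 1 --out sim/
volnet analyze --graph sim/graph.tsv --roster sim/roster.tsv \
    --n-random 1000 --seed 42 --steps 6 --out results/
```

`volnet analyze` writes `report.json` (every network characteristic plus
provenance, validated by the JSON Schema shipped in
`src/volnet/data/analysis_report.schema.json`), raw and normalized
centrality TSVs, community membership and composition TSVs, and Circos
files for the whole network and each of the eight processes. Supplying the
real atlas-derived adjacency instead of a simulated graph produces the
full characteristics table for direct comparison with published values.

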