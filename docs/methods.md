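# Methods

## The network and its containers

The object of study is a simple undirected graph over a fixed 82-node
parcellation: 41 bilateral sub-area stems, each expanded to `_l`/`_r`
homologues, grouped into seven lobe groups (frontal, insula, limbic,
temporal, parietal, occipital, sub-cortical nuclei) and assigned to one or
more of eight movement processes. A stem listed under several processes
(pre-SMA under Planning and Timing, the insula under Motivation and
Agency, A9m under Planning and Decision) becomes a single node per
hemisphere carrying the union of processes. Node order is deterministic
(lobe group, hemisphere, label), so all outputs are reproducible
byte-for-byte.

`BrainGraph` stores an explicit dense 0/1 adjacency matrix (n = 82 makes
dense linear algebra the simplest correct choice) and enforces symmetry, a
zero diagonal and binary entries at construction. Files use labels, never
indices; loaders accept case-insensitive hemisphere suffixes and
normalize, drop self-loops with a warning, collapse duplicate edges, and
reject asymmetric matrices unless explicitly asked to symmetrize by union.

Edge counts are reported in both conventions. The published
characteristics table counts *ordered* adjacency entries (2330 for this
network); the density printed there, 0.350798, equals 2330/(82·81), which
is why `density()` uses the ordered-pair denominator `n(n-1)`. Internally
the graph stores 1165 undirected edges.

## Descriptive statistics

Path metrics are hop counts from BFS (scipy's unweighted shortest paths).
The mean is over ordered reachable pairs, i ≠ j; unreachable pairs are
excluded and flagged rather than fatal, because degree-preserving rewires
of sparse graphs can in principle disconnect. Local clustering is
`2t_i/(k_i(k_i−1))`; nodes with degree < 2 score 0 and are included in the
average by default (an `exclude` mode exists; the convention is
unobservable on the 82-node regime, which has no such nodes). Global
transitivity is 3·triangles/triples via `diag(A³)`. Degree assortativity
is the Pearson correlation of endpoint degrees over both orientations of
every edge; it raises on regular graphs (zero variance) instead of
returning NaN.

## Centralities

Betweenness uses Brandes' pair-dependency accumulation over BFS
shortest-path DAGs, unnormalized, each unordered source–target pair
counted once, endpoints excluded — the default of the igraph/R family, so
rankings are comparable with published per-node tables. Closeness is
`(n−1)/Σd`; on disconnected graphs it is scaled by reachable-set size so
isolated components do not inflate scores.

Eigenvector, hubs and authorities all come from power iteration (uniform
positive start, tolerance 1e−10): hubs iterate `AAᵀ`, authorities `AᵀA`,
eigenvector `A`. On a symmetric adjacency the three are mathematically
identical after max-normalization, and the pipeline computes all three so
that identity is visible in the output. Bipartite components break the
iteration — the ±λ spectral symmetry makes iteration on `A` oscillate and
iteration on `A²` stall inside a degenerate eigenspace — so bipartiteness
is detected by 2-coloring up front and a unit diagonal shift `A+I` is
applied; the shift moves every eigenvalue by one and changes neither the
eigenvectors nor their order. Max-normalization (divide each measure by
its column maximum) is the form used by the connectogram heat rings;
all-zero columns stay zero with a warning.

## Small-worldness

σ compares the observed graph to random graphs with *exactly* its degree
sequence: `γ = C/⟨C_r⟩`, `λ = L/⟨L_r⟩`, `σ = γ/λ`. "Same degree
distribution" is implemented as exact degree-sequence preservation via
double-edge swaps — the standard null for this statistic and verifiable
deterministically (the degree sequence is asserted conserved per
replicate). Each rewire attempts `⌈10·m⌉` swaps (configurable); swaps
creating self-loops or duplicate edges are rejected. C defaults to the
mean local clustering coefficient, with a switch to global transitivity
since both appear in published tables; λ is sometimes written μ — same
quantity, the report names it `lam`. Replicate r draws from an
independent stream derived from `(seed, r)`, so ensembles are reproducible
regardless of evaluation order. Disconnected replicates are kept under
the finite-pair rule rather than resampled; at density 0.35 on 82 nodes
they essentially never occur. The ensemble default is 1000 replicates;
tests and the acceptance script use 200 (50 for the regime checks), which
leaves the ensemble-mean standard error far below the decision thresholds
they assert.

## Walktrap communities

The transition matrix is the *lazy* walk `P = (D+I)⁻¹(A+I)` — a unit
self-loop on every vertex, as in the reference implementation; the lazy
walk is aperiodic, which keeps t-step profiles informative on short even
cycles (without it, agreement with the reference drops sharply). A
community's profile is the mean of its members' rows of `Pᵗ` (t = 6 by
default); the distance between communities is
`r² = Σ_k (p_A(k) − p_B(k))²/(d(k)+1)`, and each step merges the adjacent
pair minimizing `Δσ = (|A||B|/(|A|+|B|))·r²/n`, with ties broken by
smallest community ids. Only adjacent pairs merge, so components never
join and a graph with c components yields exactly n − c merges; isolated
nodes stay singletons. Modularity is recorded after every merge and the
partition returned is the modularity-maximal cut along the merge sequence
(ties toward fewer communities). Merged profiles use the incremental
weighted-mean update, which is algebraically identical to naive
recomputation.

Walktrap is a greedy agglomerative heuristic: it does not guarantee the
globally modularity-optimal partition. On exhaustively enumerable graphs
it matches igraph's implementation exactly and reaches the global optimum
at the same rate (~75% of unique-optimum random graphs in the test
suite).

## Synthetic generators

Erdős–Rényi and Watts–Strogatz generators provide the reference regimes
used to interpret σ (a WS graph at n=500, k=10, p=0.1 is the canonical
small-world case; an ER graph is its own null, σ ≈ 1). The planted
stochastic block model provides community ground truth.

`generate_volitional_like` is the stand-in for the atlas-derived network,
which is not printed in any public table. It reproduces the *regime*, not
the values: 82 roster nodes, four planted blocks with the observed
hemispheric asymmetry (a bilateral block of 34 nodes — left 21/right 13 —
one left-only block of 20, two right-only blocks of 14), pair
probabilities from a planted-partition kernel (within/between propensity
1.0/0.12) with two high-propensity hub roles per block, globally scaled so
the expected ordered-pair density is 0.350798 and clipped at 0.99. The
propensity ratio was fixed once so that the planted structure is cleanly
recoverable across seeds (Walktrap ARI = 1.0 on 40 consecutive seeds)
while density, clustering, path length and diameter stay near the
empirical regime. Block-density heterogeneity plus hub roles make degree
assortativity reliably positive (≈ 0.55 — stronger than the empirical
0.24; only the sign is contractual). What the generator does *not*
emulate: the actual atlas wiring, spatial adjacency, hemispheric homotopy
of individual edges, and any weighted or directed structure. Tests
passing on it show the pipeline is correct and sensitive to this class of
structure, not that the empirical network's published values are
reproduced; those require the user-supplied adjacency.

## Numerical and design choices

- Power iteration tolerance 1e−10 in the max-norm, cap 10 000 iterations;
  non-convergence raises naming the measure rather than returning a stale
  vector.
- The modularity-optimal cut includes level 0 (all singletons), so graphs
  whose best partition is trivial report it honestly.
- Reported "absolute difference" between the observed and null mean path
  is recomputed from unrounded internal values; quotients of printed
  (rounded) table values can disagree with printed derived values by one
  unit in the last decimal, and the report does not chase printed digit
  strings.
- The analysis report is a pydantic model; its JSON Schema is shipped as
  package data and every written `report.json` revalidates against it.
- Seeds: every stochastic stage takes one named seed; derived streams use
  `SeedSequence(seed, spawn_key=(replicate,))`.

## Limitations

Unweighted, undirected graphs only — no weighted centralities, no
directed variants, no lattice-referenced small-world indices (ω, SWP).
Community detection is Walktrap-only by design. The Circos export writes
the data files (karyotype, links, heat rings); rendering the circular
figure is left to Circos or any compatible plotter.
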