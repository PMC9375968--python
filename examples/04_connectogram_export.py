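"""Centralities and Circos connectogram export for one movement process.

Computes the six centrality measures, max-normalizes them for the heat
rings, restricts the links to the edges touching the Decision seed nodes
(left/right A9m), and writes plain-text Circos files: a karyotype (left
hemisphere first, lobes in fixed order), a link file, and one heatmap
track per ring (outer to inner: authorities, betweenness, degree,
eigenvector, hubs, closeness).
"""

import tempfile
from pathlib import Path

from volnet import (
    VolitionalProcess,
    compute_centralities,
    connectogram_tables,
    export_circos,
    generate_volitional_like,
    process_subnetwork,
)

truth = generate_volitional_like(seed=1)
table = compute_centralities(truth.graph)

top = table["degree_norm"].sort_values(ascending=False).head(3)
print("top-3 nodes by normalized degree:")
for lab, val in top.items():
    print(f"  {lab:12s} {val:.3f}")

sub = process_subnetwork(truth.graph, truth.roster, VolitionalProcess.DECISION)
print(f"\nDecision subnetwork: seeds {sub.seed_nodes}, "
      f"{len(sub.edges)} incident edges")

out = Path(tempfile.mkdtemp()) / "circos_decision"
records = connectogram_tables(truth.graph, truth.roster, table, sub)
written = export_circos(records, out)
print(f"\nwrote {len(written)} Circos files to {out}:")
for p in written:
    print(f"  {p.name}")
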