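"""Full pipeline: two contrasts, two networks, key-TF comparison.

Runs the synthetic study end to end (consensus -> counting -> differential
-> footprints -> motifs -> enrichment -> networks) and prints the key-TF
table: nodes above the 99th PageRank percentile of either network, with
their value in both networks.
"""

import tempfile
from pathlib import Path

from atacgrn import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_regions=150, n_perm=500)
with tempfile.TemporaryDirectory() as tmp:
    result = run_pipeline(cfg, Path(tmp) / "run")

print(f"consensus peaks: {len(result.consensus_peaks)}")
for name, c in result.contrasts.items():
    print(
        f"{name:7s} DARs={len(c.dar_peaks):3d} DEGs={len(c.deg_genes):3d} "
        f"sources={sorted(c.sources)} edges={c.network.graph.number_of_edges()}"
    )
print(f"\nplanted hub TF: {result.truth.hub_tf}")
print(result.key_tf_table.round(4).to_string())

# The hub TF (planted in every top peak of the first contrast) tops the
# first network's inverted PageRank and is reported with value 0 in the
# second network - the signature of a contrast-specific master regulator.
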