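"""Build a compound-target interaction network and export it for Cytoscape.

Predictions for query compounds are unioned into a bipartite graph; the
common-target intersection mirrors asking which proteins every lead
compound hits, and the SIF/GraphML exports load directly in Cytoscape.
"""

import tempfile
from pathlib import Path

from herbnetpharm import (
    SynthConfig,
    build_cti,
    build_sdt_network,
    common_targets,
    export_network,
    gen_dti_with_signal,
    predict_targets,
)

cfg = SynthConfig(seed=42)
synth = gen_dti_with_signal(cfg)
net = build_sdt_network(synth.dti, synth.fingerprints)

predictions = [
    predict_targets(net, synth.query_fingerprints.substructures_of(q), k=5, query_id=q)
    for q in synth.query_fingerprints.compound_ids[:5]
]
cti = build_cti(predictions)
print(f"CTI network: {len(cti.compounds)} compounds, {len(cti.targets)} targets, "
      f"{len(cti.edges)} edges")

shared = common_targets(cti, set(list(cti.compounds)[:2]))
print(f"targets common to the first two compounds: {sorted(shared)}")

out = Path(tempfile.mkdtemp())
export_network(cti, "sif", out / "cti.sif")
export_network(cti, "graphml", out / "cti.graphml")
print(f"exported SIF and GraphML under {out}")
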