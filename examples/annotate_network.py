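"""Annotate a small synthetic molecular network end to end.

Plants four proline-containing CDPs plus cyclo(Asn-Ser), which a de
novo engine reports as the linear dipeptide Asn-Ser with a -18.01 Da
(dehydration) tag.  The pipeline runs in seed-driven mode from a single
database seed.  The report shows how each annotation was reached: the
seed stays `database`; neighbours whose precursor gap matches a
single-residue exchange become `propagated`; cyclo(Asn-Ser) shares no
residue with the seed chain, so no exchange reaches it — instead the
dehydration-tag reconciliation revises the linear call to the isobaric
cyclic form (`revised`).
"""

import tempfile
from pathlib import Path

from cdpmine import (
    Annotation,
    FixtureSpec,
    PipelineConfig,
    PlantedCompound,
    generate_network,
    make_cdp,
    run_pipeline,
)

compounds = (
    PlantedCompound(("Val", "Pro"), 12.71),
    PlantedCompound(("Ala", "Pro"), 5.05),
    PlantedCompound(("Leu", "Pro"), 18.79),
    PlantedCompound(("Gly", "Pro"), 3.62),
    PlantedCompound(("Asn", "Ser"), 1.10, denovo=True, dehydrated_tag=True),
)
# one cluster, as if the network had grouped all five features together
clusters = {c.name: 1 for c in compounds}
spec = FixtureSpec(compounds=compounds, seed=7, ppm_sigma=2.0,
                   explicit_clusters=clusters)

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_network(spec, out_dir=tmp)
    net = bundle.network()
    seed_id = bundle.truth.loc[bundle.truth.name == "cyclo(Val-Pro)",
                               "feature_id"].iloc[0]
    seed = Annotation(node_id=seed_id, candidate=make_cdp("Val", "Pro"),
                      level="database", observed_mz=net.node_mz(seed_id),
                      rt=net.node_rt(seed_id))
    result = run_pipeline(
        PipelineConfig(enumerate_unannotated=False),
        mgf=bundle.paths["mgf"],
        nodes=bundle.paths["nodes"],
        edges=bundle.paths["edges"],
        denovo=bundle.paths["denovo"],
        seeds=[seed],
        out=Path(tmp) / "out",
    )

print(result.report.to_string(index=False))
print()
print(result.summary())
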