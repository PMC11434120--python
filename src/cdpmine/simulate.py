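"""Synthetic fixtures: planted-truth spectra, networks and tables.

Everything the pipeline consumes can be generated here with a known
ground truth: MGF spectra whose peaks are the predicted fragments of
planted compounds (plus tunable dropout and uniform noise), node/edge
tables whose edges link compounds sharing diagnostic fragments — so
composition-sharing CDPs aggregate into clusters exactly as they do in
real molecular networks — and de novo tables emulating how sequencing
engines report cyclic dipeptides as dehydrated linear dipeptides.

Also ships a curated reference set of the 53 cyclic dipeptides detected
in *Limosilactobacillus reuteri* culture, with their reported retention
times and observed m/z; formulas are derived from residue composition,
and rows whose printed values disagree with that derivation are flagged
rather than copied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import round_half_up
from .fragments import (
    CDPCandidate,
    LinearPeptide,
    Spectrum,
    cdp_fragments,
    linear_fragments,
    make_cdp,
)
from .io import Annotation, MolecularNetwork, write_mgf
from .residues import ResidueLibrary, residue_library

__all__ = [
    "PlantedCompound",
    "FixtureSpec",
    "FixtureBundle",
    "generate_spectrum",
    "generate_network",
    "reference_cdp_table",
    "reference_cdp_annotations",
]


@dataclass(frozen=True)
class PlantedCompound:
    """One ground-truth compound in a synthetic dataset."""

    residues: tuple[str, ...]
    rt: float
    kind: str = "cdp"  # "cdp" | "linear"
    #: emit a de novo table row for this compound
    denovo: bool = False
    #: report the de novo row as the linear dipeptide with a -18.01 tag,
    #: emulating how sequencing engines see a DKP
    dehydrated_tag: bool = False

    def __post_init__(self):
        if self.kind == "cdp" and len(self.residues) != 2:
            raise ValueError("a CDP plants exactly two residues")
        if self.kind not in ("cdp", "linear"):
            raise ValueError(f"unknown compound kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "cdp":
            return f"cyclo({self.residues[0]}-{self.residues[1]})"
        return "-".join(self.residues)

    def candidate(self, library: ResidueLibrary) -> CDPCandidate | LinearPeptide:
        if self.kind == "cdp":
            return make_cdp(self.residues[0], self.residues[1], library)
        return LinearPeptide(residues=tuple(library.get(c) for c in self.residues))

    def fragments(self, library: ResidueLibrary):
        cand = self.candidate(library)
        if isinstance(cand, CDPCandidate):
            return cand, cdp_fragments(cand)
        return cand, linear_fragments(cand)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic dataset.

    Defaults emulate a clean high-resolution run: 5 ppm Gaussian mass
    error truncated at 10 ppm, log-normal fragment intensities around
    1000 counts, no fragment dropout and no noise peaks unless asked
    for.  Edges connect compounds sharing at least
    ``shared_fragment_threshold`` predicted fragment m/z values at two
    decimals, which clusters CDPs by amino-acid composition.
    """

    compounds: tuple[PlantedCompound, ...]
    seed: int = 0
    dropout: float = 0.0
    noise_peaks: int = 0
    noise_mz_min: float = 50.0
    base_intensity: float = 1000.0
    intensity_sigma: float = 0.5
    ppm_sigma: float = 5.0
    ppm_max: float = 10.0
    shared_fragment_threshold: int = 2
    #: explicit cluster assignment (compound name -> cluster id); when
    #: set, edges join all same-cluster pairs instead of the
    #: shared-fragment rule
    explicit_clusters: dict[str, int] | None = None

    def __post_init__(self):
        if not self.compounds:
            raise ValueError("fixture needs at least one compound")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout probability must be in [0, 1)")


def generate_spectrum(
    compound: PlantedCompound,
    spec: FixtureSpec,
    rng: np.random.Generator,
    library: ResidueLibrary | None = None,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Simulate one MS/MS spectrum of a planted compound.

    Peaks are the predicted fragments minus independent dropout draws
    (the precursor ion always survives), plus ``noise_peaks`` uniform
    noise peaks whose intensities sit below the 10th percentile of the
    true peaks.  The recorded precursor m/z carries a truncated-Gaussian
    ppm error.
    """
    library = library or residue_library()
    cand, frags = compound.fragments(library)
    theo = cand.precursor_mz

    kept = []
    for f in frags:
        if f.kind == "precursor" or rng.random() >= spec.dropout:
            kept.append(f.mz)
    intensities = spec.base_intensity * np.exp(
        rng.normal(0.0, spec.intensity_sigma, size=len(kept))
    )
    peaks = list(zip(kept, intensities))

    if spec.noise_peaks > 0:
        floor = np.percentile(intensities, 10) if len(intensities) else 1.0
        noise_mz = rng.uniform(spec.noise_mz_min, theo + 5.0, size=spec.noise_peaks)
        noise_int = rng.uniform(0.0, floor, size=spec.noise_peaks)
        peaks.extend(zip(noise_mz, noise_int))

    ppm = rng.normal(0.0, spec.ppm_sigma)
    ppm = max(-spec.ppm_max, min(spec.ppm_max, ppm))
    observed = theo * (1.0 + ppm * 1e-6)

    return Spectrum(
        id=spectrum_id or compound.name,
        precursor_mz=observed,
        rt=compound.rt,
        peaks=np.array(peaks).reshape(-1, 2),
    )


@dataclass
class FixtureBundle:
    """In-memory synthetic dataset plus file paths when written."""

    spectra: list[Spectrum]
    nodes: pd.DataFrame
    edges: pd.DataFrame
    truth: pd.DataFrame
    denovo: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)

    def network(self) -> MolecularNetwork:
        nodes = self.nodes[["feature_id", "precursor_mz", "rt", "cluster"]].copy()
        return MolecularNetwork(nodes=nodes, edges=self.edges.copy())

    def spectra_by_id(self) -> dict[str, Spectrum]:
        return {s.id: s for s in self.spectra}


def generate_network(
    spec: FixtureSpec, out_dir: str | Path | None = None,
    library: ResidueLibrary | None = None,
) -> FixtureBundle:
    """Build a full synthetic dataset: MGF + node/edge/de-novo/truth tables.

    One node per compound; edges by the shared-fragment rule (or the
    explicit cluster assignment); deterministic and byte-reproducible
    for a fixed :class:`FixtureSpec`.
    """
    library = library or residue_library()
    rng = np.random.default_rng(spec.seed)

    spectra: list[Spectrum] = []
    truth_rows = []
    frag_keys: list[set[float]] = []
    for i, compound in enumerate(sorted(spec.compounds, key=lambda c: (c.name, c.rt))):
        fid = f"F{i + 1:03d}"
        s = generate_spectrum(compound, spec, rng, library, spectrum_id=fid)
        spectra.append(s)
        cand, frags = compound.fragments(library)
        frag_keys.append({round_half_up(f.mz, 2) for f in frags})
        truth_rows.append(
            {
                "feature_id": fid,
                "name": compound.name,
                "kind": compound.kind,
                "formula": cand.formula.hill(),
                "theoretical_mz": round(cand.precursor_mz, 4),
                "rt": compound.rt,
                "denovo": compound.denovo,
                "dehydrated_tag": compound.dehydrated_tag,
            }
        )
    truth = pd.DataFrame(truth_rows)

    edge_rows = []
    compounds = sorted(spec.compounds, key=lambda c: (c.name, c.rt))
    for i in range(len(compounds)):
        for j in range(i + 1, len(compounds)):
            if spec.explicit_clusters is not None:
                ci = spec.explicit_clusters.get(compounds[i].name)
                cj = spec.explicit_clusters.get(compounds[j].name)
                connect = ci is not None and ci == cj
            else:
                shared = frag_keys[i] & frag_keys[j]
                connect = len(shared) >= spec.shared_fragment_threshold
            if connect:
                union = frag_keys[i] | frag_keys[j]
                edge_rows.append(
                    {
                        "source": truth.loc[i, "feature_id"],
                        "target": truth.loc[j, "feature_id"],
                        "cosine": round(len(frag_keys[i] & frag_keys[j]) / len(union), 4)
                        if union
                        else 0.0,
                        "delta_mz": round(
                            abs(spectra[i].precursor_mz - spectra[j].precursor_mz), 4
                        ),
                    }
                )
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "cosine", "delta_mz"])

    nodes = pd.DataFrame(
        {
            "feature_id": truth["feature_id"],
            "precursor_mz": [round(s.precursor_mz, 5) for s in spectra],
            "rt": truth["rt"],
        }
    )
    from .io import _assign_components

    nodes["cluster"] = _assign_components(nodes, edges)

    denovo_rows = []
    for compound, s in zip(compounds, spectra):
        if not compound.denovo:
            continue
        if compound.kind == "cdp" and compound.dehydrated_tag:
            seq = f"{compound.residues[0]}-{compound.residues[1]}(-18.01)"
            alc = 72.0
        else:
            seq = "-".join(compound.residues)
            alc = 90.0
        denovo_rows.append(
            {
                "feature_id": s.id,
                "sequence": seq,
                "alc": alc,
                "precursor_mz": round(s.precursor_mz, 5),
                "rt": compound.rt,
            }
        )
    denovo = pd.DataFrame(
        denovo_rows, columns=["feature_id", "sequence", "alc", "precursor_mz", "rt"]
    )

    bundle = FixtureBundle(spectra=spectra, nodes=nodes, edges=edges,
                           truth=truth, denovo=denovo)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mgf": out / "spectra.mgf",
            "nodes": out / "nodes.tsv",
            "edges": out / "edges.tsv",
            "denovo": out / "denovo.tsv",
            "truth": out / "truth.tsv",
        }
        write_mgf(spectra, paths["mgf"])
        nodes.to_csv(paths["nodes"], sep="\t", index=False)
        edges.to_csv(paths["edges"], sep="\t", index=False)
        denovo.to_csv(paths["denovo"], sep="\t", index=False)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        bundle.paths = paths
    return bundle


# --------------------------------------------------------------------------
# Reference CDP set (L. reuteri culture)
# --------------------------------------------------------------------------

# (residue_a, residue_b, printed formula or None, observed m/z, RT min, novel)
_REFERENCE_CDPS = [
    ("Gly", "Pro", "C7H10N2O2", 155.0817, 3.62, False),
    ("Ala", "Pro", "C8H12N2O2", 169.0971, 5.05, False),
    ("Ala", "Val", "C8H14N2O2", 171.1127, 7.57, False),
    ("Ala", "Val", "C8H14N2O2", 171.1132, 9.68, False),
    ("Ser", "Pro", "C8H12N2O3", 185.0918, 1.20, False),
    ("Ser", "Pro", "C8H12N2O3", 185.0921, 2.85, False),
    ("Ala", "Hyp", "C8H12N2O3", 185.0921, 2.20, False),
    ("Ala", "Hyp", "C8H12N2O3", 185.0921, 2.52, False),
    ("Ala", "Leu", "C9H16N2O2", 185.1281, 13.34, False),
    ("Ala", "Ile", "C9H16N2O2", 185.1283, 12.02, False),
    ("Pro", "Pro", "C10H14N2O2", 195.1181, 10.03, False),
    ("Val", "Pro", "C10H16N2O2", 197.1286, 12.71, False),
    ("Val", "Pro", "C10H16N2O2", 197.1286, 13.11, False),
    ("Thr", "Pro", "C9H14N2O3", 199.1073, 3.15, False),
    ("Thr", "Pro", "C9H14N2O3", 199.1078, 4.21, False),
    ("Val", "Val", "C10H18N2O2", 199.1436, 18.61, False),
    ("Ser", "Leu", "C9H16N2O3", 201.1222, 6.32, False),
    ("Leu", "Pro", "C11H18N2O2", 211.1436, 18.79, False),
    ("Ile", "Pro", "C11H18N2O2", 211.1441, 17.99, False),
    ("Leu", "Pro", None, 211.1447, 19.16, False),  # garbled printed formula
    ("Asn", "Pro", "C9H13N3O3", 212.1040, 2.24, False),
    ("Val", "Leu", "C11H20N2O2", 213.1594, 23.37, False),
    ("Asn", "Val", "C9H15N3O3", 214.1181, 2.90, False),
    ("Asp", "Val", "C9H14N2O4", 215.1020, 7.26, False),
    ("Asp", "Val", "C9H14N2O4", 215.1030, 9.41, False),
    ("Glu", "Pro", "C10H14N2O4", 227.1013, 6.47, False),
    ("Glu", "Pro", "C10H14N2O4", 227.1025, 7.64, False),
    ("Leu", "Hyp", "C11H18N2O3", 227.1385, 14.50, False),
    ("Leu", "Hyp", "C11H18N2O3", 227.1387, 15.15, False),
    ("Asn", "Ile", "C10H17N3O3", 228.1343, 6.09, False),
    ("Asn", "Leu", "C10H17N3O3", 228.1343, 6.70, False),
    ("Asp", "Ile", "C10H16N2O4", 229.1171, 12.13, False),
    ("Asp", "Ile", "C10H16N2O4", 229.1174, 11.53, False),
    ("MeEGlu", "Pro", "C11H16N2O4", 241.1180, 11.88, False),
    ("MeEGlu", "Pro", "C11H16N2O4", 241.1181, 13.12, False),
    ("Glu", "Leu", "C11H18N2O4", 243.1330, 17.17, False),
    ("Glu", "Leu", "C11H18N2O4", 243.1330, 18.51, False),
    ("MeEGlu", "Val", "C11H18N2O4", 243.1332, 16.45, False),
    ("Glu", "Ile", "C11H18N2O4", 243.1335, 14.83, False),
    ("Phe", "Pro", "C14H16N2O2", 245.1280, 22.23, False),
    ("MeEGlu", "Hyp", "C11H16N2O3", 257.1123, 8.80, True),
    ("MeEGlu", "Ile", "C12H20N2O4", 257.1486, 23.26, True),
    ("MeEGlu", "Ile", "C12H20N2O4", 257.1492, 20.82, True),
    ("Phe", "Hyp", "C11H18N2O3", 261.1230, 16.84, False),
    ("Tyr", "Pro", "C14H16N2O3", 261.1237, 13.31, False),
    ("Phe", "Hyp", "C11H18N2O3", 261.1240, 17.80, False),
    ("PyroGlu", "Tyr", "C14H14N2O4", 275.1037, 11.45, True),
    ("Tyr", "Hyp", "C14H16N2O4", 277.1171, 12.43, False),
    ("Tyr", "Hyp", "C14H16N2O4", 277.1178, 12.10, False),
    ("Glu", "Phe", "C14H16N2O4", 277.1178, 20.30, False),
    ("Tyr", "Asp", "C13H14N2O5", 279.1332, 10.06, False),
    ("Glu", "Tyr", "C14H16N2O5", 293.1119, 10.26, False),
    ("Glu", "Tyr", "C14H16N2O5", 293.1122, 11.43, False),
]

#: printed-m/z agreement threshold for flagging transcription errors
_MZ_DISCREPANCY_PPM = 20.0


def reference_cdp_table(library: ResidueLibrary | None = None) -> pd.DataFrame:
    """The curated 53-CDP reference set as a DataFrame.

    Formulas are derived from residue composition; ``formula_discrepant``
    marks rows whose printed formula disagrees with the derivation and
    ``mz_discrepant`` rows whose reported m/z is more than 20 ppm from
    the derived [M+H]+ (transcription errors in the source table).
    """
    library = library or residue_library()
    rows = []
    for i, (a, b, printed_formula, mz, rt, novel) in enumerate(_REFERENCE_CDPS):
        cand = make_cdp(a, b, library)
        derived = cand.formula.hill()
        ppm = (mz - cand.precursor_mz) / cand.precursor_mz * 1e6
        rows.append(
            {
                "row": i + 1,
                "name": cand.name,
                "residue_a": cand.residue_codes[0],
                "residue_b": cand.residue_codes[1],
                "printed_formula": printed_formula,
                "formula": derived,
                "observed_mz": mz,
                "theoretical_mz": round(cand.precursor_mz, 4),
                "ppm_error": round(ppm, 1),
                "rt": rt,
                "novel": novel,
                "unnatural": cand.unnatural,
                "formula_discrepant": printed_formula is not None
                and printed_formula != derived,
                "mz_discrepant": abs(ppm) > _MZ_DISCREPANCY_PPM,
            }
        )
    return pd.DataFrame(rows)


def reference_cdp_annotations(
    library: ResidueLibrary | None = None,
) -> list[Annotation]:
    """The reference set as annotations, ready for isomer classification."""
    library = library or residue_library()
    anns = []
    for i, (a, b, _pf, mz, rt, _novel) in enumerate(_REFERENCE_CDPS):
        cand = make_cdp(a, b, library)
        anns.append(
            Annotation(
                node_id=f"R{i + 1:02d}",
                candidate=cand,
                level="deep_mined",
                observed_mz=mz,
                rt=rt,
            )
        )
    return anns
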