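"""MS/MS fragment prediction for cyclic dipeptides and linear peptides.

Cyclic dipeptides (2,5-diketopiperazines, DKPs) do not fragment along a
b/y ladder like linear peptides.  Their positive-mode spectra are
dominated by a small set of diagnostic ions instead:

* small neutral losses from the protonated ring (H2O, CO, H2O+CO, and
  CH3OH / CH3OH+CO when a residue carries a methyl ester);
* the immonium ion of each residue (residue - CO + H, singly charged),
  e.g. m/z 70.07 for Pro, 86.06 for Hyp, 116.07 for MeEGlu, 84.04 for
  PyroGlu, 136.08 for Tyr;
* residue companion ions (the proline ring ion at m/z 98.06) and
  side-chain losses (tyrosine loses the C7H6O quinomethide).

Linear peptides get the standard b/y ladder: b_i is the first i residues
plus a proton, y_i the last i residues plus water plus a proton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import PROTON_MASS, ElementCounts, protonated_mz
from .residues import CO, METHANOL, WATER, AminoAcidResidue, ResidueLibrary

__all__ = [
    "Tolerance",
    "Spectrum",
    "CDPCandidate",
    "LinearPeptide",
    "FragmentIon",
    "MatchResult",
    "immonium_mz",
    "make_cdp",
    "cdp_fragments",
    "linear_fragments",
    "match_peaks",
]


@dataclass(frozen=True)
class Tolerance:
    """A mass-matching window, in Da or ppm."""

    value: float
    unit: str = "da"  # "da" | "ppm"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"unknown tolerance unit {self.unit!r}")

    def window(self, mz: float) -> float:
        """Half-width of the window around ``mz`` in Da."""
        return self.value if self.unit == "da" else mz * self.value * 1e-6

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit.replace('da', 'Da')}"


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor, retention time, and peak list."""

    id: str
    precursor_mz: float
    rt: float | None = None  # minutes
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        arr = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if arr.size and (arr[:, 1] < 0).any():
            raise ValueError(f"spectrum {self.id}: negative peak intensity")
        self.peaks = arr[np.argsort(arr[:, 0], kind="stable")]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CDPCandidate:
    """An unordered residue pair cyclized into a DKP.

    Cyclization of a dipeptide removes one water, so the DKP formula is
    exactly the sum of the two residue compositions (residues already
    exclude water), and cyclo(A-B) == cyclo(B-A).
    """

    residues: tuple[AminoAcidResidue, AminoAcidResidue]
    formula: ElementCounts
    precursor_mz: float

    @property
    def name(self) -> str:
        a, b = self.residues
        return f"cyclo({a.code}-{b.code})"

    @property
    def residue_codes(self) -> tuple[str, str]:
        return tuple(r.code for r in self.residues)  # type: ignore[return-value]

    @property
    def unnatural(self) -> bool:
        return any(r.unnatural for r in self.residues)

    def __repr__(self) -> str:
        return f"CDPCandidate({self.name}, {self.formula.hill()}, {self.precursor_mz:.4f})"


@dataclass(frozen=True)
class LinearPeptide:
    """An ordered linear peptide with optional mass modifications."""

    residues: tuple[AminoAcidResidue, ...]
    modifications: tuple[float, ...] = ()  # signed Da, whole-peptide tags

    @property
    def formula(self) -> ElementCounts:
        total = WATER
        for r in self.residues:
            total = total + r.formula
        return total

    @property
    def precursor_mz(self) -> float:
        return protonated_mz(self.formula) + sum(self.modifications)

    @property
    def name(self) -> str:
        return "-".join(r.code for r in self.residues)

    @property
    def unnatural(self) -> bool:
        return any(r.unnatural for r in self.residues)


@dataclass(frozen=True)
class FragmentIon:
    """A predicted fragment with its label, class, and provenance."""

    label: str
    kind: str  # precursor | neutral_loss | immonium | diagnostic | b | y
    mz: float
    provenance: str = ""

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"fragment {self.label}: non-positive m/z")


@dataclass
class MatchResult:
    """Outcome of matching predicted fragments against observed peaks."""

    matched: list[tuple[FragmentIon, tuple[float, float]]]
    unmatched: list[FragmentIon]
    tolerance: Tolerance

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    def matched_by_kind(self, kind: str) -> list[FragmentIon]:
        return [frag for frag, _ in self.matched if frag.kind == kind]


def immonium_mz(r: AminoAcidResidue) -> float:
    """m/z of the residue's singly charged immonium ion (residue - CO + H)."""
    return r.immonium_mz


def make_cdp(a: str | AminoAcidResidue, b: str | AminoAcidResidue,
             library: ResidueLibrary | None = None) -> CDPCandidate:
    """Build the cyclo(A-B) candidate from two residue codes.

    Symmetric in its arguments: the residue pair is order-normalized by
    (mass, code) so cyclo(Gly-Pro) and cyclo(Pro-Gly) compare equal.
    """
    if library is None and (isinstance(a, str) or isinstance(b, str)):
        from .residues import residue_library

        library = residue_library()
    ra = library.get(a) if isinstance(a, str) else a
    rb = library.get(b) if isinstance(b, str) else b
    ra, rb = sorted((ra, rb), key=lambda r: (r.mass, r.code))
    formula = ra.formula + rb.formula
    return CDPCandidate(residues=(ra, rb), formula=formula,
                        precursor_mz=protonated_mz(formula))


def _dedupe(fragments: list[FragmentIon]) -> list[FragmentIon]:
    """Drop duplicate predictions (same label within 1e-6 Da)."""
    seen: set[tuple[str, int]] = set()
    out = []
    for f in fragments:
        key = (f.label, round(f.mz * 1e6))
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def cdp_fragments(c: CDPCandidate) -> list[FragmentIon]:
    """Predict the diagnostic fragment set of a cyclic dipeptide."""
    mh = c.precursor_mz
    frags = [FragmentIon("[M+H]+", "precursor", mh, provenance=c.name)]

    losses: list[tuple[str, ElementCounts, str]] = [
        ("[M+H-H2O]+", WATER, "ring"),
        ("[M+H-CO]+", CO, "ring"),
        ("[M+H-CO-H2O]+", CO + WATER, "ring"),
    ]
    for r in c.residues:
        if r.methyl_ester:
            losses.append((f"[M+H-CH3OH]+", METHANOL, r.code))
            losses.append((f"[M+H-CH3OH-CO]+", METHANOL + CO, r.code))
    for label, neutral, who in losses:
        frags.append(FragmentIon(label, "neutral_loss", mh - neutral.mass, provenance=who))

    for r in c.residues:
        for label, mz in r.diagnostic_ions:
            kind = "immonium" if label.startswith("imm(") else "diagnostic"
            frags.append(FragmentIon(label, kind, mz, provenance=r.code))
        for label, neutral in r.side_chain_losses:
            frags.append(
                FragmentIon(f"[M+H-{neutral.hill()}]+", "diagnostic",
                            mh - neutral.mass, provenance=label)
            )
    return _dedupe(frags)


def linear_fragments(
    sequence: list[str | AminoAcidResidue] | LinearPeptide,
    library: ResidueLibrary | None = None,
    modifications: dict[int, float] | None = None,
) -> list[FragmentIon]:
    """Predict the b/y ladder (plus residue diagnostics) of a linear peptide.

    ``modifications`` maps 0-based residue positions to signed Da tags;
    a tagged residue shifts every b/y ion that contains it.
    """
    if isinstance(sequence, LinearPeptide):
        residues = list(sequence.residues)
    else:
        if not sequence:
            raise ValueError("empty peptide sequence")
        if library is None:
            from .residues import residue_library

            library = residue_library()
        residues = [library.get(r) if isinstance(r, str) else r for r in sequence]
    if not residues:
        raise ValueError("empty peptide sequence")
    mods = modifications or {}
    masses = [r.mass + mods.get(i, 0.0) for i, r in enumerate(residues)]
    n = len(residues)

    frags: list[FragmentIon] = []
    name = "-".join(r.code for r in residues)
    precursor = sum(masses) + WATER.mass + PROTON_MASS
    frags.append(FragmentIon("[M+H]+", "precursor", precursor, provenance=name))
    for i in range(1, n):  # b_n / y_n duplicate the precursor region
        b = sum(masses[:i]) + PROTON_MASS
        frags.append(FragmentIon(f"b{i}", "b", b, provenance=name))
    for i in range(1, n + 1):
        y = sum(masses[n - i:]) + WATER.mass + PROTON_MASS
        frags.append(FragmentIon(f"y{i}", "y", y, provenance=name))
    for r in residues:
        for label, mz in r.diagnostic_ions:
            kind = "immonium" if label.startswith("imm(") else "diagnostic"
            frags.append(FragmentIon(label, kind, mz, provenance=r.code))
    return _dedupe(frags)


def match_peaks(
    s: Spectrum, predicted: list[FragmentIon], tol: Tolerance | float = 0.02
) -> MatchResult:
    """Greedy nearest-m/z assignment of predicted fragments to peaks.

    Each observed peak is matched to at most one predicted fragment and
    vice versa; candidate pairs are taken in order of increasing m/z
    distance, breaking exact ties toward the lower predicted m/z, which
    makes the result deterministic and invariant under peak permutation.
    """
    if isinstance(tol, (int, float)):
        tol = Tolerance(float(tol), "da")
    if not predicted:
        return MatchResult([], [], tol)

    pairs: list[tuple[float, float, int, int]] = []
    mzs = s.mz
    for pi, frag in enumerate(predicted):
        if len(mzs) == 0:
            break
        win = tol.window(frag.mz)
        lo = np.searchsorted(mzs, frag.mz - win, side="left")
        hi = np.searchsorted(mzs, frag.mz + win, side="right")
        for ki in range(lo, hi):
            pairs.append((abs(mzs[ki] - frag.mz), frag.mz, pi, ki))
    pairs.sort()

    assigned_pred: dict[int, int] = {}
    used_peaks: set[int] = set()
    for _dist, _mz, pi, ki in pairs:
        if pi in assigned_pred or ki in used_peaks:
            continue
        assigned_pred[pi] = ki
        used_peaks.add(ki)

    matched = [
        (predicted[pi], (float(s.peaks[ki, 0]), float(s.peaks[ki, 1])))
        for pi, ki in sorted(assigned_pred.items())
    ]
    unmatched = [f for i, f in enumerate(predicted) if i not in assigned_pred]
    return MatchResult(matched, unmatched, tol)
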