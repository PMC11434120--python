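"""Amino-acid residue library, including non-canonical residues.

A *residue* is the in-chain unit: the free amino acid minus one water.
The library ships the 20 canonical residues plus the three non-canonical
(unnatural) residues recurrently found in lactobacilli cyclic dipeptides:

* ``Hyp``      4-hydroxyproline           = Pro + O
* ``MeEGlu``   glutamate 5-methyl ester   = Glu + CH2
* ``PyroGlu``  pyroglutamate              = Glu - H2O

Each residue carries diagnostic-ion definitions derived at load time:
its immonium ion (residue - CO + H, singly charged) plus residue-specific
companion ions (the proline-ring ion at m/z 98.06, the Leu/Ile immonium
ammonia-loss ion at m/z 69.07) and side-chain neutral losses (the tyrosine
quinomethide C7H6O; methanol from methyl esters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chem import ELECTRON_MASS, ElementCounts, FormulaError, parse_formula

__all__ = [
    "AminoAcidResidue",
    "ResidueLibrary",
    "ResidueNotFound",
    "ConfigError",
    "residue_library",
    "WATER",
    "CO",
    "METHANOL",
]

WATER = parse_formula("H2O")
CO = parse_formula("CO")
METHANOL = parse_formula("CH4O")
_H = parse_formula("H")


class ResidueNotFound(KeyError):
    """Raised when a residue code cannot be resolved in the library."""


class ConfigError(ValueError):
    """Raised for malformed residue-library override entries."""


@dataclass(frozen=True)
class AminoAcidResidue:
    """One amino-acid residue with its diagnostic-ion definitions."""

    code: str
    name: str
    formula: ElementCounts
    one_letter: str | None = None
    unnatural: bool = False
    #: cation diagnostics as (label, m/z), derived at library load
    diagnostic_ions: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    #: residue-specific neutral losses from the protonated precursor,
    #: as (label, neutral composition)
    side_chain_losses: tuple[tuple[str, ElementCounts], ...] = field(default_factory=tuple)
    #: residue contains a methyl ester, enabling -CH3OH precursor losses
    methyl_ester: bool = False

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def immonium_formula(self) -> ElementCounts:
        """Composition of the immonium cation: residue - CO + H."""
        if self.formula["C"] < 1 or self.formula["O"] < 1:
            raise ValueError(f"residue {self.code} cannot form an immonium ion")
        return self.formula - CO + _H

    @property
    def immonium_mz(self) -> float:
        """m/z of the singly charged immonium ion."""
        return self.immonium_formula.mass - ELECTRON_MASS

    def __repr__(self) -> str:
        return f"AminoAcidResidue({self.code}, {self.formula.hill()})"


# residue composition = free amino acid - H2O
_CANONICAL = [
    # code, one-letter, name, residue formula
    ("Gly", "G", "glycine", "C2H3NO"),
    ("Ala", "A", "alanine", "C3H5NO"),
    ("Ser", "S", "serine", "C3H5NO2"),
    ("Pro", "P", "proline", "C5H7NO"),
    ("Val", "V", "valine", "C5H9NO"),
    ("Thr", "T", "threonine", "C4H7NO2"),
    ("Cys", "C", "cysteine", "C3H5NOS"),
    ("Leu", "L", "leucine", "C6H11NO"),
    ("Ile", "I", "isoleucine", "C6H11NO"),
    ("Asn", "N", "asparagine", "C4H6N2O2"),
    ("Asp", "D", "aspartate", "C4H5NO3"),
    ("Gln", "Q", "glutamine", "C5H8N2O2"),
    ("Lys", "K", "lysine", "C6H12N2O"),
    ("Glu", "E", "glutamate", "C5H7NO3"),
    ("Met", "M", "methionine", "C5H9NOS"),
    ("His", "H", "histidine", "C6H7N3O"),
    ("Phe", "F", "phenylalanine", "C9H9NO"),
    ("Arg", "R", "arginine", "C6H12N4O"),
    ("Tyr", "Y", "tyrosine", "C9H9NO2"),
    ("Trp", "W", "tryptophan", "C11H10N2O"),
]

_UNNATURAL = [
    ("Hyp", None, "4-hydroxyproline", "C5H7NO2"),
    ("MeEGlu", None, "glutamate 5-methyl ester", "C6H9NO3"),
    ("PyroGlu", None, "pyroglutamate", "C5H5NO2"),
]

# Residue-specific diagnostic rules beyond the universal immonium ion.
# "ion": extra cation = residue composition + delta (charge +1).
# "loss": neutral side-chain loss from the protonated precursor.
_EXTRA_RULES: dict[str, list[tuple[str, str, str]]] = {
    "Pro": [("ion", "ring", "+H")],          # m/z 98.06, DKP ring fragment
    "Leu": [("ion", "imm-NH3", "imm-NH3")],  # m/z 69.07
    "Ile": [("ion", "imm-NH3", "imm-NH3")],  # m/z 69.07
    "Tyr": [("loss", "quinomethide", "C7H6O")],
}

_NH3 = parse_formula("NH3")


def _derive_diagnostics(
    code: str, formula: ElementCounts
) -> tuple[tuple[tuple[str, float], ...], tuple[tuple[str, ElementCounts], ...]]:
    ions: list[tuple[str, float]] = []
    losses: list[tuple[str, ElementCounts]] = []
    imm = formula - CO + _H
    if imm.is_species:
        ions.append((f"imm({code})", imm.mass - ELECTRON_MASS))
    for kind, label, what in _EXTRA_RULES.get(code, []):
        if kind == "ion":
            if what == "+H":
                comp = formula + _H
            elif what == "imm-NH3":
                comp = imm - _NH3
            else:
                comp = parse_formula(what)
            ions.append((f"{label}({code})", comp.mass - ELECTRON_MASS))
        else:
            losses.append((f"{label}({code})", parse_formula(what)))
    return tuple(ions), tuple(losses)


class ResidueLibrary:
    """Lookup table of residues by code, one-letter code or full name."""

    def __init__(self, residues: list[AminoAcidResidue]):
        self._residues = list(residues)
        self._index: dict[str, AminoAcidResidue] = {}
        for r in self._residues:
            self._index[r.code] = r
            self._index[r.name] = r
            if r.one_letter:
                self._index.setdefault(r.one_letter, r)

    def __iter__(self):
        return iter(self._residues)

    def __len__(self) -> int:
        return len(self._residues)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def get(self, code: str) -> AminoAcidResidue:
        try:
            return self._index[code]
        except KeyError:
            raise ResidueNotFound(f"unknown residue code {code!r}") from None

    __getitem__ = get

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self._residues]

    def parse_sequence(self, text: str) -> list[AminoAcidResidue]:
        """Resolve a peptide sequence string to residues.

        Accepts dash-separated multi-letter codes ("Tyr-Pro") or a bare
        run of one-letter codes ("LPPL").
        """
        text = text.strip()
        if not text:
            raise ResidueNotFound("empty sequence")
        if "-" in text:
            return [self.get(tok) for tok in text.split("-")]
        if text in self._index and len(text) > 1:
            return [self.get(text)]
        return [self.get(ch) for ch in text]


def _build_residue(
    code: str,
    one_letter: str | None,
    name: str,
    formula: str | ElementCounts,
    unnatural: bool,
) -> AminoAcidResidue:
    comp = formula if isinstance(formula, ElementCounts) else parse_formula(formula)
    if comp.mass <= 0 or not comp.is_species:
        raise ConfigError(f"residue {code}: non-physical composition {comp!r}")
    ions, losses = _derive_diagnostics(code, comp)
    return AminoAcidResidue(
        code=code,
        name=name,
        formula=comp,
        one_letter=one_letter,
        unnatural=unnatural,
        diagnostic_ions=ions,
        side_chain_losses=losses,
        methyl_ester=(code == "MeEGlu"),
    )


def residue_library(config: dict | str | Path | None = None) -> ResidueLibrary:
    """Build the residue library, optionally merged with user overrides.

    ``config`` may be a mapping ``{code: {name, formula, unnatural,
    diagnostic_ions}}`` or the path of a YAML file holding one.  An
    override with a known code replaces that entry; a new code extends
    the library.  Malformed entries raise :class:`ConfigError`.
    """
    residues = [
        _build_residue(code, ol, name, f, unnatural=False)
        for code, ol, name, f in _CANONICAL
    ]
    residues += [
        _build_residue(code, ol, name, f, unnatural=True)
        for code, ol, name, f in _UNNATURAL
    ]
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        if not isinstance(config, dict):
            raise ConfigError("residue overrides must be a mapping of code -> entry")
        by_code = {r.code: r for r in residues}
        for code, entry in config.items():
            if not isinstance(entry, dict) or "formula" not in entry:
                raise ConfigError(f"override for {code!r} must be a mapping with a formula")
            try:
                residue = _build_residue(
                    code,
                    entry.get("one_letter"),
                    entry.get("name", code),
                    entry["formula"],
                    unnatural=bool(entry.get("unnatural", True)),
                )
            except FormulaError as exc:
                raise ConfigError(f"override for {code!r}: {exc}") from exc
            extra = entry.get("diagnostic_ions", [])
            if extra:
                try:
                    extra_ions = tuple((str(lbl), float(mz)) for lbl, mz in extra)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(
                        f"override for {code!r}: diagnostic_ions must be (label, m/z) pairs"
                    ) from exc
                residue = dataclasses.replace(
                    residue, diagnostic_ions=residue.diagnostic_ions + extra_ions
                )
            by_code[code] = residue
        residues = list(by_code.values())
    return ResidueLibrary(residues)
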