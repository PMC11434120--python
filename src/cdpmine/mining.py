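"""The deep-mining annotation engine for molecular networks.

The strategy mirrors how an analyst reads a feature-based molecular
network (FBMN) of fermentation extracts:

1. ingest seed annotations (spectral-library matches and de novo calls);
2. for unannotated nodes, enumerate cyclic-dipeptide (CDP) candidates by
   exact precursor mass and keep those supported by diagnostic fragment
   ions (immonium ions, small neutral losses);
3. propagate annotations along network edges inside each cluster: an
   edge whose precursor mass difference equals a residue-exchange delta
   (e.g. 28.031 Da = C2H4 for Val->Ala) proposes the exchanged CDP,
   accepted only with fragment-ion support;
4. reconcile de novo dipeptides carrying a dehydration tag against the
   isobaric cyclic interpretation (a "dehydrated" linear dipeptide and
   the DKP share one formula);
5. classify isomers: identical residue composition at two retention
   times is a diastereomer pair; identical formula with different
   composition is positional isomerism.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .chem import ElementCounts, parse_formula
from .fragments import (
    CDPCandidate,
    LinearPeptide,
    Spectrum,
    Tolerance,
    cdp_fragments,
    linear_fragments,
    make_cdp,
    match_peaks,
)
from .io import (
    Annotation,
    DeNovoHit,
    MolecularNetwork,
    annotations_frame,
    read_denovo_table,
    read_mgf,
    read_network,
    write_annotations,
)
from .residues import ResidueLibrary, residue_library

__all__ = [
    "PipelineConfig",
    "EvidenceScore",
    "DeltaRule",
    "IsomerGroup",
    "TIER_ORDER",
    "enumerate_candidates",
    "score_annotation",
    "build_delta_rules",
    "propagate",
    "revise_linear_to_cyclic",
    "classify_isomers",
    "classify_unnatural",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

TIER_ORDER = {"weak": 0, "candidate": 1, "confident": 2}


@dataclass
class PipelineConfig:
    """All tunable tolerances, weights and behaviour switches.

    Defaults follow common high-resolution LC-MS/MS practice: 10 ppm on
    precursors, 0.02 Da on fragments, 0.01 Da when matching edge mass
    differences against residue-exchange deltas.
    """

    precursor_ppm: float = 10.0
    frag_tol_da: float = 0.02
    delta_tol_da: float = 0.01
    # evidence weights: immonium ions are the decisive class
    w_imm: float = 2.0
    w_loss: float = 1.0
    w_diag: float = 1.0
    #: minimum total matches (any class) for the "candidate" tier
    candidate_min_matches: int = 2
    #: tier required to accept a proposed annotation
    accept_tier: str = "candidate"
    min_alc: float = 50.0
    #: composition deltas allowed to cross cluster boundaries
    global_deltas: tuple[str, ...] = ("H2O",)
    #: opt-in Leu/Ile elution-order heuristic (Ile elutes earlier)
    leu_ile_rt: bool = False
    #: fallback de-novo-to-node join tolerances
    rt_join_min: float = 0.25
    #: exact-mass enumeration+scoring of unannotated nodes before
    #: propagation; disable for a propagation-only (seed-driven) run
    enumerate_unannotated: bool = True
    residue_overrides: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "global_deltas" in data:
            data["global_deltas"] = tuple(data["global_deltas"])
        return cls(**data)

    @property
    def precursor_tol(self) -> Tolerance:
        return Tolerance(self.precursor_ppm, "ppm")

    @property
    def frag_tol(self) -> Tolerance:
        return Tolerance(self.frag_tol_da, "da")


@dataclass
class EvidenceScore:
    """Fragment-match evidence for one candidate against one spectrum."""

    immonium_matches: int
    neutral_loss_matches: int
    diagnostic_matches: int
    weighted_total: float
    tier: str  # confident | candidate | weak
    precursor_ok: bool = True
    residues_covered: tuple[str, ...] = ()
    match: object | None = None  # MatchResult

    @property
    def n_matched(self) -> int:
        return self.immonium_matches + self.neutral_loss_matches + self.diagnostic_matches


@dataclass(frozen=True)
class DeltaRule:
    """A residue-exchange mass delta shared by one or more exchanges.

    ``exchanges`` lists (from, to) residue codes with
    composition(to) = composition(from) + ``composition_delta``;
    ``mass_delta`` is always positive (to is the heavier residue).
    """

    mass_delta: float
    composition_delta: ElementCounts
    exchanges: tuple[tuple[str, str], ...]

    def __repr__(self) -> str:
        return (
            f"DeltaRule({self.mass_delta:.4f} Da, {self.composition_delta.hill()}, "
            f"{len(self.exchanges)} exchanges)"
        )


@dataclass
class IsomerGroup:
    """Annotations sharing one elemental formula."""

    formula: ElementCounts
    members: tuple[Annotation, ...]
    relation: str  # diastereomer_pair | positional_isomers | unresolved


# --------------------------------------------------------------------------
# Candidate enumeration and evidence scoring
# --------------------------------------------------------------------------

def enumerate_candidates(
    precursor_mz: float,
    tol_ppm: float = 10.0,
    library: ResidueLibrary | None = None,
) -> list[CDPCandidate]:
    """All CDP residue pairs whose [M+H]+ falls within ``tol_ppm``.

    Leu- and Ile-containing pairs are both emitted (identical mass);
    results are sorted by absolute ppm error, then name.
    """
    library = library or residue_library()
    out: list[tuple[float, str, CDPCandidate]] = []
    for ra, rb in itertools.combinations_with_replacement(list(library), 2):
        c = make_cdp(ra, rb)
        ppm = (precursor_mz - c.precursor_mz) / c.precursor_mz * 1e6
        if abs(ppm) <= tol_ppm:
            out.append((abs(ppm), c.name, c))
    out.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in out]


def _score_match(
    match, candidate_residues: tuple[str, ...], config: PipelineConfig,
    precursor_ok: bool,
) -> EvidenceScore:
    imm = match.matched_by_kind("immonium")
    loss = match.matched_by_kind("neutral_loss")
    diag = match.matched_by_kind("diagnostic")
    covered = tuple(sorted({f.provenance for f in imm}))
    weighted = (
        config.w_imm * len(imm)
        + config.w_loss * len(loss)
        + config.w_diag * len(diag)
    )
    n = len(imm) + len(loss) + len(diag)
    if not precursor_ok:
        tier = "weak"
    elif set(covered) >= set(candidate_residues) and covered:
        tier = "confident"
    elif len(imm) >= 1 and len(loss) >= 2:
        tier = "confident"
    elif n >= config.candidate_min_matches:
        tier = "candidate"
    else:
        tier = "weak"
    return EvidenceScore(
        immonium_matches=len(imm),
        neutral_loss_matches=len(loss),
        diagnostic_matches=len(diag),
        weighted_total=weighted,
        tier=tier,
        precursor_ok=precursor_ok,
        residues_covered=covered,
        match=match,
    )


def score_annotation(
    s: Spectrum,
    c: CDPCandidate,
    config: PipelineConfig | None = None,
) -> EvidenceScore:
    """Score a CDP candidate against an observed spectrum.

    The tier is *confident* when every residue's immonium ion is matched
    (one ion covers both positions of a homodimeric CDP) or when one
    immonium plus two neutral losses are present; *candidate* requires at
    least ``candidate_min_matches`` matched fragments of any class.  A
    precursor outside the tolerance demotes the score to *weak* rather
    than raising.
    """
    config = config or PipelineConfig()
    window = config.precursor_tol.window(c.precursor_mz)
    precursor_ok = abs(s.precursor_mz - c.precursor_mz) <= window
    match = match_peaks(s, cdp_fragments(c), config.frag_tol)
    return _score_match(match, c.residue_codes, config, precursor_ok)


def score_linear(
    s: Spectrum,
    p: LinearPeptide,
    config: PipelineConfig | None = None,
) -> EvidenceScore:
    """Score a linear peptide by its b/y ladder plus residue diagnostics."""
    config = config or PipelineConfig()
    window = config.precursor_tol.window(p.precursor_mz)
    precursor_ok = abs(s.precursor_mz - p.precursor_mz) <= window
    frags = linear_fragments(p)
    match = match_peaks(s, frags, config.frag_tol)
    by = [f for f, _ in match.matched if f.kind in ("b", "y")]
    imm = match.matched_by_kind("immonium")
    diag = match.matched_by_kind("diagnostic")
    covered = tuple(sorted({f.provenance for f in imm}))
    weighted = config.w_imm * len(imm) + config.w_loss * len(by) + config.w_diag * len(diag)
    n = len(imm) + len(by) + len(diag)
    n_res = len(p.residues)
    if not precursor_ok:
        tier = "weak"
    elif len(by) >= max(2, n_res - 1):
        tier = "confident"
    elif n >= config.candidate_min_matches:
        tier = "candidate"
    else:
        tier = "weak"
    return EvidenceScore(
        immonium_matches=len(imm),
        neutral_loss_matches=len(by),
        diagnostic_matches=len(diag),
        weighted_total=weighted,
        tier=tier,
        precursor_ok=precursor_ok,
        residues_covered=covered,
        match=match,
    )


# --------------------------------------------------------------------------
# Residue-exchange delta rules and propagation
# --------------------------------------------------------------------------

def build_delta_rules(library: ResidueLibrary | None = None) -> list[DeltaRule]:
    """All pairwise residue-exchange deltas, deduplicated by composition.

    Includes the O exchange (Pro<->Hyp), CH2 (Glu<->MeEGlu and many
    canonical pairs), C2H4 (Ala<->Val), C3H6 (Ala<->Leu/Ile) and H2O
    (PyroGlu<->Glu).  Zero-delta pairs (Leu<->Ile) are excluded: they
    carry no precursor-mass signal.
    """
    library = library or residue_library()
    by_delta: dict[ElementCounts, list[tuple[str, str]]] = defaultdict(list)
    for ra, rb in itertools.permutations(list(library), 2):
        delta = rb.formula - ra.formula
        if delta.mass <= 1e-9:
            continue  # keep the positive direction only; zero deltas excluded
        by_delta[delta].append((ra.code, rb.code))
    rules = [
        DeltaRule(
            mass_delta=delta.mass,
            composition_delta=delta,
            exchanges=tuple(sorted(pairs)),
        )
        for delta, pairs in by_delta.items()
    ]
    rules.sort(key=lambda r: (r.mass_delta, r.composition_delta.hill()))
    return rules


def _exchange_candidate(
    base: CDPCandidate, old_code: str, new_code: str, library: ResidueLibrary
) -> CDPCandidate | None:
    codes = list(base.residue_codes)
    if old_code not in codes:
        return None
    codes[codes.index(old_code)] = new_code
    return make_cdp(codes[0], codes[1], library)


def _leu_ile_key(codes: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(sorted("Leu/Ile" if c in ("Leu", "Ile") else c for c in codes))


def _merge_leu_ile_name(codes: tuple[str, ...]) -> str:
    return "cyclo(" + "-".join(_leu_ile_key(codes)) + ")"


@dataclass
class _Proposal:
    candidate: CDPCandidate
    score: EvidenceScore
    path: tuple[str, ...]
    via: str  # human-readable delta route


def _propose(
    node: str,
    observed_mz: float,
    spectrum: Spectrum | None,
    source_ann: Annotation,
    rules: list[DeltaRule],
    config: PipelineConfig,
    library: ResidueLibrary,
) -> list[_Proposal]:
    base = source_ann.candidate
    if not isinstance(base, CDPCandidate):
        return []
    d = observed_mz - source_ann.observed_mz
    proposals: list[_Proposal] = []
    for rule in rules:
        if abs(abs(d) - rule.mass_delta) > config.delta_tol_da:
            continue
        for from_code, to_code in rule.exchanges:
            if d > 0:
                cand = _exchange_candidate(base, from_code, to_code, library)
                route = f"{from_code}->{to_code} (+{rule.composition_delta.hill()})"
            else:
                cand = _exchange_candidate(base, to_code, from_code, library)
                route = f"{to_code}->{from_code} (-{rule.composition_delta.hill()})"
            if cand is None:
                continue
            window = config.precursor_tol.window(cand.precursor_mz)
            if abs(observed_mz - cand.precursor_mz) > window:
                continue
            if spectrum is None:
                continue
            score = score_annotation(spectrum, cand, config)
            if TIER_ORDER[score.tier] >= TIER_ORDER[config.accept_tier]:
                proposals.append(
                    _Proposal(cand, score, source_ann.path + (node,), route)
                )
    return proposals


def _resolve_proposals(
    node: str, observed_mz: float, rt: float | None, proposals: list[_Proposal]
) -> Annotation | None:
    """Pick the best-scoring proposal; merge or flag exact ties.

    Tied candidates that differ only by a Leu<->Ile swap are merged into
    one annotation displayed as "Leu/Ile"; other exact ties are marked
    unresolved and every tied name is carried in the isomer tag.
    """
    if not proposals:
        return None
    best = max(p.score.weighted_total for p in proposals)
    top: dict[str, _Proposal] = {}
    for p in proposals:
        if p.score.weighted_total == best and p.candidate.name not in top:
            top[p.candidate.name] = p
    tied = sorted(top.values(), key=lambda p: p.candidate.name)
    primary = tied[0]
    ann = Annotation(
        node_id=node,
        candidate=primary.candidate,
        level="propagated",
        observed_mz=observed_mz,
        rt=rt,
        evidence=primary.score,
        path=primary.path,
        history=(f"via {primary.via}",),
    )
    if len(tied) > 1:
        keys = {_leu_ile_key(p.candidate.residue_codes) for p in tied}
        if len(keys) == 1:
            ann.display_name = _merge_leu_ile_name(primary.candidate.residue_codes)
            ann.isomer_tag = "Leu/Ile"
        else:
            ann.isomer_tag = "unresolved: " + " | ".join(
                p.candidate.name for p in tied
            )
        ann.alternatives = tuple(p.candidate for p in tied[1:])
    return ann


def propagate(
    net: MolecularNetwork,
    seeds: list[Annotation],
    spectra: dict[str, Spectrum],
    rules: list[DeltaRule] | None = None,
    config: PipelineConfig | None = None,
    library: ResidueLibrary | None = None,
) -> list[Annotation]:
    """Propagate annotations over the network to a fixpoint.

    Breadth-first within each cluster: an unannotated neighbour whose
    precursor delta matches a residue-exchange rule is proposed the
    exchanged candidate and accepted only with fragment-ion support at
    tier >= ``accept_tier``.  A second pass allows the whitelisted
    global deltas (H2O by default, the Glu<->PyroGlu exchange) between
    any annotated/unannotated node pair regardless of cluster.  Seeds
    are never overwritten, every accepted annotation records its path,
    and re-running on the output is a no-op.
    """
    config = config or PipelineConfig()
    library = library or residue_library()
    rules = rules if rules is not None else build_delta_rules(library)
    global_rules = [
        r
        for r in rules
        if r.composition_delta in {parse_formula(f) for f in config.global_deltas}
    ]

    g = net.graph()
    for s in seeds:
        if s.node_id not in g:
            raise ValueError(f"seed node {s.node_id!r} not in network")
    ann: dict[str, Annotation] = {}
    for s in seeds:
        if not s.path:
            s = replace_path(s, (s.node_id,))
        ann[s.node_id] = s

    def node_order(nid: str) -> tuple:
        return (net.node_mz(nid), net.node_rt(nid) or 0.0, nid)

    changed = True
    while changed:
        changed = False
        # pass 1: intra-cluster edges, to fixpoint
        while True:
            proposals: dict[str, list[_Proposal]] = defaultdict(list)
            for u in sorted(ann, key=node_order):
                for v in net.neighbors(u):
                    if v in ann or net.cluster_of(v) != net.cluster_of(u):
                        continue
                    proposals[v].extend(
                        _propose(v, net.node_mz(v), spectra.get(v), ann[u],
                                 rules, config, library)
                    )
            new = False
            for v in sorted(proposals, key=node_order):
                a = _resolve_proposals(v, net.node_mz(v), net.node_rt(v), proposals[v])
                if a is not None:
                    ann[v] = a
                    new = changed = True
            if not new:
                break
        # pass 2: whitelisted global deltas across clusters, one sweep
        proposals = defaultdict(list)
        annotated = sorted(ann, key=node_order)
        for u in annotated:
            for v in sorted(set(net.nodes["feature_id"]) - set(ann), key=node_order):
                proposals[v].extend(
                    _propose(v, net.node_mz(v), spectra.get(v), ann[u],
                             global_rules, config, library)
                )
        for v in sorted(proposals, key=node_order):
            a = _resolve_proposals(v, net.node_mz(v), net.node_rt(v), proposals[v])
            if a is not None:
                ann[v] = a
                changed = True

    return [ann[k] for k in sorted(ann, key=node_order)]


def replace_path(a: Annotation, path: tuple[str, ...]) -> Annotation:
    a.path = path
    return a


# --------------------------------------------------------------------------
# De novo reconciliation
# --------------------------------------------------------------------------

def join_hits_to_nodes(
    hits: list[DeNovoHit],
    net: MolecularNetwork,
    config: PipelineConfig | None = None,
) -> list[tuple[DeNovoHit, str]]:
    """Join de novo hits to network nodes.

    Prefers exact feature-id matches; otherwise falls back to the
    nearest node within the precursor ppm and RT tolerances.  Unjoinable
    hits are dropped with a warning.
    """
    config = config or PipelineConfig()
    ids = set(net.nodes["feature_id"])
    joined: list[tuple[DeNovoHit, str]] = []
    for hit in hits:
        if hit.feature_id is not None and hit.feature_id in ids:
            joined.append((hit, hit.feature_id))
            continue
        if hit.precursor_mz is None:
            logger.warning("de novo hit %s has no feature id or m/z; dropped",
                           "-".join(hit.sequence))
            continue
        best: tuple[float, str] | None = None
        for row in net.nodes.itertuples(index=False):
            dppm = abs(row.precursor_mz - hit.precursor_mz) / hit.precursor_mz * 1e6
            if dppm > config.precursor_ppm:
                continue
            if hit.rt is not None and row.rt == row.rt:  # rt not NaN
                if abs(row.rt - hit.rt) > config.rt_join_min:
                    continue
            if best is None or dppm < best[0]:
                best = (dppm, row.feature_id)
        if best is None:
            logger.warning("de novo hit %s matched no node; dropped",
                           "-".join(hit.sequence))
        else:
            joined.append((hit, best[1]))
    return joined


def revise_linear_to_cyclic(
    hits: list[DeNovoHit],
    net: MolecularNetwork,
    spectra: dict[str, Spectrum],
    config: PipelineConfig | None = None,
    existing: list[Annotation] | None = None,
    library: ResidueLibrary | None = None,
) -> list[Annotation]:
    """Reconcile de novo dipeptides against the cyclic interpretation.

    A dipeptide carrying a net dehydration tag (or whose precursor
    already equals the residue sum plus a proton) is isobaric with the
    DKP; it is rescored as the CDP and revised when the CDP evidence
    reaches tier >= ``accept_tier`` and its cluster already contains a
    CDP-annotated node.  For Glu-containing dipeptides the competing
    explanation — a linear peptide with Glu cyclized to PyroGlu — is
    scored too and wins when its evidence is strictly stronger.  Hits
    longer than two residues pass through unchanged as de novo calls.
    """
    config = config or PipelineConfig()
    library = library or residue_library()
    existing = existing or []
    cdp_clusters = {
        net.cluster_of(a.node_id)
        for a in existing
        if isinstance(a.candidate, CDPCandidate) and a.node_id in net.graph()
    }
    out: list[Annotation] = []
    for hit, node in join_hits_to_nodes(hits, net, config):
        obs_mz = net.node_mz(node)
        rt = net.node_rt(node)
        spectrum = spectra.get(node)
        residues = tuple(library.get(c) for c in hit.sequence)
        linear = LinearPeptide(residues=residues,
                               modifications=tuple(m for _, m in hit.modifications))
        original = "-".join(hit.sequence) + (
            f"({hit.total_modification:+.2f})" if hit.modifications else ""
        )

        if len(hit.sequence) != 2:
            out.append(
                Annotation(node_id=node, candidate=linear, level="denovo",
                           observed_mz=obs_mz, rt=rt,
                           evidence=score_linear(spectrum, linear, config)
                           if spectrum else None)
            )
            continue

        cdp = make_cdp(hit.sequence[0], hit.sequence[1], library)
        window = config.precursor_tol.window(cdp.precursor_mz)
        cyclizable = hit.is_dehydrated() or abs(obs_mz - cdp.precursor_mz) <= window
        if not cyclizable:
            out.append(
                Annotation(node_id=node, candidate=linear, level="denovo",
                           observed_mz=obs_mz, rt=rt,
                           evidence=score_linear(spectrum, linear, config)
                           if spectrum else None)
            )
            continue

        cdp_score = (score_annotation(spectrum, cdp, config)
                     if spectrum else None)

        # competing explanation: linear peptide with Glu -> PyroGlu
        pyro_alt = None
        pyro_score = None
        if "Glu" in hit.sequence and spectrum is not None:
            alt_seq = tuple(
                library.get("PyroGlu") if c == "Glu" else library.get(c)
                for c in hit.sequence
            )
            pyro_alt = LinearPeptide(residues=alt_seq)
            pyro_score = score_linear(spectrum, pyro_alt, config)

        accept = (
            cdp_score is not None
            and TIER_ORDER[cdp_score.tier] >= TIER_ORDER[config.accept_tier]
            and net.cluster_of(node) in cdp_clusters
        )
        if accept and pyro_score is not None \
                and pyro_score.weighted_total > cdp_score.weighted_total:
            out.append(
                Annotation(node_id=node, candidate=pyro_alt, level="revised",
                           observed_mz=obs_mz, rt=rt, evidence=pyro_score,
                           history=(f"denovo:{original}",))
            )
        elif accept:
            ann = Annotation(node_id=node, candidate=cdp, level="revised",
                             observed_mz=obs_mz, rt=rt, evidence=cdp_score,
                             history=(f"denovo:{original}",))
            if pyro_alt is not None:
                ann.alternatives = (pyro_alt,)
            out.append(ann)
        else:
            out.append(
                Annotation(node_id=node, candidate=linear, level="denovo",
                           observed_mz=obs_mz, rt=rt,
                           evidence=score_linear(spectrum, linear, config)
                           if spectrum else None)
            )
    return out


# --------------------------------------------------------------------------
# Isomer and unnatural-residue classification
# --------------------------------------------------------------------------

def _composition_key(a: Annotation) -> tuple[str, ...]:
    if isinstance(a.candidate, CDPCandidate):
        return tuple(sorted(a.candidate.residue_codes))
    return tuple(r.code for r in a.candidate.residues)


def classify_isomers(
    annotations: list[Annotation], leu_ile_rt: bool = False
) -> list[IsomerGroup]:
    """Group annotations by elemental formula and classify the isomerism.

    Within a formula group, members sharing the same named residue
    composition at exactly two distinct retention times form a
    *diastereomer pair* (same constitution, different stereochemistry,
    resolved by reversed-phase RT); members with different compositions
    are *positional isomers*; anything else is *unresolved*.  With
    ``leu_ile_rt`` the opt-in elution-order heuristic assigns Ile to the
    earlier-eluting member of a Leu/Ile-ambiguous pair.
    """
    def member_order(a: Annotation):
        return (a.rt if a.rt is not None else float("inf"), a.name, a.node_id)

    by_formula: dict[str, list[Annotation]] = defaultdict(list)
    for a in annotations:
        by_formula[a.formula.hill()].append(a)

    groups: list[IsomerGroup] = []
    for hill in sorted(by_formula):
        members = sorted(by_formula[hill], key=member_order)
        formula = members[0].formula

        if leu_ile_rt:
            _apply_leu_ile_heuristic(members)

        by_comp: dict[tuple[str, ...], list[Annotation]] = defaultdict(list)
        for a in members:
            by_comp[_composition_key(a)].append(a)

        for comp in sorted(by_comp):
            sub = by_comp[comp]
            if len(sub) < 2:
                continue
            rts = {round(a.rt, 4) for a in sub if a.rt is not None}
            if len(sub) == 2 and len(rts) == 2:
                for a in sub:
                    if not a.isomer_tag:
                        a.isomer_tag = "or isomer"
                groups.append(
                    IsomerGroup(formula=formula, members=tuple(sub),
                                relation="diastereomer_pair")
                )
            else:
                groups.append(
                    IsomerGroup(formula=formula, members=tuple(sub),
                                relation="unresolved")
                )
        if len(by_comp) > 1:
            groups.append(
                IsomerGroup(formula=formula, members=tuple(members),
                            relation="positional_isomers")
            )
    groups.sort(key=lambda g: (g.formula.hill(), g.relation,
                               tuple(a.node_id for a in g.members)))
    return groups


def _apply_leu_ile_heuristic(members: list[Annotation]) -> None:
    """Label Ile as the earlier-eluting member of Leu/Ile-ambiguous pairs.

    On C18 reversed phase the Ile-containing CDP of a same-formula pair
    elutes before its Leu counterpart; relabelled names are marked
    heuristic in the isomer tag.
    """
    by_key: dict[tuple[str, ...], list[Annotation]] = defaultdict(list)
    for a in members:
        if isinstance(a.candidate, CDPCandidate):
            key = _leu_ile_key(a.candidate.residue_codes)
            if "Leu/Ile" in key:
                by_key[key].append(a)
    for key, group in by_key.items():
        if len(group) != 2:
            continue
        rts = [a.rt for a in group]
        if None in rts or rts[0] == rts[1]:
            continue
        group.sort(key=lambda a: a.rt)
        for a, code in zip(group, ("Ile", "Leu")):
            resolved = tuple(code if c == "Leu/Ile" else c for c in key)
            a.display_name = "cyclo(" + "-".join(sorted(resolved)) + ")"
            a.isomer_tag = f"{code} by RT heuristic"


def classify_unnatural(annotations: list[Annotation]) -> dict[str, int]:
    """Count annotations containing at least one unnatural residue.

    The flag itself is derived from the residue library (Hyp, MeEGlu and
    PyroGlu ship flagged); this reports the partition.
    """
    unnatural = sum(1 for a in annotations if a.unnatural)
    return {
        "total": len(annotations),
        "unnatural": unnatural,
        "natural": len(annotations) - unnatural,
    }


# --------------------------------------------------------------------------
# Pipeline orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    annotations: list[Annotation]
    isomer_groups: list[IsomerGroup]
    counts: dict
    report: pd.DataFrame

    @property
    def diastereomer_pairs(self) -> int:
        return sum(1 for g in self.isomer_groups if g.relation == "diastereomer_pair")

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"annotated nodes: {c['total']}",
            "provenance: "
            + ", ".join(f"{k}={v}" for k, v in sorted(c["by_level"].items())),
            f"CDPs: {c['cdps']} ({c['unnatural']} with unnatural residues)",
            f"diastereomer pairs: {self.diastereomer_pairs}",
        ]
        return "\n".join(lines)


def _read_seed_table(path: str | Path, net: MolecularNetwork,
                     library: ResidueLibrary) -> list[Annotation]:
    """Seed annotations (e.g. spectral-library matches): feature_id, name."""
    df = pd.read_csv(path, sep=None, engine="python")
    seeds = []
    for row in df.itertuples(index=False):
        fid = str(row.feature_id)
        name = str(row.name if hasattr(row, "name") else row.compound)
        level = str(getattr(row, "level", "database"))
        if name.startswith("cyclo(") and name.endswith(")"):
            a_code, b_code = name[6:-1].split("-", 1)
            candidate: CDPCandidate | LinearPeptide = make_cdp(a_code, b_code, library)
        else:
            codes, mods = __import__("cdpmine.io", fromlist=["parse_denovo_sequence"]) \
                .parse_denovo_sequence(name, library)
            candidate = LinearPeptide(
                residues=tuple(library.get(c) for c in codes),
                modifications=tuple(m for _, m in mods),
            )
        seeds.append(
            Annotation(node_id=fid, candidate=candidate, level=level,
                       observed_mz=net.node_mz(fid), rt=net.node_rt(fid))
        )
    return seeds


def run_pipeline(
    config: PipelineConfig | None = None,
    *,
    mgf: str | Path,
    nodes: str | Path,
    edges: str | Path,
    denovo: str | Path | None = None,
    seeds: str | Path | list[Annotation] | None = None,
    out: str | Path | None = None,
) -> PipelineResult:
    """Run the full annotation workflow and (optionally) write the report.

    Stages: seed ingestion -> exact-mass enumeration and evidence
    scoring of unannotated nodes -> residue-exchange propagation ->
    de novo reconciliation -> isomer and unnatural-residue
    classification -> report.  Deterministic for fixed inputs/config.
    """
    config = config or PipelineConfig()
    library = residue_library(config.residue_overrides)
    spectra_list = read_mgf(mgf)
    net = read_network(nodes, edges)
    spectra = {s.id: s for s in spectra_list}

    # ---- seed ingestion -------------------------------------------------
    if seeds is None:
        seed_anns: list[Annotation] = []
    elif isinstance(seeds, (str, Path)):
        seed_anns = _read_seed_table(seeds, net, library)
    else:
        seed_anns = list(seeds)
    for a in seed_anns:
        if a.evidence is None and a.node_id in spectra \
                and isinstance(a.candidate, CDPCandidate):
            a.evidence = score_annotation(spectra[a.node_id], a.candidate, config)
    annotated = {a.node_id: a for a in seed_anns}
    logger.info("stage seeds: %d annotations", len(annotated))

    hits: list[DeNovoHit] = []
    if denovo is not None:
        hits = read_denovo_table(denovo, min_alc=config.min_alc, library=library)

    # ---- exact-mass enumeration + scoring on unannotated nodes ---------
    mined = 0
    for row in net.nodes.itertuples(index=False):
        nid = row.feature_id
        if not config.enumerate_unannotated:
            break
        if nid in annotated or nid not in spectra:
            continue
        candidates = enumerate_candidates(row.precursor_mz, config.precursor_ppm, library)
        proposals = []
        for c in candidates:
            score = score_annotation(spectra[nid], c, config)
            if TIER_ORDER[score.tier] >= TIER_ORDER[config.accept_tier]:
                proposals.append(_Proposal(c, score, (nid,), "exact mass"))
        ann = _resolve_proposals(nid, row.precursor_mz, row.rt, proposals)
        if ann is not None:
            ann.level = "deep_mined"
            annotated[nid] = ann
            mined += 1
    logger.info("stage enumeration: %d deep-mined annotations", mined)

    # ---- propagation ----------------------------------------------------
    rules = build_delta_rules(library)
    all_anns = propagate(net, list(annotated.values()), spectra, rules, config, library)
    annotated = {a.node_id: a for a in all_anns}
    logger.info("stage propagation: %d total annotations", len(annotated))

    # ---- de novo reconciliation -----------------------------------------
    if hits:
        unseen = [h for h in hits]
        revised = revise_linear_to_cyclic(
            unseen, net, spectra, config, existing=list(annotated.values()),
            library=library,
        )
        for a in revised:
            if a.node_id not in annotated:
                annotated[a.node_id] = a
            elif a.level == "revised" and annotated[a.node_id].level == "denovo":
                annotated[a.node_id] = a
        logger.info("stage revision: %d de novo hits reconciled", len(revised))

    final = sorted(
        annotated.values(),
        key=lambda a: (a.observed_mz, a.rt if a.rt is not None else 0.0, a.node_id),
    )

    # ---- classification + report ----------------------------------------
    groups = classify_isomers(final, leu_ile_rt=config.leu_ile_rt)
    unnatural_counts = classify_unnatural(final)
    by_level: dict[str, int] = defaultdict(int)
    for a in final:
        by_level[a.level] += 1
    counts = {
        "total": len(final),
        "by_level": dict(by_level),
        "cdps": sum(1 for a in final if isinstance(a.candidate, CDPCandidate)),
        "unnatural": unnatural_counts["unnatural"],
        "provenance_partition": {
            "database": by_level.get("database", 0),
            "denovo": by_level.get("denovo", 0) + by_level.get("revised", 0),
            "deep_mined": by_level.get("deep_mined", 0) + by_level.get("propagated", 0),
        },
    }
    report = annotations_frame(final)
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_annotations(final, out / "annotations.tsv")
    return PipelineResult(annotations=final, isomer_groups=groups,
                          counts=counts, report=report)
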