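"""Readers and writers for the pipeline's standard artifacts.

Supported formats:

* MGF (Mascot Generic Format) MS/MS spectra, via pyteomics;
* molecular-network node and edge tables as delimited text, in the
  GNPS/Cytoscape export dialects (column names are config-mapped);
* de novo sequencing result tables (feature key, sequence with inline
  modification tags, ALC score);
* the final annotation report as TSV.

Retention times are minutes internally; MGF RTINSECONDS is converted on
load.  Feature ids are opaque text keys.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import ElementCounts
from .fragments import CDPCandidate, LinearPeptide, Spectrum
from .residues import ResidueLibrary, ResidueNotFound, residue_library

__all__ = [
    "MolecularNetwork",
    "DeNovoHit",
    "Annotation",
    "NetworkFormatError",
    "read_mgf",
    "write_mgf",
    "read_network",
    "read_denovo_table",
    "write_annotations",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# MGF spectra
# --------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` records.

    Records without a PEPMASS line are skipped with a warning; peaks are
    sorted ascending by m/z on load and RTINSECONDS converted to minutes.
    """
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, record in enumerate(reader):
            params = record.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.warning("MGF record %d in %s lacks PEPMASS; skipped", i, path)
                continue
            rt = params.get("rtinseconds")
            title = str(params.get("title", "")) or str(
                params.get("feature_id", params.get("scans", f"spectrum_{i}"))
            )
            peaks = np.column_stack(
                (record.get("m/z array", []), record.get("intensity array", []))
            ) if len(record.get("m/z array", [])) else np.empty((0, 2))
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    rt=float(rt) / 60.0 if rt is not None else None,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF; inverse of :func:`read_mgf` up to formatting."""
    records = []
    for s in spectra:
        params: dict[str, object] = {"title": s.id, "pepmass": s.precursor_mz}
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        records.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _mgf.write(records, str(path), file_mode="w")


# --------------------------------------------------------------------------
# Molecular-network tables
# --------------------------------------------------------------------------

class NetworkFormatError(ValueError):
    """Raised when node/edge tables are structurally invalid."""


#: Recognised column aliases (lowercased, non-alphanumerics stripped).
_NODE_ALIASES = {
    "feature_id": ["featureid", "rowid", "clusterindex", "id", "node", "scans",
                   "sharedname", "name"],
    "precursor_mz": ["precursormz", "rowmz", "mz", "parentmass", "precursormass"],
    "rt": ["rt", "rtmean", "rowretentiontime", "retentiontime", "rtinminutes"],
    "cluster": ["cluster", "componentindex", "component", "clusterid", "network"],
}
_EDGE_ALIASES = {
    "source": ["clusterid1", "node1", "source", "id1", "from"],
    "target": ["clusterid2", "node2", "target", "id2", "to"],
    "cosine": ["cosine", "cosinescore", "score", "cosine_score"],
    "delta_mz": ["deltamz", "massdifference", "mzdiff", "deltamass"],
}


def _normalise(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def _map_columns(df: pd.DataFrame, aliases: dict[str, list[str]],
                 overrides: dict[str, str] | None) -> dict[str, str]:
    overrides = overrides or {}
    found: dict[str, str] = {}
    norm = {_normalise(c): c for c in df.columns}
    for canonical, names in aliases.items():
        if canonical in overrides:
            if overrides[canonical] in df.columns:
                found[canonical] = overrides[canonical]
            continue
        for alias in names:
            if alias in norm:
                found[canonical] = norm[alias]
                break
    return found


@dataclass
class MolecularNetwork:
    """Feature-based molecular network: nodes, scored edges, clusters."""

    nodes: pd.DataFrame  # feature_id, precursor_mz, rt, cluster
    edges: pd.DataFrame  # source, target, cosine, delta_mz
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            for row in self.nodes.itertuples(index=False):
                g.add_node(row.feature_id, precursor_mz=row.precursor_mz,
                           rt=row.rt, cluster=row.cluster)
            for row in self.edges.itertuples(index=False):
                g.add_edge(row.source, row.target, cosine=row.cosine,
                           delta_mz=row.delta_mz)
            self._graph = g
        return self._graph

    def neighbors(self, feature_id: str) -> list[str]:
        return sorted(self.graph().neighbors(feature_id))

    def node_mz(self, feature_id: str) -> float:
        return float(self.graph().nodes[feature_id]["precursor_mz"])

    def node_rt(self, feature_id: str) -> float | None:
        return self.graph().nodes[feature_id]["rt"]

    def cluster_of(self, feature_id: str) -> int:
        return int(self.graph().nodes[feature_id]["cluster"])

    def nodes_in_cluster(self, cluster: int) -> list[str]:
        df = self.nodes
        return df.loc[df["cluster"] == cluster, "feature_id"].tolist()

    @property
    def n_clusters(self) -> int:
        return int(self.nodes["cluster"].nunique())


def _assign_components(nodes: pd.DataFrame, edges: pd.DataFrame) -> pd.Series:
    """Deterministic connected-component numbering.

    Components are numbered 1..k by the smallest precursor m/z (then
    feature id) of their members, so identical inputs always yield
    identical cluster ids.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes["feature_id"])
    g.add_edges_from(zip(edges["source"], edges["target"]))
    mz = dict(zip(nodes["feature_id"], nodes["precursor_mz"]))
    comps = sorted(
        (sorted(c, key=lambda n: (mz[n], n)) for c in nx.connected_components(g)),
        key=lambda members: (mz[members[0]], members[0]),
    )
    label = {n: i + 1 for i, members in enumerate(comps) for n in members}
    return nodes["feature_id"].map(label)


def read_network(
    nodes_path: str | Path,
    edges_path: str | Path,
    column_map: dict[str, str] | None = None,
    delta_consistency_da: float = 0.01,
) -> MolecularNetwork:
    """Load and validate a molecular network from delimited node/edge tables.

    Self-loop edges are dropped with a warning; an edge referencing an
    unknown node raises :class:`NetworkFormatError` listing the
    offenders, as does a stored edge mass difference disagreeing with
    the node m/z difference by more than ``delta_consistency_da``.
    Cluster ids are recomputed from connected components when absent.
    """
    nodes_raw = pd.read_csv(nodes_path, sep=None, engine="python")
    edges_raw = pd.read_csv(edges_path, sep=None, engine="python")

    ncols = _map_columns(nodes_raw, _NODE_ALIASES, column_map)
    ecols = _map_columns(edges_raw, _EDGE_ALIASES, column_map)
    for required, cols, which in (
        (("feature_id", "precursor_mz"), ncols, "node"),
        (("source", "target"), ecols, "edge"),
    ):
        missing = [c for c in required if c not in cols]
        if missing:
            raise NetworkFormatError(f"{which} table lacks columns for {missing}")

    nodes = pd.DataFrame(
        {
            "feature_id": nodes_raw[ncols["feature_id"]].astype(str),
            "precursor_mz": nodes_raw[ncols["precursor_mz"]].astype(float),
            "rt": nodes_raw[ncols["rt"]].astype(float) if "rt" in ncols else np.nan,
        }
    )
    edges = pd.DataFrame(
        {
            "source": edges_raw[ecols["source"]].astype(str),
            "target": edges_raw[ecols["target"]].astype(str),
            "cosine": edges_raw[ecols["cosine"]].astype(float)
            if "cosine" in ecols
            else 1.0,
            "delta_mz": edges_raw[ecols["delta_mz"]].astype(float)
            if "delta_mz" in ecols
            else np.nan,
        }
    )

    self_loops = edges["source"] == edges["target"]
    if self_loops.any():
        logger.warning("dropping %d self-loop edge(s)", int(self_loops.sum()))
        edges = edges.loc[~self_loops].reset_index(drop=True)

    known = set(nodes["feature_id"])
    bad = edges.loc[
        ~edges["source"].isin(known) | ~edges["target"].isin(known)
    ]
    if len(bad):
        offenders = sorted(
            set(bad["source"]).union(bad["target"]) - known
        )
        raise NetworkFormatError(f"edges reference unknown node ids: {offenders}")

    mz = dict(zip(nodes["feature_id"], nodes["precursor_mz"]))
    computed = (
        edges["source"].map(mz) - edges["target"].map(mz)
    ).abs()
    stored = edges["delta_mz"]
    inconsistent = stored.notna() & ((stored - computed).abs() > delta_consistency_da)
    if inconsistent.any():
        rows = edges.loc[inconsistent, ["source", "target"]].to_records(index=False)
        raise NetworkFormatError(
            f"edge mass differences disagree with node m/z by >"
            f"{delta_consistency_da} Da: {list(map(tuple, rows))}"
        )
    edges["delta_mz"] = computed.where(stored.isna(), stored)

    if "cluster" in ncols:
        nodes["cluster"] = nodes_raw[ncols["cluster"]].astype(int)
    else:
        nodes["cluster"] = _assign_components(nodes, edges)

    # canonical deterministic ordering
    nodes = nodes.sort_values(
        ["precursor_mz", "rt", "feature_id"], na_position="last"
    ).reset_index(drop=True)
    pair = edges[["source", "target"]].apply(sorted, axis=1, result_type="expand") \
        if len(edges) else edges[["source", "target"]]
    if len(edges):
        edges[["source", "target"]] = pair
        edges = edges.sort_values(["source", "target"]).reset_index(drop=True)

    return MolecularNetwork(nodes=nodes, edges=edges)


# --------------------------------------------------------------------------
# De novo result tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeNovoHit:
    """One de novo sequencing call joined (or joinable) to a feature."""

    sequence: tuple[str, ...]
    alc: float  # average local confidence, percent
    feature_id: str | None = None
    precursor_mz: float | None = None
    rt: float | None = None
    modifications: tuple[tuple[int, float], ...] = ()  # (0-based position, Da)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("de novo hit with empty sequence")
        if not 0 <= self.alc <= 100:
            raise ValueError(f"ALC {self.alc} outside [0, 100]")

    @property
    def total_modification(self) -> float:
        return sum(m for _, m in self.modifications)

    def is_dehydrated(self, tol: float = 0.02) -> bool:
        """True when the hit carries a net -H2O (~-18.011 Da) mass tag."""
        return abs(self.total_modification + 18.010565) <= tol


_SEQ_TOKEN = re.compile(r"([A-Za-z]+)(?:\(([+-]?\d+(?:\.\d+)?)\))?")


def parse_denovo_sequence(
    text: str, library: ResidueLibrary
) -> tuple[tuple[str, ...], tuple[tuple[int, float], ...]]:
    """Parse a sequence string with optional inline modification tags.

    Accepts dash-separated codes (``Tyr-Pro(-18.01)``) or bare one-letter
    runs (``LPPL``, ``YP(-18.01)``); a parenthesised signed number binds
    to the residue it follows.
    """
    # split on dashes outside parentheses, so "(-18.01)" tags survive
    parts: list[str] = []
    depth, start = 0, 0
    stripped = text.strip().replace(" ", "")
    for i, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "-" and depth == 0:
            parts.append(stripped[start:i])
            start = i + 1
    parts.append(stripped[start:])

    codes: list[str] = []
    mods: list[tuple[int, float]] = []
    for part in parts:
        pos = 0
        while pos < len(part):
            m = _SEQ_TOKEN.match(part, pos)
            if m is None or not m.group(1):
                raise ResidueNotFound(
                    f"unparseable sequence fragment {part[pos:]!r} in {text!r}"
                )
            token, tag = m.group(1), m.group(2)
            if token in library and len(token) > 1:
                codes.append(library.get(token).code)
            else:
                for ch in token:
                    codes.append(library.get(ch).code)
            if tag is not None:
                mods.append((len(codes) - 1, float(tag)))
            pos = m.end()
    if not codes:
        raise ResidueNotFound(f"no residues parsed from {text!r}")
    return tuple(codes), tuple(mods)


_DENOVO_ALIASES = {
    "feature_id": ["featureid", "id", "scan", "scans", "feature"],
    "sequence": ["sequence", "peptide", "denovopeptide"],
    "alc": ["alc", "alcpercent", "meanlocalconfidence", "alcscore"],
    "precursor_mz": ["precursormz", "mz", "m/z", "menergy", "masscharge"],
    "rt": ["rt", "retentiontime", "rtmin"],
}


def read_denovo_table(
    path: str | Path,
    min_alc: float = 50.0,
    library: ResidueLibrary | None = None,
    column_map: dict[str, str] | None = None,
) -> list[DeNovoHit]:
    """Read a de novo result table, excluding hits below ``min_alc``.

    Rows with unparseable sequences are skipped with a warning.
    """
    library = library or residue_library()
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        return []
    cols = _map_columns(df, _DENOVO_ALIASES, column_map)
    if "sequence" not in cols or "alc" not in cols:
        raise NetworkFormatError("de novo table lacks sequence and/or ALC columns")
    hits: list[DeNovoHit] = []
    for _, row in df.iterrows():
        alc = float(row[cols["alc"]])
        if alc < min_alc:
            continue
        try:
            seq, mods = parse_denovo_sequence(str(row[cols["sequence"]]), library)
        except (ResidueNotFound, ValueError) as exc:
            logger.warning("skipping de novo row %r: %s", row[cols["sequence"]], exc)
            continue
        hits.append(
            DeNovoHit(
                sequence=seq,
                alc=alc,
                feature_id=str(row[cols["feature_id"]]) if "feature_id" in cols else None,
                precursor_mz=float(row[cols["precursor_mz"]])
                if "precursor_mz" in cols
                else None,
                rt=float(row[cols["rt"]]) if "rt" in cols else None,
                modifications=mods,
            )
        )
    return hits


# --------------------------------------------------------------------------
# Annotations
# --------------------------------------------------------------------------

#: Provenance levels in increasing order of processing depth.
LEVELS = ("database", "denovo", "propagated", "revised", "deep_mined")


@dataclass
class Annotation:
    """A node-to-candidate assignment with its evidence and provenance."""

    node_id: str
    candidate: CDPCandidate | LinearPeptide
    level: str
    observed_mz: float
    rt: float | None = None
    evidence: object | None = None  # EvidenceScore, kept loose to avoid cycles
    isomer_tag: str | None = None
    #: display override, e.g. the merged "cyclo(Leu/Ile-Pro)" label
    display_name: str | None = None
    #: propagation path (seed node ... this node) or prior calls
    path: tuple[str, ...] = ()
    history: tuple[str, ...] = ()
    alternatives: tuple[object, ...] = ()

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown annotation level {self.level!r}")

    @property
    def name(self) -> str:
        return self.display_name or self.candidate.name

    @property
    def formula(self) -> ElementCounts:
        return self.candidate.formula

    @property
    def theoretical_mz(self) -> float:
        return self.candidate.precursor_mz

    @property
    def ppm_error(self) -> float:
        return (self.observed_mz - self.theoretical_mz) / self.theoretical_mz * 1e6

    @property
    def unnatural(self) -> bool:
        return self.candidate.unnatural

    def relabel(self, level: str) -> "Annotation":
        """Record a level transition, never silently overwriting."""
        self.history = self.history + (self.level,)
        self.level = level
        return self


REPORT_COLUMNS = [
    "name", "formula", "theoretical_mz", "observed_mz", "rt",
    "level", "evidence_count", "isomer_tag", "unnatural",
]


def annotations_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Tabulate annotations with deterministic (m/z, RT) row order."""
    rows = []
    for a in annotations:
        ev = a.evidence
        rows.append(
            {
                "name": a.name,
                "formula": a.formula.hill(),
                "theoretical_mz": round(a.theoretical_mz, 4),
                "observed_mz": round(a.observed_mz, 4),
                "rt": round(a.rt, 2) if a.rt is not None else np.nan,
                "level": a.level,
                "evidence_count": getattr(ev, "n_matched", 0),
                "isomer_tag": a.isomer_tag or "",
                "unnatural": a.unnatural,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(["observed_mz", "rt", "name"], na_position="last")
    return df.reset_index(drop=True)


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    """Write the annotation report as TSV (header always present)."""
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)
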