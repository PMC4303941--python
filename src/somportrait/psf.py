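"""Pathway Signal Flow (PSF) on KGML-subset pathway graphs.

A pathway is a directed graph of gene/protein nodes with activation or
inhibition edges. Each node carries a fold change (mean over its member
accessions; 1 = neutral for unmeasured nodes). The signal starts at source
nodes (in-degree 0) with their own fold change and propagates in
topological order: each parent contributes its signal multiplied by the
child's fold change across an activation edge, or divided by it across an
inhibition edge, and a multi-parent node takes the mean of its parents'
signed contributions (which keeps a neutral pathway — all fold changes
1 — at signal 1 everywhere). Sink signals over time form PSF profiles that
are matched against spot profiles by Pearson correlation.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PathwayGraph",
    "PsfResult",
    "parse_kgml",
    "read_edge_list",
    "node_fold_change",
    "compute_psf",
    "psf_time_profiles",
    "match_profiles",
]

logger = logging.getLogger(__name__)

# KGML relation subtypes mapped onto the two supported edge types; anything
# else (binding, indirect effect, ...) is dropped and counted.
_SUBTYPE_MAP = {
    "activation": "activation",
    "expression": "activation",
    "inhibition": "inhibition",
    "repression": "inhibition",
}


@dataclass
class PathwayGraph:
    """Signed directed acyclic pathway with member accessions per node."""

    name: str
    graph: nx.DiGraph  # edge attr "type" in {activation, inhibition}
    dropped_relations: int = 0
    removed_back_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("pathway graph must be acyclic after preprocessing")
        if not self.sinks:
            raise ValueError("pathway has no sink node")
        if not self.sources:
            raise ValueError("pathway has no source node")

    @property
    def sources(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.in_degree(n) == 0)

    @property
    def sinks(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.out_degree(n) == 0)

    def members(self, node: str) -> list[str]:
        return self.graph.nodes[node].get("members", [])


@dataclass
class PsfResult:
    pathway: str
    node_signals: dict[str, float]
    sink_signals: dict[str, float]


def _break_cycles(g: nx.DiGraph) -> list[tuple[str, str]]:
    """Remove back edges found by DFS in deterministic (sorted) node order."""
    removed: list[tuple[str, str]] = []
    color: dict[str, int] = {}  # 0 = unvisited, 1 = on stack, 2 = done

    def visit(u: str) -> None:
        color[u] = 1
        for v in sorted(g.successors(u)):
            if color.get(v, 0) == 0:
                visit(v)
            elif color.get(v) == 1:
                removed.append((u, v))
        color[u] = 2

    for n in sorted(g.nodes):
        if color.get(n, 0) == 0:
            visit(n)
    g.remove_edges_from(removed)
    return removed


def parse_kgml(path: str | Path) -> PathwayGraph:
    """Parse a KGML subset: gene entries plus activation/inhibition relations.

    Unsupported relation subtypes are dropped (counted), and cycles are
    broken by removing DFS back edges in deterministic node order.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed KGML XML: {exc}") from exc
    name = root.get("title") or root.get("name") or path.stem
    g = nx.DiGraph()
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            continue
        members = (entry.get("name") or "").split()
        g.add_node(eid, members=members)
    dropped = 0
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in g or e2 not in g:
            continue
        kinds = {
            _SUBTYPE_MAP.get((st.get("name") or "").lower())
            for st in rel.findall("subtype")
        }
        kinds.discard(None)
        if not kinds:
            dropped += 1
            continue
        # inhibition dominates a mixed-annotation relation
        etype = "inhibition" if "inhibition" in kinds else "activation"
        g.add_edge(e1, e2, type=etype)
    removed = _break_cycles(g)
    if removed:
        logger.info("%s: removed %d back edge(s) to break cycles", name, len(removed))
    if dropped:
        logger.info("%s: dropped %d unsupported relation(s)", name, dropped)
    return PathwayGraph(name=name, graph=g, dropped_relations=dropped, removed_back_edges=removed)


def read_edge_list(path: str | Path, *, name: str | None = None) -> PathwayGraph:
    """Toy pathway as TSV lines: source <tab> target <tab> activation|inhibition."""
    path = Path(path)
    g = nx.DiGraph()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[2] not in ("activation", "inhibition"):
            raise ValueError(f"{path}: line {lineno}: expected 'src\\tdst\\ttype'")
        src, dst, etype = parts
        for n in (src, dst):
            if n not in g:
                g.add_node(n, members=[n])
        g.add_edge(src, dst, type=etype)
    removed = _break_cycles(g)
    return PathwayGraph(name=name or path.stem, graph=g, removed_back_edges=removed)


def node_fold_change(
    pathway: PathwayGraph, fold_changes: Mapping[str, float]
) -> dict[str, float]:
    """Per-node fold change: mean over measured members, neutral 1 otherwise."""
    for acc, fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change of {acc!r} must be positive, got {fc}")
    out: dict[str, float] = {}
    for node in pathway.graph.nodes:
        vals = [fold_changes[m] for m in pathway.members(node) if m in fold_changes]
        out[node] = float(np.mean(vals)) if vals else 1.0
    return out


def compute_psf(pathway: PathwayGraph, node_fc: Mapping[str, float]) -> PsfResult:
    """Propagate signal from sources to sinks through the signed DAG."""
    g = pathway.graph
    for node, fc in node_fc.items():
        if fc <= 0:
            raise ValueError(f"node {node!r} has nonpositive fold change {fc}")
    signals: dict[str, float] = {}
    for node in nx.topological_sort(g):
        fc = float(node_fc.get(node, 1.0))
        parents = list(g.predecessors(node))
        if not parents:
            signals[node] = fc
            continue
        contributions = []
        for p in parents:
            etype = g.edges[p, node]["type"]
            s = signals[p]
            contributions.append(s * fc if etype == "activation" else s / fc)
        signals[node] = float(np.mean(contributions))
    return PsfResult(
        pathway=pathway.name,
        node_signals=signals,
        sink_signals={s: signals[s] for s in pathway.sinks},
    )


def psf_time_profiles(
    pathway: PathwayGraph,
    abundance: pd.DataFrame,
    *,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Per-sink PSF profiles over time.

    ``abundance`` is proteins x time points; the fold change of protein p at
    time t is (abundance + eps) / (row mean + eps), the pseudocount
    guarding against the zeros of presence/absence-derived fractions.
    """
    row_mean = abundance.mean(axis=1)
    sink_profiles: dict[str, list[float]] = {s: [] for s in pathway.sinks}
    for col in abundance.columns:
        fc = ((abundance[col] + epsilon) / (row_mean + epsilon)).to_dict()
        node_fc = node_fold_change(pathway, fc)
        res = compute_psf(pathway, node_fc)
        for s in pathway.sinks:
            sink_profiles[s].append(res.sink_signals[s])
    return pd.DataFrame(sink_profiles, index=abundance.columns).T


def match_profiles(
    psf_profiles: pd.DataFrame, spot_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r for every (sink, spot) profile pair, with best match per sink.

    Zero-variance profiles cannot be correlated; their pairs are skipped and
    flagged with NaN. Returns a tidy frame (sink, spot, r, best).
    """
    if list(psf_profiles.columns) != list(spot_profiles.columns):
        raise ValueError("PSF and spot profiles must share the same time grid")
    rows = []
    for sink, sp in psf_profiles.iterrows():
        rs: dict[str, float] = {}
        for spot, pp in spot_profiles.iterrows():
            if sp.std() < 1e-12 or pp.std() < 1e-12:
                rs[spot] = math.nan
            else:
                rs[spot] = float(np.corrcoef(sp.values, pp.values)[0, 1])
        finite = {k: v for k, v in rs.items() if not math.isnan(v)}
        best = max(finite, key=finite.get) if finite else None
        for spot, r in rs.items():
            rows.append({"sink": sink, "spot": spot, "r": r, "best": spot == best})
    return pd.DataFrame(rows)
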