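"""Spot-module segmentation of the trained map.

Spots are connected regions of grid nodes (8-neighborhood adjacency, so
diagonally touching selections merge) whose member proteins are treated as
one co-expression module. Three selection methods are provided: extreme
2-percentile over-/under-expression selection (the default marker-oriented
method, either on the state-averaged landscape or as the union of
per-sample selections), correlation grouping around seed nodes, and
K-means clustering of the meta-feature profiles.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .io import StudyDesign
from .som import SomModel

__all__ = [
    "SpotModule",
    "SummaryMap",
    "select_percentile_spots",
    "select_correlation_spots",
    "select_kmeans_spots",
    "spot_profile",
    "classify_spot_phase",
    "build_summary_map",
    "connected_components",
]

# 8-neighborhood: diagonal contact merges spots
_ADJACENCY = np.ones((3, 3), dtype=int)


@dataclass
class SpotModule:
    id: str  # capital letter, assigned by decreasing member count
    method: Literal["overexpression", "underexpression", "correlation", "kmeans"]
    polarity: Literal["over", "under", "none"]
    nodes: frozenset[int]
    members: list[str]  # proteins assigned to the spot's nodes
    mean_profile: np.ndarray  # mean of member meta-feature profiles (dE units)
    phase_week: int  # argmax week of the mean profile
    max_min_lag: int  # weeks from profile maximum to minimum

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class SummaryMap:
    """Per-node over/under flags aggregated across all samples.

    A node selected in both channels across different samples is resolved
    by majority of sample hits; exact ties are flagged neither.
    """

    rows: int
    cols: int
    over: np.ndarray  # (K,) bool
    under: np.ndarray  # (K,) bool

    def flags(self) -> np.ndarray:
        out = np.full(self.rows * self.cols, "none", dtype=object)
        out[self.over] = "over"
        out[self.under] = "under"
        return out.reshape(self.rows, self.cols)


def connected_components(mask: np.ndarray, rows: int, cols: int) -> list[frozenset[int]]:
    """Connected components of a flat node mask under 8-neighborhood."""
    grid = np.asarray(mask, dtype=bool).reshape(rows, cols)
    labels, n = ndimage.label(grid, structure=_ADJACENCY)
    flat = labels.ravel()
    return [frozenset(np.flatnonzero(flat == lab).tolist()) for lab in range(1, n + 1)]


def _spot_letter(i: int) -> str:
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


def _node_members(model: SomModel) -> dict[int, list[str]]:
    return model.node_proteins()


def _make_spots(
    components: Sequence[frozenset[int]],
    model: SomModel,
    method: str,
    polarity: str,
) -> list[SpotModule]:
    node_members = _node_members(model)
    raw = []
    for nodes in components:
        members = sorted(m for n in nodes for m in node_members.get(n, []))
        profile = model.meta[sorted(nodes), :].mean(axis=0)
        weeks = np.asarray(model.time_points)
        phase = int(weeks[int(np.argmax(profile))])
        lag = int(weeks[int(np.argmin(profile))]) - phase
        raw.append((nodes, members, profile, phase, lag))
    # letters by decreasing membership; ties by node count then lowest node id
    raw.sort(key=lambda r: (-len(r[1]), -len(r[0]), min(r[0])))
    return [
        SpotModule(
            id=_spot_letter(i),
            method=method,  # type: ignore[arg-type]
            polarity=polarity,  # type: ignore[arg-type]
            nodes=nodes,
            members=members,
            mean_profile=profile,
            phase_week=phase,
            max_min_lag=lag,
        )
        for i, (nodes, members, profile, phase, lag) in enumerate(raw)
    ]


def _percentile_mask(values: np.ndarray, count: int, top: bool) -> np.ndarray:
    """Select the `count` largest (or smallest) entries, ties at cutoff included."""
    order = np.sort(values)
    cutoff = order[-count] if top else order[count - 1]
    return values >= cutoff if top else values <= cutoff


def percentile_masks(
    model: SomModel, mode: str = "per-sample-union", percentile: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Over/under node masks for the extreme-percentile selection."""
    if not 0.0 < percentile < 50.0:
        raise ValueError("percentile must lie in (0, 50)")
    K = model.n_nodes
    count = int(np.ceil(K * percentile / 100.0))
    if mode == "averaged":
        landscape = model.meta.mean(axis=1)
        over = _percentile_mask(landscape, count, top=True)
        under = _percentile_mask(landscape, count, top=False)
    elif mode == "per-sample-union":
        over = np.zeros(K, dtype=bool)
        under = np.zeros(K, dtype=bool)
        for t in range(model.n_time_points):
            vals = model.meta[:, t]
            over |= _percentile_mask(vals, count, top=True)
            under |= _percentile_mask(vals, count, top=False)
    else:
        raise ValueError(f"unknown spot mode {mode!r}")
    return over, under


def select_percentile_spots(
    model: SomModel,
    mode: Literal["averaged", "per-sample-union"] = "per-sample-union",
    percentile: float = 2.0,
) -> list[SpotModule]:
    """Extreme-percentile over- and under-expression spots.

    Selects the top and bottom ``percentile`` of meta-feature values (per
    state-averaged landscape, or unioned over per-sample selections) and
    segments each selection into grid-connected spots.
    """
    over_mask, under_mask = percentile_masks(model, mode, percentile)
    rows, cols = model.params.rows, model.params.cols
    spots = _make_spots(
        connected_components(over_mask, rows, cols), model, "overexpression", "over"
    )
    spots += _make_spots(
        connected_components(under_mask, rows, cols), model, "underexpression", "under"
    )
    return spots


def build_summary_map(
    model: SomModel, percentile: float = 2.0
) -> SummaryMap:
    """Aggregate per-sample extreme selections into one master map."""
    if not 0.0 < percentile < 50.0:
        raise ValueError("percentile must lie in (0, 50)")
    K = model.n_nodes
    count = int(np.ceil(K * percentile / 100.0))
    over_hits = np.zeros(K, dtype=int)
    under_hits = np.zeros(K, dtype=int)
    for t in range(model.n_time_points):
        vals = model.meta[:, t]
        over_hits += _percentile_mask(vals, count, top=True)
        under_hits += _percentile_mask(vals, count, top=False)
    over = over_hits > under_hits
    under = under_hits > over_hits
    return SummaryMap(rows=model.params.rows, cols=model.params.cols, over=over, under=under)


def _profile_correlations(meta: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations; zero-variance profiles correlate 0,
    except with bit-identical profiles (r := 1) so duplicates always group."""
    sd = meta.std(axis=1)
    Z = np.zeros_like(meta)
    ok = sd > 1e-12
    Z[ok] = (meta[ok] - meta[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    R = Z @ Z.T / meta.shape[1]
    # identical profiles (including constant ones) are perfectly grouped
    same = np.isclose(meta[:, None, :], meta[None, :, :], atol=1e-12).all(axis=2)
    R[same] = 1.0
    return np.clip(R, -1.0, 1.0)


def select_correlation_spots(model: SomModel, threshold: float = 0.9) -> list[SpotModule]:
    """Group nodes correlating with a seed node, then segment on the grid.

    Seeds are picked greedily: the yet-ungrouped node with the largest
    profile variance recruits every ungrouped node with Pearson r >=
    threshold; each recruited group is split into grid-connected spots.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("correlation threshold must lie in (0, 1]")
    R = _profile_correlations(model.meta)
    variance = model.meta.var(axis=1)
    K = model.n_nodes
    unassigned = np.ones(K, dtype=bool)
    components: list[frozenset[int]] = []
    rows, cols = model.params.rows, model.params.cols
    while unassigned.any():
        candidates = np.flatnonzero(unassigned)
        seed = candidates[np.argmax(variance[candidates])]
        group = unassigned & (R[seed] >= threshold)
        group[seed] = True
        components.extend(connected_components(group, rows, cols))
        unassigned &= ~group
    return _make_spots(components, model, "correlation", "none")


def select_kmeans_spots(model: SomModel, k: int, seed: int = 0) -> list[SpotModule]:
    """K-means clustering of the meta profiles, split into grid components."""
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    if k > model.n_nodes:
        raise ValueError("k cannot exceed the number of map nodes")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(model.meta)
    components: list[frozenset[int]] = []
    rows, cols = model.params.rows, model.params.cols
    for lab in range(k):
        components.extend(connected_components(labels == lab, rows, cols))
    return _make_spots(components, model, "kmeans", "none")


def spot_profile(spot: SpotModule, model: SomModel) -> tuple[np.ndarray, int, int]:
    """Mean dE profile over the spot's meta-features, with phase and lag.

    Returns (profile, phase_week = argmax week, lag = weeks from maximum to
    minimum).
    """
    if not spot.nodes:
        raise ValueError("spot has no nodes")
    profile = model.meta[sorted(spot.nodes), :].mean(axis=0)
    weeks = np.asarray(model.time_points)
    phase = int(weeks[int(np.argmax(profile))])
    lag = int(weeks[int(np.argmin(profile))]) - phase
    return profile, phase, lag


def classify_spot_phase(spot: SpotModule, design: StudyDesign) -> str:
    """Reference phase (early/intermediate/late) containing the profile maximum.

    Pre-isolation maxima classify early and post-isolation maxima late, per
    the reference phase boundaries in the design.
    """
    return design.phase_of(spot.phase_week)
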