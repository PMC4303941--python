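"""Batch self-organizing map for protein expression portraits.

Protein time profiles are distributed over a 40x40 quadratic grid of
"meta-features" (K = 1600 prototype profiles) by Euclidean nearest-prototype
assignment; batch training with a shrinking Gaussian neighborhood then
adjusts the prototypes so that the map self-organizes — proteins with
similar profiles land on nearby grid nodes. One time point's K meta-feature
values rendered on the grid form that sample's abundance portrait.

Training is batch-mode (no presentation-order nondeterminism) with a
linearly decaying neighborhood radius; initialization is either a linear
span of the first two principal components of the data (default,
deterministic) or seeded random rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import AbundanceMatrix, DifferentialMatrix

__all__ = [
    "SomParams",
    "SomModel",
    "Portrait",
    "train_som",
    "render_portrait",
    "population_map",
    "variance_profile",
    "detect_peaks",
    "save_model",
    "load_model",
]


@dataclass
class SomParams:
    rows: int = 40
    cols: int = 40
    epochs: int = 100
    radius_initial: float = 20.0
    radius_final: float = 1.0
    learning_rate_initial: float = 0.1  # kept for API symmetry; batch mode ignores it
    learning_rate_final: float = 0.01
    init_mode: Literal["pca-plane", "random"] = "pca-plane"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have positive dimensions")
        if self.radius_initial < self.radius_final:
            raise ValueError("radius schedule must be non-increasing")
        if self.learning_rate_initial < self.learning_rate_final:
            raise ValueError("learning-rate schedule must be non-increasing")
        if self.epochs < 1:
            raise ValueError("need at least one training epoch")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


@dataclass
class SomModel:
    """Trained map: K x M meta-feature matrix plus protein assignments."""

    params: SomParams
    meta: np.ndarray  # (K, M) prototype profiles
    assignment: np.ndarray  # (N,) node index per protein, row-major 0-based
    protein_ids: list[str]
    time_points: list[int]
    quantization_error_initial: float
    quantization_error: float
    data_kind: Literal["absolute", "differential"] = "differential"

    @property
    def n_nodes(self) -> int:
        return self.meta.shape[0]

    @property
    def n_time_points(self) -> int:
        return self.meta.shape[1]

    def node_position(self, node: int | np.ndarray) -> np.ndarray:
        """(row, col) grid position of a node index."""
        node = np.asarray(node)
        return np.stack([node // self.params.cols, node % self.params.cols], axis=-1)

    def grid_distance(self, a: int, b: int) -> float:
        pa, pb = self.node_position(a), self.node_position(b)
        return float(np.linalg.norm(pa - pb))

    def node_proteins(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, node in zip(self.protein_ids, self.assignment):
            out.setdefault(int(node), []).append(pid)
        return out


@dataclass
class Portrait:
    sample: int  # time index
    week: int
    values: np.ndarray  # (K,)
    symmetric: bool  # color scale symmetric about zero (differential data)


def _grid_positions(rows: int, cols: int) -> np.ndarray:
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([r.ravel(), c.ravel()]).astype(float)


def _init_meta(X: np.ndarray, params: SomParams) -> np.ndarray:
    K = params.n_nodes
    if params.init_mode == "random":
        rng = np.random.default_rng(params.seed)
        idx = rng.integers(0, X.shape[0], size=K)
        return X[idx].copy()
    # linear initialization on the plane of the first two principal components
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic SVD; sign fixed so the largest-magnitude loading is positive
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = vt[:2] if vt.shape[0] >= 2 else np.vstack([vt, np.zeros((2 - vt.shape[0], X.shape[1]))])
    for i in range(pcs.shape[0]):
        j = np.argmax(np.abs(pcs[i]))
        if pcs[i, j] < 0:
            pcs[i] *= -1
    sd = np.zeros(2)
    sd[: min(2, len(s))] = s[:2] / max(np.sqrt(X.shape[0] - 1), 1.0)
    u = np.linspace(-2.0, 2.0, params.rows)
    v = np.linspace(-2.0, 2.0, params.cols)
    U, V = np.meshgrid(u, v, indexing="ij")
    W = (
        mean[None, :]
        + (U.ravel()[:, None] * sd[0]) * pcs[0][None, :]
        + (V.ravel()[:, None] * sd[1]) * pcs[1][None, :]
    )
    return W


def _bmu(X: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching unit per row of X; ties broken by lowest node index."""
    # squared Euclidean distances via the expansion trick
    d2 = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ W.T
        + np.einsum("ij,ij->i", W, W)[None, :]
    )
    bmu = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    qe = np.sqrt(np.maximum(d2[np.arange(X.shape[0]), bmu], 0.0))
    return bmu, qe


def train_som(
    data: DifferentialMatrix | AbundanceMatrix | np.ndarray,
    params: SomParams | None = None,
    *,
    protein_ids: Sequence[str] | None = None,
    time_points: Sequence[int] | None = None,
) -> SomModel:
    """Train the map on protein profiles (rows) over time points (columns)."""
    if params is None:
        params = SomParams()
    if isinstance(data, (DifferentialMatrix, AbundanceMatrix)):
        X = np.asarray(data.values, dtype=float)
        protein_ids = list(data.protein_ids)
        time_points = list(data.time_points)
        kind = "differential" if isinstance(data, DifferentialMatrix) else "absolute"
    else:
        X = np.asarray(data, dtype=float)
        kind = "differential"
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two time points")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("all-NaN protein profiles are not allowed")
    N, M = X.shape
    K = params.n_nodes
    if N < K:
        warnings.warn(
            f"fewer proteins ({N}) than map nodes ({K}); many nodes will stay empty",
            stacklevel=2,
        )
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(N)]
    if time_points is None:
        time_points = list(range(M))

    pos = _grid_positions(params.rows, params.cols)
    grid_d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)

    W = _init_meta(X, params)
    _, qe0 = _bmu(X, W)
    qe_initial = float(qe0.mean())

    for epoch in range(params.epochs):
        frac = epoch / max(params.epochs - 1, 1)
        sigma = params.radius_initial + frac * (params.radius_final - params.radius_initial)
        bmu, _ = _bmu(X, W)
        sums = np.zeros((K, M))
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=K).astype(float)
        if sigma > 1e-9:
            H = np.exp(-grid_d2 / (2.0 * sigma * sigma))
            numer = H @ sums
            denom = H @ counts
        else:  # degenerate limit: plain Lloyd/K-means update
            numer, denom = sums, counts
        nonzero = denom > 1e-12
        W = np.where(nonzero[:, None], numer / np.maximum(denom, 1e-12)[:, None], W)

    bmu, qe = _bmu(X, W)
    return SomModel(
        params=params,
        meta=W,
        assignment=bmu,
        protein_ids=list(protein_ids),
        time_points=list(time_points),
        quantization_error_initial=qe_initial,
        quantization_error=float(qe.mean()),
        data_kind=kind,
    )


def render_portrait(
    model: SomModel, sample: int, *, path: str | Path | None = None
) -> Portrait:
    """Meta-feature landscape of one time point (red = over, blue = under)."""
    if not 0 <= sample < model.n_time_points:
        raise IndexError(f"sample index {sample} out of range (M = {model.n_time_points})")
    values = model.meta[:, sample].copy()
    symmetric = model.data_kind == "differential"
    portrait = Portrait(
        sample=sample, week=model.time_points[sample], values=values, symmetric=symmetric
    )
    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        grid = values.reshape(model.params.rows, model.params.cols)
        if symmetric:
            lim = max(np.abs(values).max(), 1e-12)
            vmin, vmax = -lim, lim
        else:
            vmin, vmax = values.min(), values.max()
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(grid, cmap="RdBu_r" if symmetric else "jet", vmin=vmin, vmax=vmax)
        ax.set_title(f"week {portrait.week}")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return portrait


def population_map(model: SomModel) -> np.ndarray:
    """Per-node protein counts, shaped (rows, cols); sums to N."""
    counts = np.bincount(model.assignment, minlength=model.n_nodes)
    return counts.reshape(model.params.rows, model.params.cols)


def variance_profile(model: SomModel) -> np.ndarray:
    """Variance over the K meta-feature values at each time point.

    On a map trained with non-centralized (absolute) abundances this tracks
    the mean squared amplitude of overall abundance over time; on
    centralized data the profile is still computed but a warning is raised
    because the absolute level has been removed.
    """
    if model.data_kind == "differential":
        warnings.warn(
            "variance profile requested on a centralized model; absolute "
            "abundance level is not recoverable",
            stacklevel=2,
        )
    return model.meta.var(axis=0)


def detect_peaks(
    profile: Sequence[float] | np.ndarray,
    min_separation: int = 1,
    weeks: Sequence[int] | None = None,
) -> list[int]:
    """Local maxima exceeding both neighbors, greedily thinned.

    Peaks are kept highest-first; any candidate within ``min_separation``
    (in week units) of an already-kept peak is dropped. Returns week labels
    if given, else profile indices.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile must have at least 3 points")
    idx = [i for i in range(1, y.size - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
    idx.sort(key=lambda i: -y[i])
    w = np.asarray(weeks if weeks is not None else np.arange(y.size))
    kept: list[int] = []
    for i in idx:
        if all(abs(int(w[i]) - int(w[j])) > min_separation for j in kept):
            kept.append(i)
    kept.sort()
    return [int(w[i]) for i in kept]


def save_model(model: SomModel, path: str | Path) -> None:
    """Serialize to a single .npz archive with a JSON header."""
    header = {
        "params": {
            k: getattr(model.params, k)
            for k in (
                "rows", "cols", "epochs", "radius_initial", "radius_final",
                "learning_rate_initial", "learning_rate_final", "init_mode", "seed",
            )
        },
        "protein_ids": model.protein_ids,
        "time_points": model.time_points,
        "quantization_error_initial": model.quantization_error_initial,
        "quantization_error": model.quantization_error,
        "data_kind": model.data_kind,
    }
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        meta=model.meta,
        assignment=model.assignment,
    )


def load_model(path: str | Path) -> SomModel:
    with np.load(path) as npz:
        header = json.loads(npz["header"].tobytes().decode())
        return SomModel(
            params=SomParams(**header["params"]),
            meta=npz["meta"],
            assignment=npz["assignment"],
            protein_ids=header["protein_ids"],
            time_points=header["time_points"],
            quantization_error_initial=header["quantization_error_initial"],
            quantization_error=header["quantization_error"],
            data_kind=header["data_kind"],
        )
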