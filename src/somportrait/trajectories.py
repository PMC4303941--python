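"""Sample similarity projections and time-trajectory segmentation.

Each sample (time point) is represented by its portrait — the K
meta-feature values of the trained map — and projected into a 2-D
similarity space either with a small second-level SOM trained on the
sample state vectors, or with fast fixed-point ICA. Successive time points
traced through that space form the sample trajectory, which is segmented
into early/intermediate/late phases by clustering and compared against the
reference phase labels of the study design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import StudyDesign
from .som import SomModel, SomParams, train_som

__all__ = [
    "Trajectory",
    "sample_states",
    "second_level_som",
    "ica_projection",
    "segment_trajectory",
    "joint_trajectories",
]


@dataclass
class Trajectory:
    coords: np.ndarray  # (n_samples, 2)
    weeks: list[int]  # temporal order of the samples
    method: Literal["som2", "ica"]
    labels: list[str] | None = None  # phase segmentation, filled by segment_trajectory
    volunteer_ids: list[str] | None = None  # for jointly projected per-volunteer samples

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


def sample_states(model: SomModel) -> np.ndarray:
    """Sample state vectors: one row of K meta-feature values per time point."""
    return model.meta.T.copy()


def second_level_som(
    states: np.ndarray,
    weeks: Sequence[int],
    *,
    rows: int = 10,
    cols: int = 10,
    epochs: int = 60,
    seed: int = 0,
) -> Trajectory:
    """Project samples onto a small SOM trained over their state vectors.

    Each sample's coordinate is the grid position of its best-matching node;
    identical samples therefore share coordinates exactly.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 samples for a similarity projection")
    params = SomParams(
        rows=rows,
        cols=cols,
        epochs=epochs,
        radius_initial=max(rows, cols) / 2.0,
        radius_final=0.5,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n_samples << grid nodes is expected here
        model = train_som(states, params, time_points=list(range(states.shape[1])))
    coords = model.node_position(model.assignment).astype(float)
    return Trajectory(coords=coords, weeks=list(weeks), method="som2")


def ica_projection(
    states: np.ndarray,
    weeks: Sequence[int],
    *,
    n_components: int = 2,
    seed: int = 0,
    max_iter: int = 500,
) -> Trajectory:
    """Whitened fast fixed-point ICA of the sample state vectors.

    Components are sign-fixed so their first non-negligible score is
    positive, making the projection reproducible per seed.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    states = np.asarray(states, dtype=float)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 samples for a similarity projection")
    if n_components > min(states.shape):
        raise ValueError("n_components exceeds the data rank bound")
    if np.allclose(states.std(axis=0), 0.0):
        raise ValueError("degenerate input: all samples are identical")
    ica = FastICA(
        n_components=n_components, random_state=seed, max_iter=max_iter, whiten="unit-variance"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            scores = ica.fit_transform(states)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"ICA did not converge within {max_iter} iterations"
            ) from exc
    for c in range(scores.shape[1]):
        nz = np.flatnonzero(np.abs(scores[:, c]) > 1e-9)
        if nz.size and scores[nz[0], c] < 0:
            scores[:, c] *= -1
    return Trajectory(coords=scores, weeks=list(weeks), method="ica")


_PHASE_NAMES = {3: ["early", "intermediate", "late"]}


def segment_trajectory(
    traj: Trajectory,
    design: StudyDesign | None = None,
    k: int = 3,
    seed: int = 0,
) -> tuple[list[str], float | None]:
    """Cluster trajectory coordinates into k temporal segments.

    Clusters are ordered by their median sample week and named
    early/intermediate/late for k = 3 (generic ordered names otherwise).
    If a study design is given, the adjusted Rand index against its
    reference phase labels is reported as well.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    if k < 2:
        raise ValueError("k must be >= 2")
    if k > traj.n_samples:
        raise ValueError("more segments than samples")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(traj.coords)
    weeks = np.asarray(traj.weeks, dtype=float)
    order = sorted(range(k), key=lambda c: np.median(weeks[raw == c]))
    names = _PHASE_NAMES.get(k, [f"segment{i + 1}" for i in range(k)])
    rename = {cluster: names[rank] for rank, cluster in enumerate(order)}
    labels = [rename[c] for c in raw]
    traj.labels = labels
    ari = None
    if design is not None:
        reference = [design.phase_of(int(w)) for w in traj.weeks]
        ari = float(adjusted_rand_score(reference, labels))
    return labels, ari


def joint_trajectories(
    states_by_volunteer: dict[str, np.ndarray],
    weeks_by_volunteer: dict[str, Sequence[int]],
    *,
    rows: int = 10,
    cols: int = 10,
    seed: int = 0,
) -> dict[str, Trajectory]:
    """Per-volunteer trajectories on one shared second-level SOM frame.

    The projection is trained with the pooled samples of all volunteers so
    the coordinate frames are directly comparable.
    """
    ids = sorted(states_by_volunteer)
    pooled = np.vstack([states_by_volunteer[v] for v in ids])
    pooled_weeks = [w for v in ids for w in weeks_by_volunteer[v]]
    joint = second_level_som(pooled, pooled_weeks, rows=rows, cols=cols, seed=seed)
    out: dict[str, Trajectory] = {}
    offset = 0
    for v in ids:
        n = states_by_volunteer[v].shape[0]
        out[v] = Trajectory(
            coords=joint.coords[offset : offset + n],
            weeks=list(weeks_by_volunteer[v]),
            method="som2",
            volunteer_ids=[v] * n,
        )
        offset += n
    return out
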