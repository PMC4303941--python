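"""Spot-spot co-expression statistics: wTO networks and the beta test.

The weighted topological overlap (wTO) scores node pairs not only by their
direct Pearson correlation but also by correlations mediated via every
third node of the map, in the Ravasz / Zhang-Horvath form

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with one-sided adjacencies a_ij = max(r_ij, 0) (positive channel) or
max(-r_ij, 0) (negative channel) and connectivities k_i = sum_u a_iu.
Spot-level edges aggregate omega over cross-spot node pairs.

The beta test scores the co-expression coherence of a spot's m
meta-feature profiles x_i with mean profile c:

    beta = (sum_i r(c, x_i))^2 / (sum_i sum_j r(x_i, x_j))

where the double sum runs over all ordered pairs including i = j, so that
a perfectly coherent (or singleton) module attains beta = 1 exactly.
Significance comes from a permutation null (member profiles resampled from
the whole map); an analytic Beta-distribution fit to that null is offered
as a cheaper alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .spots import SpotModule

__all__ = [
    "WtoEdge",
    "BetaResult",
    "wto_scores",
    "spot_wto_network",
    "beta_statistic",
    "beta_test",
    "beta_test_all",
]


@dataclass
class WtoEdge:
    spot_i: str
    spot_j: str
    channel: Literal["positive", "negative"]
    score: float


@dataclass
class BetaResult:
    spot_id: str
    beta: float
    p_value: float
    p_adjusted: float | None
    null_method: Literal["permutation", "analytic"]
    n_members: int


def _correlations(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r; zero-variance profiles correlate 0 with everything
    (and with themselves, so they contribute nothing to either channel)."""
    X = np.asarray(profiles, dtype=float)
    sd = X.std(axis=1)
    Z = np.zeros_like(X)
    ok = sd > 1e-12
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    R = Z @ Z.T / X.shape[1]
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, np.where(ok, 1.0, 0.0))
    return R


def wto_scores(
    profiles: np.ndarray, sign: Literal["positive", "negative"] = "positive"
) -> np.ndarray:
    """Weighted topological overlap matrix for one correlation channel."""
    R = _correlations(profiles)
    if sign == "positive":
        A = np.maximum(R, 0.0)
    elif sign == "negative":
        A = np.maximum(-R, 0.0)
    else:
        raise ValueError(f"unknown channel {sign!r}")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # mediated correlation mass; zero diagonal of A drops u = i, j terms
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (L + A) / denom
    omega[~np.isfinite(omega)] = 0.0
    np.fill_diagonal(omega, 0.0)
    return np.clip(omega, 0.0, 1.0)


def spot_wto_network(
    spots: Sequence[SpotModule],
    node_scores: np.ndarray,
    channel: Literal["positive", "negative"],
    threshold: float = 0.1,
) -> list[WtoEdge]:
    """Spot-pair edges: mean omega over cross-spot node pairs above threshold."""
    for i, a in enumerate(spots):
        for b in spots[i + 1 :]:
            if a.polarity == b.polarity and a.nodes & b.nodes:
                raise ValueError(
                    f"spots {a.id} and {b.id} overlap within polarity {a.polarity!r}"
                )
    edges: list[WtoEdge] = []
    for i, a in enumerate(spots):
        ia = sorted(a.nodes)
        for b in spots[i + 1 :]:
            ib = sorted(b.nodes)
            score = float(node_scores[np.ix_(ia, ib)].mean())
            if score >= threshold:
                edges.append(WtoEdge(spot_i=a.id, spot_j=b.id, channel=channel, score=score))
    return edges


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=-1, keepdims=True)
    mu = X.mean(axis=-1, keepdims=True)
    Z = np.where(sd > 1e-12, (X - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return Z


def beta_statistic(profiles: np.ndarray) -> float:
    """Coherence statistic beta of a set of profiles (rows)."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one member profile")
    M = X.shape[1]
    Z = _standardize(X)
    zsum = Z.sum(axis=0)
    denom = float(zsum @ zsum) / M  # = sum_ij r(x_i, x_j), always >= 0
    cbar = _standardize(X.mean(axis=0)[None, :])[0]
    numer = float(cbar @ zsum) / M  # = sum_i r(c, x_i)
    if denom <= 1e-12:
        return 0.0
    return numer**2 / denom


def _null_betas(
    meta: np.ndarray, m: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized beta under the null: m profiles resampled from the map."""
    K, M = meta.shape
    # m distinct node indices per permutation, vectorized over permutations
    idx = np.argpartition(rng.random((n_permutations, K)), m, axis=1)[:, :m]
    Z = _standardize(meta)
    Zsum = Z[idx].sum(axis=1)  # (P, M)
    denom = np.einsum("pm,pm->p", Zsum, Zsum) / M
    cbar = _standardize(meta[idx].mean(axis=1))
    numer = np.einsum("pm,pm->p", cbar, Zsum) / M
    with np.errstate(invalid="ignore", divide="ignore"):
        betas = np.where(denom > 1e-12, numer**2 / denom, 0.0)
    return betas


def beta_test(
    spot: SpotModule | Sequence[int],
    meta: np.ndarray,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    null: Literal["permutation", "analytic"] = "permutation",
) -> BetaResult:
    """Beta coherence test of one spot against a map-resampling null.

    The permutation p-value uses the add-one estimator
    p = (1 + #{beta_null >= beta}) / (n_permutations + 1). The analytic
    option fits a Beta distribution (method of moments) to the same null
    sample of beta/m values and reads the tail probability from it; it is
    an approximation validated only against the permutation path.
    """
    if isinstance(spot, SpotModule):
        nodes = sorted(spot.nodes)
        spot_id = spot.id
    else:
        nodes = sorted(spot)
        spot_id = "?"
    if not nodes:
        raise ValueError("spot has no member meta-features")
    meta = np.asarray(meta, dtype=float)
    m = len(nodes)
    beta = beta_statistic(meta[nodes])
    rng = np.random.default_rng(seed)
    if m == 1:
        # singleton: beta = 1 by construction, the null is degenerate
        return BetaResult(spot_id, beta, 1.0, None, null, m)
    null_betas = _null_betas(meta, m, n_permutations, rng)
    if null == "permutation":
        p = (1.0 + float(np.sum(null_betas >= beta))) / (n_permutations + 1.0)
    else:
        x = np.clip(null_betas / m, 1e-9, 1.0 - 1e-9)
        mu, var = float(x.mean()), float(x.var())
        var = max(var, 1e-12)
        common = mu * (1.0 - mu) / var - 1.0
        a, b = max(mu * common, 1e-6), max((1.0 - mu) * common, 1e-6)
        p = float(stats.beta.sf(np.clip(beta / m, 0.0, 1.0), a, b))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    return BetaResult(spot_id, beta, p, None, null, m)


def beta_test_all(
    spots: Sequence[SpotModule],
    meta: np.ndarray,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    null: Literal["permutation", "analytic"] = "permutation",
) -> list[BetaResult]:
    """Beta test every spot, Benjamini-Hochberg adjusted across spots."""
    from statsmodels.stats.multitest import multipletests

    results = [
        beta_test(s, meta, n_permutations=n_permutations, seed=seed + i, null=null)
        for i, s in enumerate(spots)
    ]
    if results:
        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
    return results
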