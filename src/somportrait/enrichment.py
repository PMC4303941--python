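"""Gene-set function mining for spot modules.

Overlap significance uses the one-sided Fisher exact (hypergeometric
upper-tail) test over the universe of proteins entering the SOM. The GSZ
score additionally rewards the degree of overexpression of set members in
the spot: it combines the hypergeometric z-score of the overlap with the
z-score of the members' mean differential abundance, variance-stabilized
as (z_overlap + w * z_dE) / sqrt(1 + w^2) with equal weight w = 1 by
default. Tissue (or any) gene sets can also be mapped onto the grid as
smoothed member-density landscapes, and summarized as mean abundance
profiles over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import AbundanceMatrix, DifferentialMatrix, GeneSetCollection
from .som import SomModel
from .spots import SpotModule

__all__ = [
    "EnrichmentResult",
    "DensityMap",
    "fisher_enrichment",
    "gsz_score",
    "enrich_spots",
    "tissue_density_map",
    "set_profile",
    "enrichment_heatmap",
]


@dataclass
class EnrichmentResult:
    spot_id: str
    set_name: str
    overlap: int
    n_universe: int
    n_set: int
    n_spot: int
    fisher_p: float
    gsz: float | None = None
    p_adjusted: float | None = None


@dataclass
class DensityMap:
    set_name: str
    density: np.ndarray  # (rows, cols), >= 0, integrates to mapped set size
    regions: list[frozenset[int]]  # connected nodes above the 90th percentile


def fisher_enrichment(
    spot_members: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    *,
    spot_id: str = "?",
    set_name: str = "?",
) -> EnrichmentResult:
    """Hypergeometric upper-tail p of the spot/set overlap in the universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    members = set(spot_members) & uni
    gset = set(gene_set) & uni
    k = len(members & gset)
    N, n_set, n_spot = len(uni), len(gset), len(members)
    if n_set == 0 or n_spot == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, N, n_set, n_spot))
    return EnrichmentResult(
        spot_id=spot_id, set_name=set_name, overlap=k,
        n_universe=N, n_set=n_set, n_spot=n_spot, fisher_p=min(p, 1.0),
    )


def gsz_score(
    delta_values: Mapping[str, float],
    spot_members: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    *,
    weight: float = 1.0,
) -> float:
    """Enrichment Z-score combining overlap and overexpression.

    ``delta_values`` maps each universe protein to its dE summary (e.g. its
    value at the spot's peak week or its mean dE over the spot's nodes).
    Raises if the set is disjoint from the universe (score undefined).
    """
    uni = set(universe)
    gset = set(gene_set) & uni
    if not gset:
        raise ValueError("gene set is disjoint from the universe; GSZ undefined")
    members = set(spot_members) & uni
    hit = members & gset
    k, N, n_set, n_spot = len(hit), len(uni), len(gset), len(members)
    mu = n_spot * n_set / N
    var = (
        n_spot * (n_set / N) * (1 - n_set / N) * (N - n_spot) / max(N - 1, 1)
    )
    z_overlap = (k - mu) / np.sqrt(var) if var > 0 else 0.0
    vals = np.array([delta_values[p] for p in uni if p in delta_values])
    sd_uni = vals.std() if vals.size else 0.0
    if k > 0 and sd_uni > 1e-12:
        mean_hit = float(np.mean([delta_values[p] for p in hit]))
        z_de = (mean_hit - vals.mean()) / (sd_uni / np.sqrt(k))
    else:
        z_de = 0.0
    return float((z_overlap + weight * z_de) / np.sqrt(1.0 + weight**2))


def enrich_spots(
    spots: Sequence[SpotModule],
    collection: GeneSetCollection,
    universe: Iterable[str],
    delta_values: Mapping[str, Mapping[str, float]] | None = None,
    *,
    gsz_weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Fisher (and optionally GSZ) enrichment of every spot against every set.

    ``delta_values`` maps spot id -> protein -> dE summary for the GSZ
    overexpression term. Benjamini-Hochberg adjustment is applied across
    sets within each spot.
    """
    from statsmodels.stats.multitest import multipletests

    uni = set(universe)
    restricted = collection.restrict_to_universe(uni)
    results: list[EnrichmentResult] = []
    for spot in spots:
        spot_results = []
        for name, gset in sorted(restricted.sets.items()):
            res = fisher_enrichment(
                spot.members, gset, uni, spot_id=spot.id, set_name=name
            )
            if delta_values is not None and spot.id in delta_values:
                res.gsz = gsz_score(
                    delta_values[spot.id], spot.members, gset, uni, weight=gsz_weight
                )
            spot_results.append(res)
        if spot_results:
            _, p_adj, _, _ = multipletests(
                [r.fisher_p for r in spot_results], method="fdr_bh"
            )
            for r, pa in zip(spot_results, p_adj):
                r.p_adjusted = float(pa)
        results.extend(spot_results)
    return results


def tissue_density_map(
    gene_set: Iterable[str],
    model: SomModel,
    bandwidth: float = 1.5,
    *,
    set_name: str = "?",
    region_percentile: float = 90.0,
) -> DensityMap:
    """Smoothed per-node density of a gene set's members on the map.

    Member counts per node are convolved with a Gaussian kernel of the
    given grid bandwidth and renormalized so the landscape integrates to
    the number of mapped members; high-density regions are the connected
    nodes above the given density percentile.
    """
    from .spots import connected_components

    rows, cols = model.params.rows, model.params.cols
    gset = set(gene_set)
    counts = np.zeros(model.n_nodes)
    total = 0
    for pid, node in zip(model.protein_ids, model.assignment):
        if pid in gset:
            counts[int(node)] += 1
            total += 1
    density = ndimage.gaussian_filter(
        counts.reshape(rows, cols), sigma=bandwidth, mode="constant"
    )
    density = np.maximum(density, 0.0)
    s = density.sum()
    if s > 0:
        density *= total / s
    if total > 0:
        cutoff = np.percentile(density[density > 0], region_percentile)
        regions = connected_components((density >= cutoff).ravel() & (density.ravel() > 0), rows, cols)
    else:
        regions = []
    return DensityMap(set_name=set_name, density=density, regions=regions)


def set_profile(
    gene_set: Iterable[str], matrix: AbundanceMatrix | DifferentialMatrix
) -> np.ndarray:
    """Unweighted mean abundance profile over the set's member rows."""
    gset = set(gene_set)
    rows = [i for i, p in enumerate(matrix.protein_ids) if p in gset]
    if not rows:
        raise ValueError("gene set has no members in the matrix")
    return matrix.values[rows, :].mean(axis=0)


def enrichment_heatmap(
    results: Sequence[EnrichmentResult],
    spot_order: Sequence[str] | None = None,
    *,
    score: str = "neglog10p",
    path_png: str | Path | None = None,
    path_tsv: str | Path | None = None,
) -> pd.DataFrame:
    """Sets x spots score matrix, sets hierarchically clustered.

    Spots are ordered as given (typically by phase); sets are reordered by
    average-linkage hierarchical clustering of their score profiles. The
    score is -log10 of the Fisher p by default, or the GSZ when requested.
    """
    from scipy.cluster import hierarchy

    if score == "neglog10p":
        get = lambda r: -np.log10(max(r.fisher_p, 1e-300))  # noqa: E731
    elif score == "gsz":
        get = lambda r: (r.gsz if r.gsz is not None else 0.0)  # noqa: E731
    else:
        raise ValueError(f"unknown score {score!r}")
    table: dict[str, dict[str, float]] = {}
    for r in results:
        table.setdefault(r.set_name, {})[r.spot_id] = get(r)
    df = pd.DataFrame(table).T.fillna(0.0)
    if spot_order is not None:
        df = df.reindex(columns=[s for s in spot_order if s in df.columns])
    if df.shape[0] > 2:
        link = hierarchy.linkage(df.values, method="average")
        order = hierarchy.leaves_list(link)
        df = df.iloc[order]
    if path_tsv is not None:
        df.to_csv(path_tsv, sep="\t")
    if path_png is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, 0.4 * df.shape[1]), max(3, 0.25 * df.shape[0])))
        im = ax.imshow(df.values, aspect="auto", cmap="Oranges")
        ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(df.shape[0]), df.index, fontsize=6)
        fig.colorbar(im, ax=ax, label=score)
        fig.savefig(path_png, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return df
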