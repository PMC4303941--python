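"""End-to-end pipeline: simulate/load -> SOM -> spots -> trajectories ->
networks -> enrichment -> PSF -> total abundance, with a run manifest.

Every stage reads its inputs from and writes its outputs into the run
directory, so single stages can be re-executed from cached artifacts. One
global seed is fanned out to per-stage seeds by stable hashing of the
stage name, keeping stage-level reruns reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import netstats, psf as psf_mod, spots as spots_mod, trajectories as traj_mod
from .som import (
    SomModel,
    SomParams,
    detect_peaks,
    load_model,
    population_map,
    render_portrait,
    save_model,
    train_som,
    variance_profile,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "mean_volunteer",
    "som",
    "portraits",
    "spots",
    "trajectories",
    "networks",
    "enrichment",
    "psf",
    "total_abundance",
]


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    cohort_dir: str | None = None  # read TSV cohort instead of simulating
    cohort: dict[str, Any] = field(default_factory=dict)  # CohortDesign overrides
    analysis_mode: str = "mean-volunteer"  # or single-volunteer / both
    centralize: bool = True
    som: dict[str, Any] = field(default_factory=dict)  # SomParams overrides
    spot_method: str = "percentile"  # percentile | correlation | kmeans
    spot_mode: str = "per-sample-union"
    spot_percentile: float = 2.0
    correlation_threshold: float = 0.9
    kmeans_k: int = 12
    trajectory_grid: int = 10
    segmentation_k: int = 3
    wto_edge_threshold: float = 0.1
    beta_permutations: int = 1000
    gmt_path: str | None = None  # default: gene sets derived from ground truth
    kgml_paths: list[str] = field(default_factory=list)
    psf_epsilon: float = 0.01
    render_images: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _out(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream artifact {path}; run its producer first"
        )
    return path


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    if config.cohort_dir is not None:
        # cohort supplied externally; nothing to simulate
        return []
    overrides = dict(config.cohort)
    n_per_module = overrides.pop("n_per_module", None)
    if n_per_module is not None:
        overrides["modules"] = cohort_mod.default_module_specs(n_per_module)
    design = cohort_mod.CohortDesign(**overrides)
    matrices, gt = cohort_mod.generate_cohort(design, seed=config.stage_seed("simulate"))
    paths = []
    cdir = out / "cohort"
    cdir.mkdir(exist_ok=True)
    for m in matrices:
        p = cdir / f"{m.volunteer_id}.tsv"
        io_mod.write_presence_matrix(m, p)
        paths.append(p)
    gt_path = out / "ground_truth.tsv"
    cohort_mod.export_ground_truth(gt, gt_path)
    paths.append(gt_path)
    return paths


def _load_cohort(config: PipelineConfig, stage: str) -> list[io_mod.VolunteerMatrix]:
    cdir = Path(config.cohort_dir) if config.cohort_dir else _out(config) / "cohort"
    _require(cdir, stage)
    files = sorted(cdir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no cohort TSV files under {cdir}")
    return [io_mod.read_presence_matrix(f) for f in files]


def stage_mean_volunteer(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    matrices = _load_cohort(config, "mean_volunteer")
    mean = io_mod.build_mean_volunteer(matrices)
    mean.to_frame().to_csv(out / "mean_volunteer.tsv", sep="\t")
    diff = io_mod.centralize(mean)
    diff.to_frame().to_csv(out / "mean_volunteer_centralized.tsv", sep="\t")
    return [out / "mean_volunteer.tsv", out / "mean_volunteer_centralized.tsv"]


def _read_matrix(path: Path, differential: bool):
    df = pd.read_csv(path, sep="\t", index_col=0)
    cls = io_mod.DifferentialMatrix if differential else io_mod.AbundanceMatrix
    return cls(
        protein_ids=list(df.index),
        time_points=[int(c) for c in df.columns],
        values=df.values,
    )


def stage_som(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    params = SomParams(seed=config.stage_seed("som"), **config.som)
    produced = []
    diff = _read_matrix(_require(out / "mean_volunteer_centralized.tsv", "som"), True)
    data = diff if config.centralize else _read_matrix(out / "mean_volunteer.tsv", False)
    model = train_som(data, params)
    save_model(model, out / "som_model.npz")
    produced.append(out / "som_model.npz")
    np.savetxt(out / "population_map.tsv", population_map(model), fmt="%d", delimiter="\t")
    produced.append(out / "population_map.tsv")
    # a second map on absolute values feeds the total-abundance stage
    absolute = _read_matrix(out / "mean_volunteer.tsv", False)
    abs_model = train_som(absolute, params)
    save_model(abs_model, out / "som_model_absolute.npz")
    produced.append(out / "som_model_absolute.npz")
    return produced


def stage_portraits(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model.npz", "portraits"))
    pdir = out / "portraits"
    pdir.mkdir(exist_ok=True)
    produced = []
    for t in range(model.n_time_points):
        path = pdir / f"week_{model.time_points[t]:+03d}.png" if config.render_images else None
        render_portrait(model, t, path=path)
        if path is not None:
            produced.append(path)
    return produced


def _select_spots(config: PipelineConfig, model: SomModel) -> list[spots_mod.SpotModule]:
    if config.spot_method == "percentile":
        return spots_mod.select_percentile_spots(
            model, mode=config.spot_mode, percentile=config.spot_percentile
        )
    if config.spot_method == "correlation":
        return spots_mod.select_correlation_spots(model, config.correlation_threshold)
    if config.spot_method == "kmeans":
        return spots_mod.select_kmeans_spots(
            model, config.kmeans_k, seed=config.stage_seed("spots")
        )
    raise ValueError(f"unknown spot method {config.spot_method!r}")


def _spots_frame(spots: Sequence[spots_mod.SpotModule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot": s.id,
            "method": s.method,
            "polarity": s.polarity,
            "n_nodes": s.n_nodes,
            "n_members": s.n_members,
            "phase_week": s.phase_week,
            "max_min_lag": s.max_min_lag,
            "nodes": ",".join(map(str, sorted(s.nodes))),
            "members": ",".join(s.members),
        }
        for s in spots
    )


def stage_spots(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model.npz", "spots"))
    spots = _select_spots(config, model)
    _spots_frame(spots).to_csv(out / "spots.tsv", sep="\t", index=False)
    profiles = pd.DataFrame(
        [s.mean_profile for s in spots],
        index=[s.id for s in spots],
        columns=model.time_points,
    )
    profiles.to_csv(out / "spot_profiles.tsv", sep="\t")
    summary = spots_mod.build_summary_map(model, config.spot_percentile)
    pd.DataFrame(summary.flags()).to_csv(out / "summary_map.tsv", sep="\t", header=False, index=False)
    return [out / "spots.tsv", out / "spot_profiles.tsv", out / "summary_map.tsv"]


def _load_spots(config: PipelineConfig, model: SomModel, stage: str) -> list[spots_mod.SpotModule]:
    out = _out(config)
    df = pd.read_csv(_require(out / "spots.tsv", stage), sep="\t")
    spots = []
    for _, row in df.iterrows():
        nodes = frozenset(int(n) for n in str(row["nodes"]).split(","))
        members = str(row["members"]).split(",") if isinstance(row["members"], str) else []
        profile = model.meta[sorted(nodes), :].mean(axis=0)
        spots.append(
            spots_mod.SpotModule(
                id=row["spot"], method=row["method"], polarity=row["polarity"],
                nodes=nodes, members=members, mean_profile=profile,
                phase_week=int(row["phase_week"]), max_min_lag=int(row["max_min_lag"]),
            )
        )
    return spots


def stage_trajectories(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model.npz", "trajectories"))
    states = traj_mod.sample_states(model)
    design = io_mod.StudyDesign.default(model.time_points)
    produced = []
    for method in ("som2", "ica"):
        seed = config.stage_seed(f"trajectories-{method}")
        if method == "som2":
            traj = traj_mod.second_level_som(
                states, model.time_points,
                rows=config.trajectory_grid, cols=config.trajectory_grid, seed=seed,
            )
        else:
            traj = traj_mod.ica_projection(states, model.time_points, seed=seed)
        labels, ari = traj_mod.segment_trajectory(
            traj, design, k=config.segmentation_k, seed=seed
        )
        df = pd.DataFrame(
            {
                "week": traj.weeks,
                "x": traj.coords[:, 0],
                "y": traj.coords[:, 1],
                "segment": labels,
                "reference_phase": [design.phase_of(w) for w in traj.weeks],
            }
        )
        df.attrs["ari"] = ari
        path = out / f"trajectory_{method}.tsv"
        df.to_csv(path, sep="\t", index=False)
        produced.append(path)
        if config.render_images:
            produced.append(_plot_trajectory(traj, design, out / f"trajectory_{method}.png"))
    return produced


def _plot_trajectory(traj, design, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    xy = traj.coords
    ax.plot(xy[:, 0], xy[:, 1], "-", color="0.7", lw=0.8)
    colors = {"early": "tab:blue", "intermediate": "tab:green", "late": "tab:red"}
    for i, w in enumerate(traj.weeks):
        ax.scatter(*xy[i], color=colors[design.phase_of(w)], s=25, zorder=3)
        ax.annotate(
            f"{w} ({design.salt_dose.get(w, 0):.0f}g)" if design.is_isolation(w) else str(w),
            xy[i], fontsize=5, xytext=(2, 2), textcoords="offset points",
        )
    for i in range(len(traj.weeks) - 1):
        ax.annotate(
            "", xy[i + 1], xy[i],
            arrowprops=dict(arrowstyle="->", color="0.5", lw=0.6),
        )
    ax.set_title(f"sample trajectory ({traj.method})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def stage_networks(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model.npz", "networks"))
    spots = _load_spots(config, model, "networks")
    edges = []
    for channel in ("positive", "negative"):
        omega = netstats.wto_scores(model.meta, sign=channel)
        edges.extend(netstats.spot_wto_network(spots, omega, channel, config.wto_edge_threshold))
    pd.DataFrame(
        {"spot_i": e.spot_i, "spot_j": e.spot_j, "channel": e.channel, "score": e.score}
        for e in edges
    ).to_csv(out / "wto_edges.tsv", sep="\t", index=False)
    results = netstats.beta_test_all(
        spots, model.meta,
        n_permutations=config.beta_permutations, seed=config.stage_seed("networks"),
    )
    pd.DataFrame(
        {
            "spot": r.spot_id, "beta": r.beta, "p": r.p_value,
            "p_adj": r.p_adjusted, "null": r.null_method, "m": r.n_members,
        }
        for r in results
    ).to_csv(out / "beta_results.tsv", sep="\t", index=False)
    return [out / "wto_edges.tsv", out / "beta_results.tsv"]


def _gene_sets(config: PipelineConfig) -> io_mod.GeneSetCollection:
    if config.gmt_path is not None:
        return io_mod.read_gene_sets(config.gmt_path)
    gt_path = _require(_out(config) / "ground_truth.tsv", "enrichment")
    labels = cohort_mod.read_ground_truth(gt_path)
    sets: dict[str, set[str]] = {}
    for pid, label in labels.items():
        sets.setdefault(f"planted:{label}", set()).add(pid)
    return io_mod.GeneSetCollection(sets=sets, categories={n: "custom" for n in sets})


def stage_enrichment(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model.npz", "enrichment"))
    spots = _load_spots(config, model, "enrichment")
    collection = _gene_sets(config)
    universe = model.protein_ids
    diff = _read_matrix(_require(out / "mean_volunteer_centralized.tsv", "enrichment"), True)
    # dE summary per spot: each protein's value at the spot's peak week
    week_index = {w: i for i, w in enumerate(diff.time_points)}
    delta: dict[str, dict[str, float]] = {}
    for s in spots:
        col = diff.values[:, week_index[s.phase_week]]
        delta[s.id] = dict(zip(diff.protein_ids, col))
    results = enrich_mod.enrich_spots(spots, collection, universe, delta)
    pd.DataFrame(
        {
            "spot": r.spot_id, "set": r.set_name, "overlap": r.overlap,
            "n_universe": r.n_universe, "n_set": r.n_set, "n_spot": r.n_spot,
            "fisher_p": r.fisher_p, "p_adj": r.p_adjusted, "gsz": r.gsz,
        }
        for r in results
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    spot_order = [s.id for s in sorted(spots, key=lambda s: s.phase_week)]
    enrich_mod.enrichment_heatmap(
        results, spot_order,
        path_png=(out / "enrichment_heatmap.png") if config.render_images else None,
        path_tsv=out / "enrichment_heatmap.tsv",
    )
    produced = [out / "enrichment.tsv", out / "enrichment_heatmap.tsv"]
    if config.render_images:
        produced.append(out / "enrichment_heatmap.png")
    return produced


def _toy_pathways(config: PipelineConfig) -> list[psf_mod.PathwayGraph]:
    if config.kgml_paths:
        return [psf_mod.parse_kgml(p) for p in config.kgml_paths]
    # fall back to chain pathways over the planted modules: each planted
    # module feeds an activation->inhibition chain, giving PSF profiles
    # that track (and invert) the module wave
    gt_path = _require(_out(config) / "ground_truth.tsv", "psf")
    labels = cohort_mod.read_ground_truth(gt_path)
    by_label: dict[str, list[str]] = {}
    for pid, label in labels.items():
        if not label.startswith("invariant") and label != "spiked":
            by_label.setdefault(label, []).append(pid)
    pathways = []
    for label, members in sorted(by_label.items()):
        members = sorted(members)
        third = max(len(members) // 3, 1)
        g = psf_mod.nx.DiGraph()
        g.add_node("receptor", members=members[:third])
        g.add_node("kinase", members=members[third : 2 * third])
        g.add_node("effector", members=members[2 * third :])
        g.add_edge("receptor", "kinase", type="activation")
        g.add_edge("kinase", "effector", type="activation")
        pathways.append(psf_mod.PathwayGraph(name=f"toy:{label}", graph=g))
    return pathways


def stage_psf(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    abundance = pd.read_csv(
        _require(out / "mean_volunteer.tsv", "psf"), sep="\t", index_col=0
    )
    spot_profiles = pd.read_csv(
        _require(out / "spot_profiles.tsv", "psf"), sep="\t", index_col=0
    )
    all_profiles = []
    matches = []
    for pw in _toy_pathways(config):
        prof = psf_mod.psf_time_profiles(pw, abundance, epsilon=config.psf_epsilon)
        prof.index = [f"{pw.name}/{s}" for s in prof.index]
        all_profiles.append(prof)
    profiles = pd.concat(all_profiles)
    profiles.columns = spot_profiles.columns
    profiles.to_csv(out / "psf_profiles.tsv", sep="\t")
    match = psf_mod.match_profiles(profiles, spot_profiles)
    match.to_csv(out / "psf_matches.tsv", sep="\t", index=False)
    return [out / "psf_profiles.tsv", out / "psf_matches.tsv"]


def stage_total_abundance(config: PipelineConfig) -> list[Path]:
    out = _out(config)
    model = load_model(_require(out / "som_model_absolute.npz", "total_abundance"))
    profile = variance_profile(model)
    peaks = detect_peaks(profile, min_separation=2, weeks=model.time_points)
    df = pd.DataFrame({"week": model.time_points, "variance": profile})
    df["is_peak"] = df["week"].isin(peaks)
    df.to_csv(out / "total_abundance.tsv", sep="\t", index=False)
    return [out / "total_abundance.tsv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "mean_volunteer": stage_mean_volunteer,
    "som": stage_som,
    "portraits": stage_portraits,
    "spots": stage_spots,
    "trajectories": stage_trajectories,
    "networks": stage_networks,
    "enrichment": stage_enrichment,
    "psf": stage_psf,
    "total_abundance": stage_total_abundance,
}


def run_stage(config: PipelineConfig, stage: str) -> list[Path]:
    """Re-execute a single stage from cached upstream artifacts."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    t0 = time.time()
    produced = _STAGE_FUNCS[stage](config)
    logger.info("stage %-16s %3d output(s) in %.1fs", stage, len(produced), time.time() - t0)
    return produced


def run_pipeline(config: PipelineConfig) -> dict[str, list[str]]:
    """Run all stages in order; write the effective config and a manifest."""
    out = _out(config)
    config.to_yaml(out / "config.yaml")
    manifest: dict[str, list[str]] = {}
    for stage in STAGES:
        produced = run_stage(config, stage)
        manifest[stage] = [str(p.relative_to(out)) for p in produced]
    digest = {}
    for stage, files in manifest.items():
        for f in files:
            p = out / f
            if p.suffix == ".tsv":
                digest[f] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps({"stages": manifest, "sha256": digest}, indent=2)
    )
    return manifest
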