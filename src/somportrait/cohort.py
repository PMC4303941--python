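"""Synthetic binary time-course cohorts with planted co-expression modules.

The generator emulates the statistical structure of a weekly-sampled
isolation cohort: six volunteers, ~23 weekly samples spanning
pre-isolation (negative weeks), 15 isolation weeks (0-14) and a short
post-isolation tail, and ~2000 binary protein profiles. Roughly half the
proteins belong to ten wave-like co-expression modules that differ in
phase phi (week of maximal detection probability), period T and shape
(harmonic cosine vs single Gaussian peak); the other half is invariantly
present, invariantly absent, or single-spiked noise. Every protein carries
a ground-truth label so downstream module recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import StudyDesign, VolunteerMatrix

__all__ = [
    "ModuleSpec",
    "CohortDesign",
    "GroundTruth",
    "wave_probability",
    "generate_cohort",
    "export_ground_truth",
    "read_ground_truth",
    "default_module_specs",
]

EXPERIMENT_WEEKS = 15.0  # T*: duration of the isolation period in weeks


@dataclass
class ModuleSpec:
    """Planted co-expression module: a detection-probability wave.

    phi is the week of the probability maximum, T the period (cosine shape
    only), amplitude a and baseline b bound the probability between b and
    b + a (clipped to [0, 1]); peak-shaped modules use a Gaussian bump of
    the given width instead of a cosine.
    """

    name: str
    size: int
    phase: float
    period: float = EXPERIMENT_WEEKS
    shape: Literal["cosine", "peak"] = "cosine"
    amplitude: float = 0.8
    baseline: float = 0.1
    peak_width: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline must lie in [0, 1]")
        if self.shape == "cosine" and self.period == 0:
            raise ValueError("cosine period must be nonzero")
        if self.shape == "peak" and self.peak_width <= 0:
            raise ValueError("peak width must be positive")


def wave_probability(spec: ModuleSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Detection probability of a module protein at week t."""
    t = np.asarray(t, dtype=float)
    if spec.shape == "cosine":
        if spec.period == 0:
            raise ValueError("cosine period must be nonzero")
        p = spec.baseline + spec.amplitude * (
            1.0 + np.cos(2.0 * math.pi * (t - spec.phase) / spec.period)
        ) / 2.0
    else:
        p = spec.baseline + spec.amplitude * np.exp(
            -((t - spec.phase) ** 2) / (2.0 * spec.peak_width**2)
        )
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def default_module_specs(n_per_module: int = 95) -> list[ModuleSpec]:
    """Ten modules staggered in phase across the three reference phases.

    Phases 0-6 (early, 4 modules), 8-11 (intermediate, 3) and 13-16 (late,
    3, one peaking after isolation), alternating cosine and peak shapes.
    Cosine periods are drawn from {T*, 2T*} such that exactly one maximum
    falls inside the sampled window, keeping the planted phase identifiable
    from the profile argmax.
    """
    T = EXPERIMENT_WEEKS
    mk = lambda name, phi, shape, period, width=2.0: ModuleSpec(  # noqa: E731
        name=name, size=n_per_module, phase=phi, period=period, shape=shape,
        amplitude=0.8, baseline=0.1 if shape == "cosine" else 0.05, peak_width=width,
    )
    return [
        mk("M01", 0.0, "cosine", 2 * T),
        mk("M02", 2.0, "peak", T),
        mk("M03", 4.0, "cosine", 2 * T),
        mk("M04", 6.0, "peak", T / 2),
        mk("M05", 8.0, "cosine", T),
        mk("M06", 10.0, "peak", T / 2),
        mk("M07", 11.0, "cosine", 2 * T),
        mk("M08", 13.0, "peak", T / 2, 2.5),
        mk("M09", 14.0, "cosine", 2 * T),
        mk("M10", 16.0, "peak", T / 2),
    ]


@dataclass
class CohortDesign:
    """Cohort layout: volunteers, week grid, modules and background mix.

    Defaults state a world of 6 volunteers, weeks -4..18, ten planted
    modules of 95 proteins, and 1050 background proteins (250 invariantly
    present at p=0.95, 550 invariantly absent at p=0.02, 250 single-spiked),
    i.e. 52.5% of 2000 proteins outside modules, with symmetric bit-flip
    noise eps=0.05 applied after each Bernoulli draw.
    """

    n_volunteers: int = 6
    weeks: list[int] = field(default_factory=lambda: list(range(-4, 19)))
    modules: list[ModuleSpec] = field(default_factory=default_module_specs)
    n_invariant_high: int = 250
    n_invariant_low: int = 550
    n_single_spiked: int = 250
    noise: float = 0.05
    p_invariant_high: float = 0.95
    p_invariant_low: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("bit-flip noise must lie in [0, 0.5)")
        if self.n_volunteers < 1:
            raise ValueError("need at least one volunteer")

    @property
    def n_proteins(self) -> int:
        return (
            sum(m.size for m in self.modules)
            + self.n_invariant_high
            + self.n_invariant_low
            + self.n_single_spiked
        )

    def study_design(self) -> StudyDesign:
        return StudyDesign.default(self.weeks)


@dataclass
class GroundTruth:
    """Protein -> planted label; labels partition the cohort universe."""

    labels: dict[str, str]  # module name or invariant-high/invariant-low/spiked
    module_specs: dict[str, ModuleSpec]

    def members(self, label: str) -> set[str]:
        return {p for p, l in self.labels.items() if l == label}

    def module_names(self) -> list[str]:
        return sorted(self.module_specs)


def generate_cohort(
    design: CohortDesign | None = None, seed: int = 0
) -> tuple[list[VolunteerMatrix], GroundTruth]:
    """Draw a cohort of binary volunteer matrices plus its ground truth.

    Module protein bits are Bernoulli(wave_probability) per (volunteer,
    week), then flipped with probability ``design.noise``; invariant
    proteins are flat Bernoulli draws; single-spiked proteins are detected
    at exactly one random (volunteer, week).
    """
    if design is None:
        design = CohortDesign()
    rng = np.random.default_rng(seed)
    weeks = np.asarray(design.weeks, dtype=float)
    n_weeks = len(weeks)

    protein_ids: list[str] = []
    labels: dict[str, str] = {}
    probs: list[np.ndarray] = []  # per-protein probability profile, NaN for spiked
    for spec in design.modules:
        profile = wave_probability(spec, weeks)
        for i in range(spec.size):
            pid = f"{spec.name}_P{i:04d}"
            protein_ids.append(pid)
            labels[pid] = spec.name
            probs.append(profile)
    for i in range(design.n_invariant_high):
        pid = f"IH_P{i:04d}"
        protein_ids.append(pid)
        labels[pid] = "invariant-high"
        probs.append(np.full(n_weeks, design.p_invariant_high))
    for i in range(design.n_invariant_low):
        pid = f"IL_P{i:04d}"
        protein_ids.append(pid)
        labels[pid] = "invariant-low"
        probs.append(np.full(n_weeks, design.p_invariant_low))
    spiked_start = len(protein_ids)
    for i in range(design.n_single_spiked):
        pid = f"SP_P{i:04d}"
        protein_ids.append(pid)
        labels[pid] = "spiked"
        probs.append(np.zeros(n_weeks))

    prob_matrix = np.vstack(probs) if probs else np.zeros((0, n_weeks))
    n_proteins = len(protein_ids)

    matrices: list[VolunteerMatrix] = []
    for v in range(design.n_volunteers):
        bits = (rng.random((n_proteins, n_weeks)) < prob_matrix).astype(np.int8)
        if design.noise > 0:
            flips = rng.random((n_proteins, n_weeks)) < design.noise
            # spiked rows stay clean: their single detection is planted below
            flips[spiked_start:, :] = False
            bits = np.where(flips, 1 - bits, bits)
        matrices.append(
            VolunteerMatrix(
                volunteer_id=f"V{v + 1}",
                protein_ids=list(protein_ids),
                time_points=list(design.weeks),
                values=bits,
            )
        )
    # each spiked protein gets exactly one detection across the whole cohort
    for i in range(design.n_single_spiked):
        v = int(rng.integers(design.n_volunteers))
        w = int(rng.integers(n_weeks))
        matrices[v].values[spiked_start + i, w] = 1

    specs = {m.name: m for m in design.modules}
    return matrices, GroundTruth(labels=labels, module_specs=specs)


def export_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the protein -> label mapping as a two-column TSV."""
    if not gt.labels:
        raise ValueError("ground truth is empty")
    with Path(path).open("w") as fh:
        fh.write("protein\tlabel\n")
        for pid, label in gt.labels.items():
            fh.write(f"{pid}\t{label}\n")


def read_ground_truth(path: str | Path) -> dict[str, str]:
    lines = Path(path).read_text().splitlines()
    out: dict[str, str] = {}
    for line in lines[1:]:
        if line.strip():
            pid, label = line.split("\t")
            out[pid] = label
    return out
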