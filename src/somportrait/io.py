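"""Input/output and matrix assembly for binary time-course proteomics.

The pipeline starts from per-volunteer presence/absence matrices (rows =
protein accessions, columns = integer week indices; 0 = first isolation
week, negative = pre-isolation). Volunteers are averaged into a common-grid
"mean volunteer" matrix of detection fractions, which is then centralized
per protein so values express over-/under-presence relative to the
protein's own mean (differential detection level, dE).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VolunteerMatrix",
    "AbundanceMatrix",
    "DifferentialMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "read_presence_matrix",
    "write_presence_matrix",
    "build_mean_volunteer",
    "centralize",
    "read_gene_sets",
    "read_mapping_table",
]


class FormatError(ValueError):
    """A file violated the expected tabular contract."""


@dataclass
class VolunteerMatrix:
    """Binary protein x week detection matrix of one volunteer.

    Weeks may be ragged across volunteers (missing sampling weeks are simply
    absent columns, never imputed).
    """

    volunteer_id: str
    protein_ids: list[str]
    time_points: list[int]
    values: np.ndarray  # shape (n_proteins, n_weeks), entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.protein_ids), len(self.time_points)):
            raise ValueError("values shape does not match protein/time labels")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein accessions")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value at protein {self.protein_ids[r]!r}, "
                f"week {self.time_points[c]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.time_points)


@dataclass
class AbundanceMatrix:
    """Protein x week matrix of detection fractions on a common week grid.

    ``values[i, t]`` is the fraction of volunteers with a sample at week t
    that detected protein i; ``n_contributing[t]`` counts those volunteers.
    """

    protein_ids: list[str]
    time_points: list[int]
    values: np.ndarray  # (N, M) floats in [0, 1]
    n_contributing: np.ndarray | None = None  # (M,) ints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.time_points)):
            raise ValueError("values shape does not match labels")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("abundance fractions must lie in [0, 1]")
        if self.n_contributing is not None:
            self.n_contributing = np.asarray(self.n_contributing, dtype=int)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.time_points)


@dataclass
class DifferentialMatrix:
    """Row-centered profiles (dE): per-protein deviation from its own mean."""

    protein_ids: list[str]
    time_points: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.time_points)):
            raise ValueError("values shape does not match labels")
        rm = self.values.mean(axis=1)
        if self.values.size and np.abs(rm).max() > 1e-9:
            raise ValueError("rows of a DifferentialMatrix must have zero mean")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.time_points)


# Printed isolation schedule: weeks 0-14 (0-based), salt 12 g/day for weeks
# 0-4, 9 g/day for 5-8, back to 12 for week 9, then 6 g/day for 10-14.
_DEFAULT_SALT = {**{w: 12.0 for w in range(0, 5)},
                 **{w: 9.0 for w in range(5, 9)},
                 9: 12.0,
                 **{w: 6.0 for w in range(10, 15)}}


@dataclass
class StudyDesign:
    """Week-indexed experimental design: salt dose, isolation flag, phase.

    Reference phases: early = week <= 6 (including pre-isolation),
    intermediate = weeks 7-11, late = week >= 12 (including post-isolation).
    """

    weeks: list[int]
    salt_dose: dict[int, float] = field(default_factory=dict)
    isolation_weeks: tuple[int, int] = (0, 14)  # inclusive range

    def __post_init__(self) -> None:
        if not self.salt_dose:
            self.salt_dose = {w: _DEFAULT_SALT.get(w, 0.0) for w in self.weeks}

    def is_isolation(self, week: int) -> bool:
        lo, hi = self.isolation_weeks
        return lo <= week <= hi

    def phase_of(self, week: int) -> str:
        if week <= 6:
            return "early"
        if week <= 11:
            return "intermediate"
        return "late"

    def phase_labels(self) -> list[str]:
        return [self.phase_of(w) for w in self.weeks]

    @classmethod
    def default(cls, weeks: Sequence[int] | None = None) -> "StudyDesign":
        if weeks is None:
            weeks = list(range(-4, 19))
        return cls(weeks=list(weeks))


@dataclass
class GeneSetCollection:
    """Named gene sets with a category tag and unique members."""

    sets: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.categories.setdefault(name, "custom")

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with the universe, dropping emptied sets."""
        uni = set(universe)
        kept = {n: m & uni for n, m in self.sets.items()}
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(sets=kept, categories={n: self.categories[n] for n in kept})

    def __len__(self) -> int:
        return len(self.sets)


def _sniff_delimiter(sample: str) -> str:
    # restricted to tab/comma by design
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_presence_matrix(
    path: str | Path, *, delimiter: str | None = None, volunteer_id: str | None = None
) -> VolunteerMatrix:
    """Read a binary proteins x weeks table (header row = week indices)."""
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one protein row")
    header = rows[0]
    try:
        weeks = [int(w) for w in header[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}: week header must be integers: {exc}") from exc
    protein_ids: list[str] = []
    data: list[list[int]] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        acc = row[0]
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc!r} at line {lineno}")
        seen.add(acc)
        if len(row) != len(weeks) + 1:
            raise FormatError(f"{path}: line {lineno} has {len(row) - 1} cells, expected {len(weeks)}")
        vals = []
        for week, cell in zip(weeks, row[1:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise FormatError(
                    f"{path}: non-binary cell {cell!r} at protein {acc!r}, week {week}"
                )
            vals.append(int(cell))
        protein_ids.append(acc)
        data.append(vals)
    return VolunteerMatrix(
        volunteer_id=volunteer_id or path.stem,
        protein_ids=protein_ids,
        time_points=weeks,
        values=np.array(data, dtype=np.int8),
    )


def write_presence_matrix(m: VolunteerMatrix, path: str | Path, *, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["protein"] + [str(t) for t in m.time_points])
        for acc, row in zip(m.protein_ids, m.values):
            w.writerow([acc] + [str(int(v)) for v in row])


def build_mean_volunteer(matrices: Sequence[VolunteerMatrix]) -> AbundanceMatrix:
    """Average binary detections over the volunteers sampled each week.

    The protein universe is the union over volunteers (a protein absent from
    one volunteer's table counts as never detected there); the week grid is
    the union of sampled weeks, and each cell averages only the volunteers
    that actually provided a sample that week.
    """
    if not matrices:
        raise ValueError("need at least one volunteer matrix")
    proteins: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for p in m.protein_ids:
            if p not in seen:
                seen.add(p)
                proteins.append(p)
    weeks = sorted({t for m in matrices for t in m.time_points})
    p_index = {p: i for i, p in enumerate(proteins)}
    w_index = {w: j for j, w in enumerate(weeks)}
    total = np.zeros((len(proteins), len(weeks)))
    n_contrib = np.zeros(len(weeks), dtype=int)
    for m in matrices:
        cols = [w_index[t] for t in m.time_points]
        rows = [p_index[p] for p in m.protein_ids]
        block = np.zeros((len(proteins), len(m.time_points)))
        block[rows, :] = m.values
        total[:, cols] += block
        n_contrib[cols] += 1
    values = total / n_contrib[None, :]
    return AbundanceMatrix(
        protein_ids=proteins, time_points=weeks, values=values, n_contributing=n_contrib
    )


def centralize(m: AbundanceMatrix | DifferentialMatrix) -> DifferentialMatrix:
    """Subtract each profile's mean so values express over/under-presence."""
    if m.values.shape[1] < 2:
        raise ValueError("need at least two time points to centralize")
    vals = m.values - m.values.mean(axis=1, keepdims=True)
    return DifferentialMatrix(
        protein_ids=list(m.protein_ids), time_points=list(m.time_points), values=vals
    )


def read_gene_sets(path: str | Path, *, default_category: str = "custom") -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> members...).

    The description field is used as the category when it matches one of
    BP/CC/MF/tissue; members within a line are deduplicated.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    cats: dict[str, str] = {}
    known = {"BP", "CC", "MF", "tissue"}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: need name, description and >=1 member")
        name, desc = parts[0], parts[1]
        members = {m for m in parts[2:] if m}
        if not members:
            raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = members
        cats[name] = desc if desc in known else default_category
    return GeneSetCollection(sets=sets, categories=cats)


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column accession -> gene symbol TSV (static mapping table)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: line {lineno}: need two tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping
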