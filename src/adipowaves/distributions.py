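"""Cell-size distribution containers and elementary operations.

Adipose cell sizes are measured as particle-diameter histograms on a
logarithmic grid (Coulter-counter style: 80 bins spanning 20-240 um by
default).  A single measurement is one replicate histogram expressed as
percentages of counted particles; a longitudinal dataset collects all
replicate measurements of one animal across an irregular biopsy-day
schedule.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiameterGrid",
    "SizeDistribution",
    "LongitudinalDataset",
    "make_log_grid",
    "normalize_to_percent",
    "mean_distribution",
    "fractional_difference",
    "read_dataset",
    "write_dataset",
    "export_heatmap_matrix",
]

#: Absolute tolerance on the "percentages sum to 100" invariant.
PERCENT_TOL = 1e-6


@dataclass(frozen=True)
class DiameterGrid:
    """Logarithmic diameter grid: ``n_bins`` bins spanning ``d_min``..``d_max`` um."""

    n_bins: int = 80
    d_min: float = 20.0
    d_max: float = 240.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if not (0 < self.d_min < self.d_max):
            raise ValueError(
                f"need 0 < d_min < d_max, got d_min={self.d_min}, d_max={self.d_max}"
            )

    @property
    def edges(self) -> np.ndarray:
        """The ``n_bins + 1`` bin edges, geometrically spaced."""
        return np.geomspace(self.d_min, self.d_max, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        """Bin centers at the geometric mean of adjacent edges."""
        e = self.edges
        return np.sqrt(e[:-1] * e[1:])


def make_log_grid(n_bins: int = 80, d_min: float = 20.0, d_max: float = 240.0) -> DiameterGrid:
    """Build a logarithmically spaced diameter grid.

    Adjacent edges are in the constant ratio ``(d_max/d_min)**(1/n_bins)``.
    """
    return DiameterGrid(n_bins=int(n_bins), d_min=float(d_min), d_max=float(d_max))


@dataclass(frozen=True)
class SizeDistribution:
    """One replicate histogram: percentage of cells per diameter bin on one day."""

    day: int
    replicate_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if np.any(v < 0):
            raise ValueError("percentages must be non-negative")
        total = float(v.sum())
        if abs(total - 100.0) > PERCENT_TOL:
            raise ValueError(f"percentages must sum to 100, got {total!r}")


@dataclass
class LongitudinalDataset:
    """All replicate size distributions of one animal over its biopsy schedule."""

    animal_id: str
    grid: DiameterGrid
    measurements: list[SizeDistribution] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.measurements:
            if len(m.values) != self.grid.n_bins:
                raise ValueError(
                    f"measurement on day {m.day} has {len(m.values)} bins, "
                    f"grid has {self.grid.n_bins}"
                )
        if self.measurements and self.days[0] != 0:
            raise ValueError("first biopsy day must be 0")

    @property
    def days(self) -> list[int]:
        """Sorted unique biopsy days."""
        return sorted({m.day for m in self.measurements})

    def replicates_on(self, day: int) -> list[SizeDistribution]:
        return [m for m in self.measurements if m.day == day]

    def day_mean(self, day: int) -> np.ndarray:
        """Replicate-averaged percentage histogram for one day."""
        reps = self.replicates_on(day)
        if not reps:
            raise ValueError(f"no measurements on day {day}")
        return np.mean([m.values for m in reps], axis=0)

    def values_matrix(self) -> np.ndarray:
        """(n_measurements, n_bins) array in file order."""
        return np.array([m.values for m in self.measurements])


def normalize_to_percent(counts: np.ndarray) -> np.ndarray:
    """Convert raw non-negative counts to percentages summing to 100."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector")
    return 100.0 * c / total


def mean_distribution(dataset: LongitudinalDataset) -> np.ndarray:
    """Average cell-size distribution over all experimental days.

    Replicates are averaged within each day first; the per-day means are then
    averaged with equal weight per day, so days with extra replicates do not
    dominate.
    """
    days = dataset.days
    if not days:
        raise ValueError("dataset has no measurements")
    return np.mean([dataset.day_mean(d) for d in days], axis=0)


def fractional_difference(day_values: np.ndarray, mean_values: np.ndarray) -> np.ndarray:
    """Elementwise ``(day - mean) / mean``.

    Bins where the mean is zero are returned as NaN markers rather than
    raising, since trailing diameter bins of a sparse histogram can be empty
    on every day.
    """
    d = np.asarray(day_values, dtype=float)
    m = np.asarray(mean_values, dtype=float)
    if d.shape != m.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {m.shape}")
    out = np.full_like(d, np.nan)
    ok = m > 0
    out[ok] = (d[ok] - m[ok]) / m[ok]
    return out


# ---------------------------------------------------------------------------
# CSV I/O
#
# Format: a comment line fixing the grid, then one row per replicate:
#   # grid: n=80 dmin=20 dmax=240
#   animal_id,day,replicate,bin_001,...,bin_080

_GRID_RE = re.compile(
    r"#\s*grid:\s*n=(\d+)\s+dmin=([0-9.eE+-]+)\s+dmax=([0-9.eE+-]+)"
)


def write_dataset(dataset: LongitudinalDataset, path) -> None:
    g = dataset.grid
    cols = [f"bin_{i + 1:03d}" for i in range(g.n_bins)]
    rows = []
    for m in dataset.measurements:
        rows.append([dataset.animal_id, m.day, m.replicate_id, *m.values])
    df = pd.DataFrame(rows, columns=["animal_id", "day", "replicate", *cols])
    with open(path, "w") as fh:
        fh.write(f"# grid: n={g.n_bins} dmin={g.d_min:g} dmax={g.d_max:g}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_dataset(path) -> LongitudinalDataset:
    with open(path) as fh:
        first = fh.readline()
        match = _GRID_RE.match(first)
        if not match:
            raise ValueError(
                f"{path}: expected leading '# grid: n=.. dmin=.. dmax=..' line"
            )
        grid = make_log_grid(int(match.group(1)), float(match.group(2)), float(match.group(3)))
        body = fh.read()
    df = pd.read_csv(io.StringIO(body))
    required = {"animal_id", "day", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    if len(bin_cols) != grid.n_bins:
        raise ValueError(
            f"{path}: {len(bin_cols)} value columns but grid declares {grid.n_bins} bins"
        )
    values = df[bin_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-numeric value at row {bad[0]}, column {bin_cols[bad[1]]}")
    animal_ids = df["animal_id"].astype(str).unique()
    if len(animal_ids) != 1:
        raise ValueError(f"{path}: expected one animal per file, found {list(animal_ids)}")
    order = np.argsort(df["day"].to_numpy(), kind="stable")
    measurements = [
        SizeDistribution(
            day=int(df["day"].iloc[i]),
            replicate_id=str(df["replicate"].iloc[i]),
            values=values[i],
        )
        for i in order
    ]
    return LongitudinalDataset(animal_id=str(animal_ids[0]), grid=grid, measurements=measurements)


def export_heatmap_matrix(dataset: LongitudinalDataset) -> pd.DataFrame:
    """Per-day mean percentages as a (days x n_bins) frame.

    Rows are ascending biopsy days; missing days are simply absent, which is
    what makes the sampling gaps visible when the frame is rendered as a
    heat map.  Columns are labelled by bin-center diameter.
    """
    days = dataset.days
    if not days:
        raise ValueError("dataset has no measurements")
    mat = np.array([dataset.day_mean(d) for d in days])
    cols = [f"{c:.2f}" for c in dataset.grid.centers]
    return pd.DataFrame(mat, index=pd.Index(days, name="day"), columns=cols)
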