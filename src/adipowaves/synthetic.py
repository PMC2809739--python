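"""Synthetic longitudinal cell-size data with a known periodic modulation.

The generator emulates the statistical structure of osmium-fixed
Coulter-counter measurements of adipose tissue: a bimodal diameter
distribution (a small immature-cell mode plus a large lipid-filled mode),
~6,000 counted particles per measurement, four replicate measurements per
biopsy, and an irregular biopsy-day schedule.  The mixture weight of the
small mode is modulated with a configurable true period so that parameter
recovery by the inference modules is a well-posed test.

Two modulation modes are supported:

``piecewise_constant``
    The small-mode weight depends only on the period-bin index
    ``floor(day / (true_period / n_period_bins_true)) mod n_period_bins_true``,
    exactly matching the exchangeability-within-period-bin assumption of the
    inference model.

``smooth``
    ``w_small(day) = w_small_base + w_small_amplitude * sin(2*pi*day/true_period)``,
    a stress test in which the inference model's piecewise-constancy
    assumption only holds approximately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .distributions import (
    DiameterGrid,
    LongitudinalDataset,
    SizeDistribution,
    make_log_grid,
)

__all__ = [
    "GeneratorConfig",
    "TrueSignal",
    "biopsy_schedule",
    "true_distribution",
    "sample_dataset",
]

#: The 16 irregular biopsy days of the full study schedule.
_FULL_SCHEDULE = (0, 2, 6, 9, 13, 23, 33, 57, 69, 86, 98, 134, 141, 150, 156, 162)


def biopsy_schedule(truncated: bool = False) -> list[int]:
    """The irregular biopsy-day schedule.

    ``truncated=True`` returns the 14-day variant ending at day 150 (one of
    the two animals lost its last two time points, days 156 and 162).
    """
    sched = list(_FULL_SCHEDULE)
    return [d for d in sched if d <= 150] if truncated else sched


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic animal.

    The lognormal mode locations/scales are on the log-diameter (um) scale;
    defaults place the small mode near 35 um and the large mode near 100 um,
    the characteristic bimodal shape of adipose tissue.
    """

    grid: DiameterGrid = field(default_factory=make_log_grid)
    schedule: list[int] = field(default_factory=biopsy_schedule)
    true_period: float = 56.0
    mode: str = "piecewise_constant"
    n_period_bins_true: int = 7
    small_mode: tuple[float, float] = (np.log(35.0), 0.22)
    large_mode: tuple[float, float] = (np.log(100.0), 0.30)
    w_small_base: float = 0.5
    w_small_amplitude: float = 0.2
    particles_per_measurement: int = 6000
    replicates_per_day: int = 4
    replicate_overrides: dict[int, int] = field(default_factory=dict)
    measurement_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_period <= 0:
            raise ValueError("true_period must be positive")
        if self.particles_per_measurement < 1:
            raise ValueError("particles_per_measurement must be >= 1")
        if self.mode not in ("piecewise_constant", "smooth"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lo = self.w_small_base - self.w_small_amplitude
        hi = self.w_small_base + self.w_small_amplitude
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError(
                f"small-mode weight escapes [0,1]: range [{lo:.3f}, {hi:.3f}]"
            )
        if self.mode == "piecewise_constant" and self.n_period_bins_true < 1:
            raise ValueError("n_period_bins_true must be >= 1")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["grid"] = {"n_bins": self.grid.n_bins, "d_min": self.grid.d_min,
                     "d_max": self.grid.d_max}
        return d


@dataclass
class TrueSignal:
    """Noise-free per-day bin probabilities: the generator's ground truth."""

    days: list[int]
    probabilities: np.ndarray  # (n_days, n_bins), rows sum to 1
    w_small: list[float]
    true_period: float
    mode: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "days": self.days,
                    "w_small": self.w_small,
                    "true_period": self.true_period,
                    "mode": self.mode,
                    "probabilities": self.probabilities.tolist(),
                },
                fh,
                indent=1,
            )


def _mode_bin_probs(grid: DiameterGrid, loc: float, scale: float) -> np.ndarray:
    """Probability mass of LN(loc, scale) in each grid bin, renormalized to the grid."""
    z = (np.log(grid.edges) - loc) / scale
    cdf = norm.cdf(z)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise ValueError("lognormal mode places no mass on the diameter grid")
    return mass / total


def _w_small_of_day(day: float, config: GeneratorConfig) -> float:
    if config.mode == "smooth":
        return config.w_small_base + config.w_small_amplitude * np.sin(
            2.0 * np.pi * day / config.true_period
        )
    width = config.true_period / config.n_period_bins_true
    b = int(day // width) % config.n_period_bins_true
    # per-period-bin offsets sampled from one sine cycle at bin midpoints
    return config.w_small_base + config.w_small_amplitude * np.sin(
        2.0 * np.pi * (b + 0.5) / config.n_period_bins_true
    )


def true_distribution(day: float, config: GeneratorConfig) -> np.ndarray:
    """Noise-free bin-probability vector for one day: a two-mode lognormal mixture."""
    w = _w_small_of_day(day, config)
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"small-mode weight {w:.3f} outside [0,1] on day {day}")
    p = w * _mode_bin_probs(config.grid, *config.small_mode) + (1.0 - w) * _mode_bin_probs(
        config.grid, *config.large_mode
    )
    return p / p.sum()


def sample_dataset(
    config: GeneratorConfig, animal_id: str = "synthetic"
) -> tuple[LongitudinalDataset, TrueSignal]:
    """Draw one synthetic longitudinal dataset.

    Per scheduled day and replicate: multinomial particle counting from the
    day's true bin probabilities, then independent multiplicative lognormal
    per-bin noise with the configured coefficient of variation, then
    renormalization to percentages.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    days = sorted(config.schedule)
    if days and days[0] != 0:
        raise ValueError("schedule must start at day 0")
    probs = np.array([true_distribution(d, config) for d in days])
    signal = TrueSignal(
        days=list(days),
        probabilities=probs,
        w_small=[float(_w_small_of_day(d, config)) for d in days],
        true_period=config.true_period,
        mode=config.mode,
    )
    cv = config.measurement_noise_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    measurements = []
    for day, p in zip(days, probs):
        n_rep = config.replicate_overrides.get(day, config.replicates_per_day)
        for rep in range(n_rep):
            counts = rng.multinomial(config.particles_per_measurement, p).astype(float)
            if sigma > 0:
                # mean-one multiplicative lognormal noise per bin
                counts *= rng.lognormal(-0.5 * sigma * sigma, sigma, size=counts.shape)
            total = counts.sum()
            if total <= 0:  # pragma: no cover - requires pathological config
                raise RuntimeError(f"all-zero measurement drawn on day {day}")
            measurements.append(
                SizeDistribution(day=int(day), replicate_id=f"r{rep + 1}",
                                 values=100.0 * counts / total)
            )
    dataset = LongitudinalDataset(animal_id=animal_id, grid=config.grid,
                                  measurements=measurements)
    return dataset, signal
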