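"""Discrete periodic models of an irregular biopsy schedule.

A periodic model divides a period of ``T = n_bins * bin_width`` days into
``n_bins`` period-bins of ``bin_width`` days each, plus an integer phase
locating day 0 inside the first period-bin.  Each biopsy day is assigned the
period-bin ``floor((day + phase) / bin_width) mod n_bins``; the inference
downstream assumes the cell-size distribution is constant within a
period-bin across repetitions of the period.

Because sampling is sparse, distinct ``(bin_width, phase)`` parameterizations
can induce exactly the same day-to-bin assignment and are then empirically
indistinguishable: they are deduplicated into one model whose *period
ambiguity* is the spread of the generating periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeriodicModel",
    "ModelSpaceConfig",
    "ModelEnumeration",
    "assign_bins",
    "is_testable",
    "enumerate_models",
    "ambiguity_stats",
    "null_model",
    "models_to_frame",
]


@dataclass(frozen=True)
class PeriodicModel:
    """One deduplicated periodic model on a fixed day schedule."""

    n_bins: int
    bin_width: int
    phase: int
    assignment: tuple[int, ...]
    generating_combos: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def is_null(self) -> bool:
        return self.n_bins == 1

    @property
    def generating_periods(self) -> tuple[int, ...]:
        if not self.generating_combos:
            return (self.n_bins * self.bin_width,)
        return tuple(sorted({self.n_bins * w for w, _ in self.generating_combos}))

    @property
    def period_min(self) -> int:
        return self.generating_periods[0]

    @property
    def period_max(self) -> int:
        return self.generating_periods[-1]

    @property
    def period(self) -> float:
        """Representative period: midpoint of the generating-period range."""
        return 0.5 * (self.period_min + self.period_max)

    @property
    def period_ambiguity(self) -> int:
        return self.period_max - self.period_min

    def __repr__(self) -> str:  # compact, assignment elided
        tag = "null" if self.is_null else f"T={self.period:g}"
        return (
            f"PeriodicModel(n_bins={self.n_bins}, bin_width={self.bin_width}, "
            f"phase={self.phase}, {tag})"
        )


@dataclass
class ModelSpaceConfig:
    """Enumeration ranges and pruning bounds (all bounds inclusive)."""

    n_bins_min: int = 2
    n_bins_max: int = 10
    bin_width_min: int = 5
    bin_width_max: int = 50
    period_min: int = 30
    period_max: int = 100
    include_null: bool = True

    def __post_init__(self) -> None:
        if self.n_bins_min > self.n_bins_max or self.bin_width_min > self.bin_width_max:
            raise ValueError("empty enumeration range")
        if self.period_min >= self.period_max:
            raise ValueError("period_min must be < period_max")


def assign_bins(days, n_bins: int, bin_width: int, phase: int) -> tuple[int, ...]:
    """Map each biopsy day to its period-bin index.

    ``assignment[j] = floor((days[j] + phase) / bin_width) mod n_bins``.
    The phase must satisfy ``0 <= phase < bin_width`` (day 0 lies inside the
    first period-bin); larger phases are redundant up to bin relabeling.
    """
    if not (0 <= phase < bin_width):
        raise ValueError(f"phase must be in [0, bin_width), got {phase} for width {bin_width}")
    days = list(days)
    if any(d < 0 for d in days):
        raise ValueError("days must be non-negative")
    return tuple(int((d + phase) // bin_width) % n_bins for d in days)


def is_testable(assignment, n_bins: int) -> bool:
    """Whether every period-bin receives days that are not all contiguous.

    A period-bin whose occurrences form a single contiguous run of positions
    in the day sequence (including a single occurrence, or none) could look
    internally consistent merely because the underlying signal is continuous
    in time; such a model cannot test periodicity.
    """
    assignment = list(assignment)
    for b in range(n_bins):
        pos = [i for i, a in enumerate(assignment) if a == b]
        if len(pos) < 2:
            return False
        if pos[-1] - pos[0] + 1 == len(pos):  # one contiguous run
            return False
    return True


@dataclass
class ModelEnumeration:
    """Result of enumerate_models, keeping pre- and post-pruning views."""

    models: list[PeriodicModel]          # pruned, deduplicated, sorted
    n_raw_combos: int                    # all (n_bins, bin_width, phase) triples
    n_pre_pruning: int                   # deduplicated models before pruning
    n_rejected_untestable: int
    n_rejected_period: int

    @property
    def n_post_pruning(self) -> int:
        return len(self.models)


def enumerate_models(days, config: ModelSpaceConfig | None = None) -> ModelEnumeration:
    """Enumerate, deduplicate and prune the discrete periodic model space.

    Every ``(n_bins, bin_width, phase)`` triple in the configured ranges is
    mapped to its day-to-bin assignment; triples sharing ``(n_bins,
    assignment)`` are one model.  A model is kept if its assignment is
    testable and at least one generating period lies within
    ``[period_min, period_max]``.  Output order is deterministic:
    representative period, then n_bins, then assignment.
    """
    days = sorted(days)
    if len(days) < 2:
        raise ValueError("need at least two biopsy days")
    config = config or ModelSpaceConfig()

    groups: dict[tuple[int, tuple[int, ...]], set[tuple[int, int]]] = {}
    n_raw = 0
    for n_bins in range(config.n_bins_min, config.n_bins_max + 1):
        for width in range(config.bin_width_min, config.bin_width_max + 1):
            for phase in range(width):
                n_raw += 1
                a = assign_bins(days, n_bins, width, phase)
                groups.setdefault((n_bins, a), set()).add((width, phase))

    kept: list[PeriodicModel] = []
    n_untestable = 0
    n_period = 0
    for (n_bins, a), combos in groups.items():
        if not is_testable(a, n_bins):
            n_untestable += 1
            continue
        periods = {n_bins * w for w, _ in combos}
        if not any(config.period_min <= T <= config.period_max for T in periods):
            n_period += 1
            continue
        width, phase = min(combos)
        kept.append(
            PeriodicModel(
                n_bins=n_bins,
                bin_width=width,
                phase=phase,
                assignment=a,
                generating_combos=frozenset(combos),
            )
        )
    kept.sort(key=lambda m: (m.period, m.n_bins, m.assignment))
    return ModelEnumeration(
        models=kept,
        n_raw_combos=n_raw,
        n_pre_pruning=len(groups),
        n_rejected_untestable=n_untestable,
        n_rejected_period=n_period,
    )


def ambiguity_stats(models) -> tuple[float, int]:
    """(mean, max) period ambiguity in days over a model list."""
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    ambs = [m.period_ambiguity for m in models]
    return float(np.mean(ambs)), int(max(ambs))


def null_model(days) -> PeriodicModel:
    """The no-period model: a single bin receiving every day."""
    days = list(days)
    if not days:
        raise ValueError("empty day list")
    return PeriodicModel(
        n_bins=1, bin_width=1, phase=0, assignment=tuple(0 for _ in days),
        generating_combos=frozenset(),
    )


def models_to_frame(models) -> pd.DataFrame:
    """Model list as a flat table (one row per model)."""
    rows = []
    for m in models:
        rows.append(
            {
                "n_bins": m.n_bins,
                "bin_width": m.bin_width,
                "phase": m.phase,
                "period_min": m.period_min,
                "period_max": m.period_max,
                "representative_period": m.period,
                "ambiguity": m.period_ambiguity,
                "assignment": "-".join(map(str, m.assignment)),
            }
        )
    return pd.DataFrame(rows)
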