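import numpy as np
import pytest

from adipowaves.distributions import (
    LongitudinalDataset,
    SizeDistribution,
    make_log_grid,
)


def build_dataset(values_by_day: dict[int, list[list[float]]], n_bins: int,
                  animal_id: str = "test") -> LongitudinalDataset:
    """Dataset from {day: [replicate percentage vectors]} (vectors sum to 100)."""
    grid = make_log_grid(n_bins)
    measurements = [
        SizeDistribution(day=day, replicate_id=f"r{i + 1}", values=np.asarray(v, float))
        for day, reps in values_by_day.items()
        for i, v in enumerate(reps)
    ]
    return LongitudinalDataset(animal_id=animal_id, grid=grid, measurements=measurements)


@pytest.fixture
def three_day_dataset() -> LongitudinalDataset:
    """Two-bin dataset over three days with two replicates each."""
    return build_dataset(
        {
            0: [[30.0, 70.0], [34.0, 66.0]],
            5: [[50.0, 50.0], [46.0, 54.0]],
            10: [[20.0, 80.0], [24.0, 76.0]],
        },
        n_bins=2,
    )
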