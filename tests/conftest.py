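import numpy as np
import pandas as pd
import pytest

from emadyn import HarmonicCurve, SimulationConfig

ITEMS = ("anxious", "stressed", "sleepy", "down")


def single_item_config(**overrides) -> SimulationConfig:
    """One-item generator used by the heavier simulation studies."""
    defaults = dict(
        items=("anxious",),
        baseline_curve={
            "anxious": HarmonicCurve(1.8, ((1, 0.3, 20.0), (2, 0.25, 8.0)))
        },
        isi_level_slope={"anxious": 0.118},
        interaction_amplitude={"anxious": 0.0},
        interaction_windows={"anxious": ()},
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_records():
    from emadyn import simulate_dataset

    cfg = SimulationConfig(n_participants=20, seed=42)
    records, truth = simulate_dataset(cfg)
    return records, truth, cfg


def toy_fixture():
    """Five-participant fixture exercising the QC boundary cases.

    p1 completes all six occasions; p2 exactly three (boundary: retained);
    p3 only two (excluded); p4 completes all six but failed one quality
    check (boundary: retained); p5 completes all six, no failures.
    """
    rows = []
    completed = {1: [1, 2, 3, 4, 5, 6], 2: [1, 3, 5], 3: [2, 4], 4: list(range(1, 7)), 5: list(range(1, 7))}
    times = {j: 8.5 + 2.9 * (j - 1) for j in range(1, 7)}
    for pid, done in completed.items():
        for j in range(1, 7):
            for item in ITEMS:
                rows.append(
                    {
                        "participant_id": pid,
                        "isi": 5 * pid % 28,
                        "assessment_index": j,
                        "time_of_day": times[j],
                        "item": item,
                        "rating": float((pid + j) % 9) if j in done else np.nan,
                    }
                )
    records = pd.DataFrame(rows)
    checks = pd.DataFrame(
        {"participant_id": [1, 2, 3, 4, 5], "failed_checks": [0, 0, 0, 1, 0]}
    )
    return records, checks
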