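"""Shared fixtures: a hand-scored mini score table and one default colony."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from colonywatch.simulate import SimulationTruth, simulate_colony


def _mini_rows():
    """5 sites × 10 days × 3 images, subcolony 1, season 2018/19.

    Day 105 is a camera outage (no images).  The per-site count patterns
    are chosen so every metric is hand-computable; the expected values live
    in HAND_EXPECTED below.
    """
    days = [d for d in range(100, 110) if d != 105]
    times = [480, 510, 540]
    counts = {
        # site: {day: (c1, c2, c3)}
        "A": {d: (1, 1, 1) for d in days},
        "B": {d: ((2, 0, 0) if d in (102, 104, 106, 108) else (0, 0, 0))
              for d in days},
        "C": {d: ((0, 0, 1) if d == 109 else (0, 0, 0)) for d in days},
        "D": {d: (0, 0, 0) for d in days},
        "E": {d: ((0, 1, 2) if d == 100 else (1, 0, 0) if d == 101
                  else (0, 0, 0)) for d in days},
    }
    sep1 = pd.Timestamp("2018-09-01")
    rows = []
    for site, per_day in counts.items():
        for d in days:
            for t, c in zip(times, per_day[d]):
                rows.append({
                    "subcolony": 1, "site_id": site, "season": "2018/19",
                    "date": (sep1 + pd.Timedelta(days=d)).date().isoformat(),
                    "time": t, "count": c, "season_day": d,
                })
    return pd.DataFrame(rows)


#: hand-computed per-site expectations for the mini table, by filter
HAND_EXPECTED = {
    # filter: {site: (return_day, freq_num, freq_den, rti_num, rti_den)}
    "any": {
        "A": (100, 9, 9, 27, 27),
        "B": (102, 4, 7, 4, 21),
        "C": (109, 1, 1, 1, 3),
        "D": (None, 0, 0, 0, 0),
        "E": (100, 2, 9, 3, 27),
    },
    "pair": {
        "A": (None, 0, 0, 0, 0),
        "B": (102, 4, 7, 4, 21),
        "C": (None, 0, 0, 0, 0),
        "D": (None, 0, 0, 0, 0),
        "E": (100, 1, 9, 1, 27),
    },
    "single": {
        "A": (100, 9, 9, 27, 27),
        "B": (None, 0, 0, 0, 0),
        "C": (109, 1, 1, 1, 3),
        "D": (None, 0, 0, 0, 0),
        "E": (100, 2, 9, 2, 27),
    },
}


@pytest.fixture(scope="session")
def mini_scores() -> pd.DataFrame:
    return _mini_rows()


@pytest.fixture(scope="session")
def default_colony():
    """One default-condition synthetic colony, shared across tests."""
    return simulate_colony(SimulationTruth(seed=7))


@pytest.fixture(scope="session")
def default_metrics(default_colony):
    from colonywatch.metrics import occupancy_metrics

    return occupancy_metrics(default_colony.image_scores)


@pytest.fixture(scope="session")
def analysis_table(default_colony, default_metrics):
    from colonywatch.io import build_analysis_table

    return build_analysis_table(default_metrics, default_colony.sites,
                                default_colony.breeding)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
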