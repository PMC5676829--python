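"""Shared fixtures: synthetic gaze frames and a canonical ROI layout."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from socialgaze.io import SAMPLE_INTERVAL_MS
from socialgaze.simulate import CohortParams, default_roi_set, default_trial_infos


def make_gaze(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    validity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binocular gaze frame with zero disparity (left == right == position).

    Samples with validity > 1 get their positions blanked, mirroring how
    a tracker reports untracked eyes.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    v = np.zeros(len(t), dtype=int) if validity is None else np.asarray(validity)
    lost = v > 1
    x[lost] = np.nan
    y[lost] = np.nan
    return pd.DataFrame(
        {
            "t_ms": t,
            "left_x": x,
            "left_y": y,
            "left_validity": v,
            "right_x": x.copy(),
            "right_y": y.copy(),
            "right_validity": v.copy(),
        }
    )


def sample_times(n: int, t0: float = 0.0) -> np.ndarray:
    return t0 + np.arange(n) * SAMPLE_INTERVAL_MS


@pytest.fixture(scope="session")
def roi_set():
    return default_roi_set()


@pytest.fixture(scope="session")
def trial_infos():
    return default_trial_infos()


@pytest.fixture(scope="session")
def small_cohort_params():
    return CohortParams(n_participants=12, seed=11)
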