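import numpy as np
import pandas as pd
import pytest

import endotyper as et
from endotyper.episodes import extract_cohort_points


@pytest.fixture(scope="session")
def small_direct_cohort():
    """Small direct-mode cohort with planted Table-style endotypes."""
    cfg = et.CohortConfig(n_patients=40, points_per_patient=200, mode="direct", seed=101)
    return et.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_consistent_cohort():
    cfg = et.CohortConfig(n_patients=20, points_per_patient=150, mode="consistent", seed=202)
    return et.generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_points(small_direct_cohort):
    """Analysis point set of the small direct cohort, with true labels attached."""
    coh = small_direct_cohort
    pts = extract_cohort_points(coh.frame)
    truth = coh.truth.set_index(["patient_id", "time_s"])
    true = truth.loc[list(zip(pts.patient_id, pts.time_s)), "true_endotype"].to_numpy()
    return pts, true


def make_series(map_values, patient_id="P1", start_s=0.0, grid_s=20.0, gaps_at=()):
    """Build a single-patient frame from a MAP sequence; indices in
    ``gaps_at`` get an extra grid step inserted before them (a missing point)."""
    t = []
    cur = start_s
    for i, _ in enumerate(map_values):
        if i in gaps_at:
            cur += grid_s
        t.append(cur)
        cur += grid_s
    n = len(map_values)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "time_s": t,
            "map": np.asarray(map_values, dtype=float),
            "svi": np.full(n, 40.0),
            "hr": np.full(n, 80.0),
            "svv": np.full(n, 10.0),
            "dpdt": np.full(n, 600.0),
            "quality_ok": 1,
        }
    )
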