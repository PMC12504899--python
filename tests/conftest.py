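import pandas as pd
import pytest

from vbmon.pipeline import analyze_dataset
from vbmon.simulate import CohortConfig, simulate_cohort_with_truth


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size simulated cohort with its latent truth (seed fixed)."""
    ds, truth = simulate_cohort_with_truth(CohortConfig(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def analyzed(default_cohort):
    """Pipeline result for the shared cohort."""
    ds, _ = default_cohort
    return analyze_dataset(ds)


def make_scored(rows):
    """Small labeled-session frame from (pid, time, score, state[, extra]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        pid, t, score, state = row[:4]
        rec = {
            "session_id": i,
            "participant_id": pid,
            "session_time": pd.Timestamp(t),
            "final_score": float(score),
            "state": state,
            "normalized_score": float("nan"),
        }
        if len(row) > 4:
            rec.update(row[4])
        recs.append(rec)
    return pd.DataFrame(recs)
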