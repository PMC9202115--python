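import numpy as np
import pandas as pd
import pytest

import randaudit as ra


@pytest.fixture(scope="session")
def trial_frame() -> pd.DataFrame:
    """One clean synthetic trial at the default (audited-trial) scale."""
    return ra.simulate_trial(ra.SimConfig(seed=123))


@pytest.fixture
def six_row_csv(tmp_path):
    """Tiny hand-written table in the fixture dialect: 3 treatment, 3 control."""
    path = tmp_path / "six.csv"
    path.write_text(
        "participant_id,clinical_center,time_stratum,arm,nihss_baseline,mrs_90d\n"
        "p1,C01,early,treatment,10,1\n"
        "p2,C01,early,control,12,3\n"
        "p3,C01,late,treatment,8,0\n"
        "p4,C02,late,control,20,4\n"
        "p5,C02,early,treatment,15,2\n"
        "p6,C02,late,control,11,1\n"
    )
    return path


@pytest.fixture
def small_frame() -> pd.DataFrame:
    """Deterministic 40-row frame with two centers fully crossed."""
    rng = np.random.default_rng(5)
    n = 40
    frame = pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "clinical_center": np.repeat(["C01", "C02"], n // 2),
            "time_stratum": np.tile(["early", "late"], n // 2),
            "arm": np.tile(["treatment", "control"], n // 2),
            "enrollment_index": np.arange(1, n + 1),
            "nihss_baseline": rng.integers(0, 30, n),
            "mrs_90d": rng.integers(0, 6, n),
        }
    )
    return frame
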