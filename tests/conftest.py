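"""Shared fixtures: expensive synthetic datasets built once per session."""

import numpy as np
import pandas as pd
import pytest

from pulseman import activity, bp_estimation
from pulseman.signal_quality import preprocess_ppg
from pulseman.synth import (PPGSessionSpec, gen_activity_session,
                            gen_ppg_session, gen_wellbeing_dataset)


@pytest.fixture(scope="session")
def personal_bp_instances():
    """Labelled per-cycle instances of one simulated 4-h wear session
    (generator defaults: 64 Hz, 5% noise, cuff readings every 30 min)."""
    spec = PPGSessionSpec(seed=7)
    ppg, accel, readings, gt = gen_ppg_session(spec)
    screened = preprocess_ppg(ppg)
    rt = readings["timestamp_s"].to_numpy()
    fs = spec.sampling_rate
    near = [c for c in screened.kept_cycles
            if np.min(np.abs(rt - c.systolic_peak / fs)) <= 35.0]
    feats = bp_estimation.build_feature_table(screened.signal, near, accel)
    inst = bp_estimation.pair_with_ground_truth(feats, readings)
    return inst


@pytest.fixture(scope="session")
def activity_table_6subjects():
    """Window-feature table of the 6-subject, 5-regime scenario."""
    script = [("rest", 40.0), ("walking", 40.0), ("running", 40.0),
              ("eating", 40.0), ("chores", 40.0)]
    tables = []
    for i in range(6):
        stream = gen_activity_session(script, rate=50.0, seed=100 + i,
                                      subject_id=f"s{i}")
        windows = activity.segment_windows(stream, 50.0)
        tables.append(activity.windows_to_table(windows))
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def wellbeing():
    """Default well-being table (n=500, 2% label noise) with ground truth."""
    df, gt = gen_wellbeing_dataset(n=500, noise=0.02, seed=11)
    return df, gt
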