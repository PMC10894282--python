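import numpy as np
import pandas as pd
import pytest

from myorsa import reduced_protocol


@pytest.fixture(scope="session")
def reduced_cfg():
    """Scaled-down protocol: 5 movements, 4 channels, 6 reps, 500 Hz."""
    return reduced_protocol()


def make_feature_table(values_by_channel, limb="unaffected", movement="IF",
                       phase="contraction"):
    """Tidy feature table from {channel: [per-repetition values]} where the
    same value feeds rms and mnf columns (plus normalised copies)."""
    rows = []
    for channel, vals in values_by_channel.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({"limb": limb, "movement": movement,
                         "repetition": rep, "phase": phase,
                         "channel": channel, "rms": v, "mnf": v,
                         "rms_norm": v, "mnf_norm": v})
    return pd.DataFrame(rows, columns=["limb", "movement", "repetition",
                                       "phase", "channel", "rms", "mnf",
                                       "rms_norm", "mnf_norm"])


def make_summary(vectors, limb="unaffected", measure="RMS",
                 statistic="median"):
    """Channel-summary frame from {movement: per-channel vector}."""
    rows = []
    for movement, vec in vectors.items():
        for ch, v in enumerate(np.asarray(vec, dtype=float), start=1):
            row = {"limb": limb, "movement": movement, "channel": ch,
                   "measure": measure, "median": 0.0, "iqr": 0.0}
            row[statistic] = v
            rows.append(row)
    return pd.DataFrame(rows)
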