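"""Extract RMS/MNF features and score within-movement consistency.

Every trimmed repetition yields one RMS (amplitude) and one MNF (mean
frequency) value per channel, normalised per channel to a percentage of
its maximum.  Kendall's W then scores how consistently each movement's
channel pattern recurs across the 6 repetitions: W near 1 means the
channels rank the same way every time.
"""

import pandas as pd

from myorsa import reduced_protocol, generate_cohort, consistency_table
from myorsa.pipeline import extract_features

config = reduced_protocol()
rec_u, rec_a = generate_cohort(config, distinctness=0.8, fidelity=0.9,
                               attenuation=0.8, seed=42,
                               rep_jitter_sd=0.1)
table = pd.concat([extract_features(rec_u, config),
                   extract_features(rec_a, config)], ignore_index=True)

print("feature table (one row per limb/movement/repetition/phase/channel):")
print(table.head(3).to_string(index=False))

cons = consistency_table(table)
print("\nper-movement consistency (Kendall's W with strength category):")
print(cons.to_string(index=False))
print("\nWith low repetition jitter the unaffected limb shows mostly "
      "moderate-to-strong consistency (W >= 0.60); the degraded affected "
      "limb tracks it closely at fidelity 0.9.")
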