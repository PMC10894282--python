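"""Compare the two limbs: consistency difference and RDM relatedness.

The per-movement Kendall's W values of the affected limb are compared to
the unaffected limb's with an exact paired Wilcoxon signed-rank test.
Separately, the two limbs' (unsplit) RDMs are correlated with Kendall's
tau-a and tested with a label-randomisation null that permutes the rows
and columns of the affected RDM.
"""

import pandas as pd

from myorsa import (reduced_protocol, generate_cohort, consistency_table,
                    limb_comparison_table)
from myorsa.pipeline import extract_features, relatedness_results_table

config = reduced_protocol()
rec_u, rec_a = generate_cohort(config, distinctness=0.8, fidelity=0.9,
                               attenuation=0.8, seed=42)
table = pd.concat([extract_features(rec_u, config),
                   extract_features(rec_a, config)], ignore_index=True)

comparison = limb_comparison_table(consistency_table(table))
print("across-limb consistency (exact Wilcoxon signed-rank):")
print(comparison.to_string(index=False))

relatedness = relatedness_results_table(table, seed=0,
                                        n_permutations=10_000)
print("\nacross-limb RDM relatedness (tau-a label randomisation):")
print(relatedness.to_string(index=False))
print("\nSmall relatedness p-values mean the affected limb's movement "
      "structure mirrors the unaffected limb's — expected here because "
      "the affected profile keeps 90% fidelity.")
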