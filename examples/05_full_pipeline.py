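"""Run the full pipeline end to end and list the exported artifacts.

`run_pipeline` simulates a two-limb session, extracts features, scores
consistency, builds RDMs/sdRDMs, runs the EDI and relatedness tests,
embeds each RDM with nonmetric MDS, and writes every table as delimited
text plus a manifest of SHA-256 digests (same seed -> byte-identical run).
"""

import tempfile
from pathlib import Path

from myorsa import reduced_protocol, run_pipeline

out = Path(tempfile.mkdtemp()) / "run"
manifest = run_pipeline(reduced_protocol(), out, seed=7,
                        analysis={"n_permutations": 5000,
                                  "edi_draws": 5000})

print(f"artifacts written to {out}:")
for name in sorted(manifest.digests):
    print(f"  {name}")
print(f"\nclipped-sample fraction per limb: {manifest.clipped_fraction}")
print("re-running with the same seed reproduces identical digests; "
      "see manifest.json")
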