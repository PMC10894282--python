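"""Test whether movements are distinguishable: split-data RDM and EDI.

Repetitions are split into even and odd halves; each movement is summarised
by its per-channel median (or IQR) of normalised RMS/MNF, and movements are
compared with the rank-correlation distance 1 - Kendall's tau-b.  The
exemplar discriminability index (EDI) — mean between-movement distance
minus mean within-movement (diagonal) distance — is tested against an
exhaustive row-permutation null.
"""

from myorsa import reduced_protocol, generate_cohort, \
    edi_randomization_test
from myorsa.pipeline import extract_features, limb_rdms

config = reduced_protocol()
rec_u, _ = generate_cohort(config, distinctness=0.8, fidelity=0.9,
                           attenuation=0.8, seed=42)
table = extract_features(rec_u, config)
rdms, sdrdms = limb_rdms(table, "unaffected")

sdrdm = sdrdms["RMS-median"]
print("split-data RDM (rows: even split, cols: odd split):")
print(sdrdm.matrix.round(3))

res = edi_randomization_test(sdrdm, mode="exhaustive")
print(f"\nEDI = {res.edi:.3f}  (null of {res.null_size} row permutations)")
print(f"p (>= counting) = {res.p:.4f}, mid-p = {res.p_mid:.4f}")
print("\nA positive EDI with small p means the movements' excitation "
      "patterns are reliably distinguishable — the within-movement "
      "distances on the diagonal are smaller than the between-movement "
      "distances.")
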