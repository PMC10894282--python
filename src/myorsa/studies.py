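"""Seeded simulation studies of the pipeline's statistical behaviour.

These drive the full chain (generator → features → split-data RDM → EDI /
relatedness tests) over many small synthetic sessions to measure null
calibration and power under controlled conditions.  Sessions use the
scaled-down protocol (5 movements, 4 channels, 6 repetitions, 500 Hz with
a 20–200 Hz band) so that hundreds of cohorts run in minutes.

Decisions use the tie-split mid-p at α = 0.05: with few channels the
rank-correlation distances are lattice-valued, the permutation null is
heavily tied, and the conservative ≥-counting p would be essentially
powerless at this scale (see `EDIResult`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .protocol import reduced_protocol, ProtocolConfig
from .simulate import generate_activation_profile, generate_recording, \
    generate_cohort
from .pipeline import extract_features, limb_rdms
from .dissimilarity import edi_randomization_test, rdm_relatedness_test
from .consistency import consistency_table

ALPHA = 0.05


def _study_config(n_movements: int = 5) -> ProtocolConfig:
    return reduced_protocol(n_movements=n_movements)


def single_limb_edi(seed: int, distinctness: float, gain: float = 4.0,
                    rep_jitter_sd: float = 0.2,
                    measure: str = "RMS-median",
                    config: ProtocolConfig | None = None):
    """Generate one limb's session and run the exhaustive EDI test."""
    config = config or _study_config()
    profile = generate_activation_profile(
        len(config.movements), config.n_channels_unaffected, distinctness,
        seed, band=config.band, rep_jitter_sd=rep_jitter_sd, gain=gain)
    recording = generate_recording(config, profile, "unaffected", seed + 1)
    table = extract_features(recording, config)
    _, sdrdms = limb_rdms(table, "unaffected")
    return edi_randomization_test(sdrdms[measure], mode="exhaustive")


def edi_rejection_rate(n_cohorts: int, distinctness: float, seed: int,
                       gain: float = 4.0, rep_jitter_sd: float = 0.2,
                       alpha: float = ALPHA) -> float:
    """Fraction of seeded cohorts whose EDI mid-p falls at or below alpha."""
    hits = sum(
        single_limb_edi(seed + k, distinctness, gain,
                        rep_jitter_sd).p_mid <= alpha
        for k in range(n_cohorts))
    return hits / n_cohorts


def relatedness_rejection_rate(n_cohorts: int, fidelity: float, seed: int,
                               distinctness: float = 0.9,
                               attenuation: float = 0.8,
                               n_permutations: int = 3000,
                               measure: str = "RMS-median",
                               alpha: float = ALPHA) -> float:
    """Fraction of two-limb cohorts whose RDM relatedness p < alpha."""
    config = _study_config()
    hits = 0
    for k in range(n_cohorts):
        rec_u, rec_a = generate_cohort(config, distinctness, fidelity,
                                       attenuation, seed + k)
        table = pd.concat([extract_features(rec_u, config),
                           extract_features(rec_a, config)],
                          ignore_index=True)
        rdms = {limb: limb_rdms(table, limb)[0]
                for limb in ("affected", "unaffected")}
        res = rdm_relatedness_test(rdms["affected"][measure],
                                   rdms["unaffected"][measure],
                                   n_permutations=n_permutations,
                                   seed=seed + k)
        hits += res.p < alpha
    return hits / n_cohorts


def consistency_profile(seed: int, rep_jitter_sd: float = 0.05,
                        distinctness: float = 0.8, gain: float = 2.0
                        ) -> np.ndarray:
    """Per-movement RMS Kendall's W of one 10-movement low-jitter session."""
    config = _study_config(n_movements=10)
    profile = generate_activation_profile(
        10, config.n_channels_unaffected, distinctness, seed,
        band=config.band, rep_jitter_sd=rep_jitter_sd, gain=gain)
    recording = generate_recording(config, profile, "unaffected", seed + 1)
    table = extract_features(recording, config)
    cons = consistency_table(table)
    return cons[cons["measure"] == "RMS"]["W"].to_numpy()
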