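"""Seeded synthetic two-limb sEMG session generator.

The real sessions this package analyses cannot be redistributed, so this
module produces surrogate recordings that reproduce the protocol's
*structure*: multi-channel band-limited voltage traces with a known
relaxation/contraction schedule, movement-specific per-channel activation
patterns (amplitude and spectral content), repetition-to-repetition
variability, and an "affected" limb whose activation structure is a noisy,
attenuated copy of the "unaffected" limb's.

Carrier model
-------------
Every phase segment is Gaussian noise synthesised in the frequency domain
and confined to the configured band.  Relaxation segments carry baseline
noise only (standard deviation ``baseline_sd``).  Contraction segments add
an excitation component with a Gaussian spectral bump centred at the
movement/channel ``spectral_center`` so that both amplitude (RMS) and mean
frequency (MNF) carry movement information.  The per-channel contraction
standard deviation is

    baseline_sd * (1 + gain * weight * jitter)

where ``jitter = exp(N(0, rep_jitter_sd))`` is redrawn per repetition.
All randomness descends from one integer seed through a
``numpy.random.SeedSequence`` tree split per (movement, trial, cycle), so
the same seed reproduces a session byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .protocol import ProtocolConfig, LIMBS

logger = logging.getLogger(__name__)

#: Width of the excitation spectral bump, as a fraction of the band width.
SPECTRAL_BW_FRAC = 0.08
#: Spectral centres are drawn in this fractional range of the band, keeping
#: the bump comfortably inside the pass-band.
_CENTER_FRAC = (0.15, 0.85)

SCHEDULE_COLUMNS = ("movement", "trial", "cycle", "phase",
                    "start_sample", "end_sample")


@dataclass(frozen=True)
class ActivationProfile:
    """Movement × channel activation structure of one limb.

    ``weights`` in [0, 1] scale contraction amplitude; ``spectral_centers``
    (Hz, strictly inside ``band``) set each movement/channel's dominant
    frequency.  ``rep_jitter_sd`` is the log-normal sigma of the
    multiplicative repetition jitter; ``baseline_sd`` (mV) the resting noise
    floor; ``gain`` the maximal excitation-to-baseline amplitude ratio.
    """

    weights: np.ndarray
    spectral_centers: np.ndarray
    band: tuple[float, float]
    rep_jitter_sd: float = 0.2
    baseline_sd: float = 0.05
    gain: float = 4.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        c = np.asarray(self.spectral_centers, dtype=float)
        if w.ndim != 2 or c.shape != w.shape:
            raise ValueError("weights and spectral_centers must be "
                             "matching 2-D movement×channel matrices")
        if not (np.isfinite(w).all() and (w >= 0).all() and (w <= 1).all()):
            raise ValueError("weights must lie in [0, 1]")
        lo, hi = self.band
        if not ((c > lo) & (c < hi)).all():
            raise ValueError("spectral_centers must lie strictly inside band")
        if self.rep_jitter_sd < 0:
            raise ValueError("rep_jitter_sd must be >= 0")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "spectral_centers", c)

    @property
    def n_movements(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]


@dataclass
class RawRecording:
    """One limb's continuous multi-channel recording plus its schedule.

    ``signal`` is channels × samples in mV; ``schedule`` is a DataFrame
    with columns (movement, trial, cycle, phase, start_sample, end_sample)
    using 0-based half-open sample intervals; ``clipped_fraction`` is the
    fraction of samples that hit the ADC rails.
    """

    limb: str
    signal: np.ndarray
    sampling_rate: float
    schedule: pd.DataFrame
    clipped_fraction: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a finite value in [0, 1], "
                         f"got {value!r}")
    return value


def generate_activation_profile(
    n_movements: int,
    n_channels: int,
    distinctness: float,
    seed: int,
    band: tuple[float, float] = (20.0, 450.0),
    rep_jitter_sd: float = 0.2,
    baseline_sd: float = 0.05,
    gain: float = 4.0,
) -> ActivationProfile:
    """Draw a movement×channel activation profile.

    ``distinctness`` in [0, 1] interpolates between one flat shared
    activation row for all movements (0: movements indistinguishable —
    uniform mean excitation across channels, so that under this null the
    channel ordering of any repetition is driven entirely by
    repetition-to-repetition variability, giving the downstream
    discriminability test an exchangeable, non-degenerate null) and fully
    independent movement-specific rows (1).  Deterministic for a fixed
    seed.
    """
    if n_movements < 1 or n_channels < 1:
        raise ValueError("counts must be >= 1")
    d = _check_unit_interval("distinctness", distinctness)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    base_w = np.full((1, n_channels), 0.5)
    uniq_w = rng.uniform(0.0, 1.0, size=(n_movements, n_channels))
    weights = (1.0 - d) * base_w + d * uniq_w

    lo_f, hi_f = _CENTER_FRAC
    base_c = np.full((1, n_channels), 0.5 * (lo_f + hi_f))
    uniq_c = rng.uniform(lo_f, hi_f, size=(n_movements, n_channels))
    frac = (1.0 - d) * base_c + d * uniq_c
    lo, hi = band
    centers = lo + frac * (hi - lo)
    return ActivationProfile(weights, centers, (float(lo), float(hi)),
                             rep_jitter_sd, baseline_sd, gain)


def derive_affected_profile(
    profile: ActivationProfile,
    fidelity: float,
    attenuation: float,
    seed: int,
) -> ActivationProfile:
    """Derive an affected-limb profile as a degraded copy.

    ``fidelity`` in [0, 1] mixes the source profile with an independent
    fresh draw (1 keeps the structure, 0 discards it); ``attenuation`` in
    (0, 1] then scales the weights (clipped to [0, 1]).  With fidelity 1
    and attenuation 1 the profile is returned unchanged.
    """
    f = _check_unit_interval("fidelity", fidelity)
    a = float(attenuation)
    if not (0.0 < a <= 1.0):
        raise ValueError("attenuation must lie in (0, 1]")
    if f == 1.0 and a == 1.0:
        return profile
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    fresh_w = rng.uniform(0.0, 1.0, size=profile.weights.shape)
    lo_f, hi_f = _CENTER_FRAC
    fresh_frac = rng.uniform(lo_f, hi_f, size=profile.weights.shape)
    lo, hi = profile.band
    fresh_c = lo + fresh_frac * (hi - lo)

    weights = np.clip(a * (f * profile.weights + (1.0 - f) * fresh_w),
                      0.0, 1.0)
    centers = f * profile.spectral_centers + (1.0 - f) * fresh_c
    return replace(profile, weights=weights, spectral_centers=centers)


def build_schedule(config: ProtocolConfig) -> pd.DataFrame:
    """Lay out the trial schedule: movements × trials × cycles × 2 phases."""
    rows = []
    cursor = 0
    relax_n = config.phase_samples("relaxation")
    contract_n = config.phase_samples("contraction")
    for movement in config.movements:
        for trial in range(1, config.trials + 1):
            for cycle in range(1, config.cycles_per_trial + 1):
                rows.append((movement, trial, cycle, "relaxation",
                             cursor, cursor + relax_n))
                cursor += relax_n
                rows.append((movement, trial, cycle, "contraction",
                             cursor, cursor + contract_n))
                cursor += contract_n
    return pd.DataFrame(rows, columns=list(SCHEDULE_COLUMNS))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float],
                center: float | None = None) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band``.

    Synthesised in the frequency domain: complex Gaussian coefficients
    shaped by a flat in-band envelope, optionally multiplied by a Gaussian
    bump at ``center`` (width SPECTRAL_BW_FRAC of the band width).
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    lo, hi = band
    env = ((freqs > lo) & (freqs < hi)).astype(float)
    if center is not None:
        bw = SPECTRAL_BW_FRAC * (hi - lo)
        env *= np.exp(-0.5 * ((freqs - center) / bw) ** 2)
    coef = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    x = np.fft.irfft(coef * env, n=n)
    sd = x.std()
    if sd == 0:
        return x
    return x / sd


def generate_recording(
    config: ProtocolConfig,
    profile: ActivationProfile,
    limb: str,
    seed: int,
) -> RawRecording:
    """Synthesise one limb's full session recording.

    Relaxation segments carry baseline noise only; contraction segments add
    movement/channel-specific excitation so that the per-channel standard
    deviation equals ``baseline_sd * (1 + gain * weight * jitter)``.
    The signal is clipped to the configured ADC range.
    """
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}")
    n_ch = config.n_channels(limb)
    if profile.n_channels != n_ch:
        raise ValueError(
            f"profile has {profile.n_channels} channels but config expects "
            f"{n_ch} for the {limb} limb")
    if profile.n_movements != len(config.movements):
        raise ValueError("profile movement count does not match config")

    schedule = build_schedule(config)
    signal = np.zeros((n_ch, config.total_samples), dtype=np.float32)
    root = int(seed)
    fs = config.sampling_rate
    mov_index = {m: i for i, m in enumerate(config.movements)}

    grouped = schedule.groupby(["movement", "trial", "cycle"], sort=False)
    for (movement, trial, cycle), seg in grouped:
        mi = mov_index[movement]
        rng = np.random.default_rng(
            np.random.SeedSequence([root, 2, mi, int(trial), int(cycle)]))
        jitter = np.exp(rng.normal(0.0, profile.rep_jitter_sd, size=n_ch))
        for row in seg.itertuples(index=False):
            n = row.end_sample - row.start_sample
            for ch in range(n_ch):
                base = profile.baseline_sd * _band_noise(
                    rng, n, fs, config.band)
                if row.phase == "contraction":
                    g = profile.gain * profile.weights[mi, ch] * jitter[ch]
                    target_sd = profile.baseline_sd * (1.0 + g)
                    exc_sd = np.sqrt(
                        max(target_sd ** 2 - profile.baseline_sd ** 2, 0.0))
                    if exc_sd > 0:
                        base = base + exc_sd * _band_noise(
                            rng, n, fs, config.band,
                            center=profile.spectral_centers[mi, ch])
                signal[ch, row.start_sample:row.end_sample] = base

    clipped = np.abs(signal) > config.adc_range
    clipped_fraction = float(clipped.mean())
    if clipped_fraction > 0:
        logger.info("%s limb: clipped %.4f%% of samples at ±%g mV",
                    limb, 100 * clipped_fraction, config.adc_range)
        np.clip(signal, -config.adc_range, config.adc_range, out=signal)
    return RawRecording(limb, signal, fs, schedule, clipped_fraction)


def generate_cohort(
    config: ProtocolConfig,
    distinctness: float,
    fidelity: float,
    attenuation: float,
    seed: int,
    rep_jitter_sd: float = 0.2,
    baseline_sd: float = 0.05,
    gain: float = 4.0,
) -> tuple[RawRecording, RawRecording]:
    """Generate a matched (unaffected, affected) pair of recordings.

    Both limbs share the trial schedule and the noise stream; the affected
    limb uses a profile degraded by ``fidelity``/``attenuation`` (and, if
    the config assigns it fewer electrodes, the leading channel subset).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    profile_seed, derive_seed, noise_seed = (
        int(s) for s in rng.integers(0, 2 ** 31 - 1, size=3))

    profile = generate_activation_profile(
        len(config.movements), config.n_channels_unaffected, distinctness,
        profile_seed, band=config.band, rep_jitter_sd=rep_jitter_sd,
        baseline_sd=baseline_sd, gain=gain)
    affected = derive_affected_profile(profile, fidelity, attenuation,
                                       derive_seed)
    if config.n_channels_affected != config.n_channels_unaffected:
        affected = replace(
            affected,
            weights=affected.weights[:, :config.n_channels_affected],
            spectral_centers=affected.spectral_centers[
                :, :config.n_channels_affected])

    rec_u = generate_recording(config, profile, "unaffected", noise_seed)
    rec_a = generate_recording(config, affected, "affected", noise_seed)
    return rec_u, rec_a


# ---------------------------------------------------------------------------
# session container round-trip

def save_session(path: str | Path, config: ProtocolConfig,
                 recordings: dict[str, RawRecording]) -> None:
    """Write a session to an HDF5 container: one signal array per limb plus
    its schedule table, with the protocol config attached as YAML text."""
    import yaml

    with h5py.File(path, "w") as f:
        f.attrs["config"] = yaml.safe_dump(config.to_dict())
        for limb, rec in recordings.items():
            grp = f.create_group(limb)
            grp.create_dataset("signal", data=rec.signal,
                               compression="gzip", compression_opts=4)
            grp.attrs["sampling_rate"] = rec.sampling_rate
            grp.attrs["clipped_fraction"] = rec.clipped_fraction
            sched = rec.schedule
            grp.create_dataset(
                "schedule/movement",
                data=np.array(sched["movement"], dtype="S8"))
            for col in ("trial", "cycle", "start_sample", "end_sample"):
                grp.create_dataset(f"schedule/{col}",
                                   data=sched[col].to_numpy())
            grp.create_dataset("schedule/phase",
                               data=np.array(sched["phase"], dtype="S16"))


def load_session(path: str | Path
                 ) -> tuple[ProtocolConfig, dict[str, RawRecording]]:
    import yaml

    recordings: dict[str, RawRecording] = {}
    with h5py.File(path, "r") as f:
        config = ProtocolConfig.from_dict(yaml.safe_load(f.attrs["config"]))
        for limb in f:
            grp = f[limb]
            sched = pd.DataFrame({
                "movement": [s.decode() for s in grp["schedule/movement"][:]],
                "trial": grp["schedule/trial"][:],
                "cycle": grp["schedule/cycle"][:],
                "phase": [s.decode() for s in grp["schedule/phase"][:]],
                "start_sample": grp["schedule/start_sample"][:],
                "end_sample": grp["schedule/end_sample"][:],
            })[list(SCHEDULE_COLUMNS)]
            recordings[limb] = RawRecording(
                limb, grp["signal"][:], float(grp.attrs["sampling_rate"]),
                sched, float(grp.attrs["clipped_fraction"]))
    return config, recordings
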