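"""Per-segment amplitude and frequency features.

Two channel-level features are computed on every trimmed repetition:

* RMS — root-mean-square amplitude, ``sqrt(mean(x_i^2))`` over the N
  samples of one repetition; the amplitude-domain excitation measure.
* MNF — mean frequency, the power-weighted mean of the spectrum,
  ``sum(f_j p_j) / sum(p_j)`` over M frequency bins (default 0–1000 Hz in
  0.4 Hz bins, M = 2500).

Per limb and channel, each feature is then normalised to its maximum over
all movements, repetitions and both phases and expressed as a percentage,
so downstream statistics compare patterns, not absolute gains.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import PhaseSegment

FEATURE_COLUMNS = ("limb", "movement", "repetition", "phase", "channel",
                   "rms", "mnf")
MEASURES = ("RMS", "MNF")


class UndefinedFeatureError(ValueError):
    """A feature is undefined for this segment (e.g. MNF of zero power)."""


def compute_rms(samples: np.ndarray) -> float:
    """Root-mean-square of a 1-D series (same units as the input)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot compute RMS of an empty series")
    return float(np.sqrt(np.mean(samples ** 2)))


def compute_binned_spectrum(
    samples: np.ndarray,
    sampling_rate: float,
    f_max: float = 1000.0,
    bin_width: float = 0.4,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum summed into fixed-width frequency bins.

    A single windowed periodogram (Hann by default; "boxcar" gives the
    unwindowed estimator) is computed with enough zero padding that the raw
    resolution is at most ``bin_width / 2``, then raw power is summed into
    ``M = f_max / bin_width`` bins.  Returns (bin centres, bin powers);
    the binned total equals the raw periodogram total below ``f_max``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if sampling_rate <= 2 * f_max:
        raise ValueError("sampling_rate must exceed 2 × f_max")
    samples = np.asarray(samples, dtype=float)
    if samples.shape[-1] == 0:
        raise ValueError("cannot compute a spectrum of an empty series")
    n = samples.shape[-1]
    nfft = max(n, int(np.ceil(2.0 * sampling_rate / bin_width)))
    freqs, power = sps.periodogram(samples, fs=sampling_rate, window=window,
                                   nfft=nfft, axis=-1)
    n_bins = int(round(f_max / bin_width))
    keep = freqs < f_max
    idx = np.floor(freqs[keep] / bin_width).astype(int)
    idx = np.minimum(idx, n_bins - 1)
    if power.ndim == 1:
        binned = np.bincount(idx, weights=power[keep], minlength=n_bins)
    else:
        binned = np.vstack([
            np.bincount(idx, weights=row, minlength=n_bins)
            for row in power[..., keep]])
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return centers, binned


def compute_mnf(bin_frequencies: np.ndarray,
                bin_powers: np.ndarray) -> float:
    """Power-weighted mean frequency (Hz) of a binned spectrum."""
    f = np.asarray(bin_frequencies, dtype=float)
    p = np.asarray(bin_powers, dtype=float)
    total = p.sum()
    if not total > 0:
        raise UndefinedFeatureError(
            "MNF undefined: spectrum carries no power")
    return float((f * p).sum() / total)


def default_f_max(sampling_rate: float) -> float:
    """Spectrum cap: 1000 Hz, lowered to 40% of fs for slow-sampled data."""
    return min(1000.0, 0.4 * sampling_rate)


def build_feature_table(
    segments: Iterable[PhaseSegment],
    sampling_rate: float,
    f_max: float | None = None,
    bin_width: float = 0.4,
    window: str = "hann",
) -> pd.DataFrame:
    """Compute RMS and MNF for every segment and channel.

    Returns a tidy table keyed by (limb, movement, repetition, phase,
    channel) with ``rms`` (mV) and ``mnf`` (Hz) columns.
    """
    if f_max is None:
        f_max = default_f_max(sampling_rate)
    rows = []
    for seg in segments:
        data = seg.channel_data
        rms = np.sqrt(np.mean(np.asarray(data, dtype=float) ** 2, axis=1))
        centers, binned = compute_binned_spectrum(
            data, sampling_rate, f_max=f_max, bin_width=bin_width,
            window=window)
        binned = np.atleast_2d(binned)
        totals = binned.sum(axis=1)
        if not (totals > 0).all():
            raise UndefinedFeatureError(
                f"zero-power segment: {seg.limb} {seg.movement} "
                f"rep {seg.repetition} {seg.phase}")
        mnf = (binned * centers).sum(axis=1) / totals
        for ch in range(data.shape[0]):
            rows.append((seg.limb, seg.movement, seg.repetition, seg.phase,
                         ch + 1, rms[ch], mnf[ch]))
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def normalize_per_channel(table: pd.DataFrame,
                          include_relaxation: bool = True) -> pd.DataFrame:
    """Express features as a percentage of their per-(limb, channel) maximum.

    The maximum is taken over all movements and repetitions and, by
    default, both phases (so the relaxed state shares the percentage
    scale).  Adds ``rms_norm`` and ``mnf_norm`` columns in (0, 100].
    Idempotent: re-normalising leaves the columns unchanged.
    """
    table = table.copy()
    scope = table if include_relaxation else table[
        table["phase"] == "contraction"]
    for col in ("rms", "mnf"):
        maxima = scope.groupby(["limb", "channel"])[col].max()
        if not (maxima > 0).all():
            bad = maxima[~(maxima > 0)].index.tolist()
            raise ValueError(f"degenerate channel(s) with zero maximum "
                             f"{col}: {bad}")
        denom = table.set_index(["limb", "channel"]).index.map(maxima)
        table[f"{col}_norm"] = 100.0 * table[col].to_numpy() / np.asarray(
            denom, dtype=float)
    return table


def _select_split(reps: pd.Series, split: str) -> pd.Series:
    if split == "all":
        return pd.Series(True, index=reps.index)
    if split == "even":
        return reps % 2 == 0
    if split == "odd":
        return reps % 2 == 1
    raise ValueError(f"unknown split {split!r}; use all, even or odd")


def summarize_channels(table: pd.DataFrame, split: str = "all",
                       split_by: str = "repetition") -> pd.DataFrame:
    """Median/IQR summary of normalised features per (limb, movement, channel).

    ``split`` selects all repetitions or only the even/odd ones —
    by repetition-index parity (default) or, with ``split_by="trial"``,
    by trial parity (repetitions 1..cycles vs the rest).  Contraction
    repetitions feed the summary statistics; the relaxation-phase median is
    carried alongside as the resting baseline.  Quartiles use linear
    interpolation between order statistics; whisker bounds follow the
    1.5 × IQR convention.

    Returns one row per (limb, movement, channel, measure) with measure in
    {"RMS", "MNF"} over the normalised percentage values.
    """
    if not {"rms_norm", "mnf_norm"} <= set(table.columns):
        table = normalize_per_channel(table)
    if split_by == "repetition":
        parity_key = table["repetition"]
    elif split_by == "trial":
        cycles = int(table["repetition"].max()) // 2
        parity_key = (table["repetition"] - 1) // max(cycles, 1) + 1
    else:
        raise ValueError("split_by must be 'repetition' or 'trial'")
    mask = _select_split(parity_key, split)
    selected = table[mask]

    contraction = selected[selected["phase"] == "contraction"]
    relaxation = selected[selected["phase"] == "relaxation"]
    norm_col = {"RMS": "rms_norm", "MNF": "mnf_norm"}

    rows = []
    for (limb, movement, channel), grp in contraction.groupby(
            ["limb", "movement", "channel"], sort=False):
        if split != "all" and len(grp) < 2:
            raise ValueError(
                f"split {split!r} leaves {len(grp)} repetition(s) for "
                f"{limb}/{movement}/ch{channel}; need at least 2")
        relax_grp = relaxation[
            (relaxation["limb"] == limb)
            & (relaxation["movement"] == movement)
            & (relaxation["channel"] == channel)]
        for measure in MEASURES:
            vals = grp[norm_col[measure]].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            relax_vals = relax_grp[norm_col[measure]].to_numpy()
            rows.append({
                "limb": limb, "movement": movement, "channel": channel,
                "measure": measure, "split": split,
                "median": med, "q1": q1, "q3": q3, "iqr": iqr,
                "whisker_low": inside.min() if inside.size else med,
                "whisker_high": inside.max() if inside.size else med,
                "n": len(vals),
                "relax_median": (float(np.median(relax_vals))
                                 if relax_vals.size else np.nan),
            })
    return pd.DataFrame(rows)


def channel_vector(summary: pd.DataFrame, limb: str, movement: str,
                   measure: str, statistic: str) -> np.ndarray:
    """Per-channel vector of one summary statistic, in channel order."""
    sub = summary[(summary["limb"] == limb)
                  & (summary["movement"] == movement)
                  & (summary["measure"] == measure)]
    sub = sub.sort_values("channel")
    if statistic not in ("median", "iqr"):
        raise ValueError("statistic must be 'median' or 'iqr'")
    return sub[statistic].to_numpy(dtype=float)
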