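"""Within-movement reproducibility and across-limb comparison.

Kendall's coefficient of concordance W measures how consistently the
per-channel excitation pattern of one movement recurs across its
repetitions: each repetition ranks the channels, and W in [0, 1] scores
the agreement of those rankings (tie-corrected with mid-ranks).  W values
are banded into the conventional strength categories poor (< 0.20),
minimal, weak, moderate and strong (≥ 0.80).

Across limbs, the ten per-movement W values of the affected limb are
compared with the unaffected limb's using an exact paired Wilcoxon
signed-rank test (full sign-pattern null via subset-sum counting, valid
with tied ranks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import normalize_per_channel

W_CATEGORIES = (
    (0.20, "poor"),
    (0.40, "minimal"),
    (0.60, "weak"),
    (0.80, "moderate"),
    (np.inf, "strong"),
)


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. all values tied)."""


def kendalls_w(values: np.ndarray,
               orientation: str = "repetitions") -> float:
    """Kendall's coefficient of concordance of a repetitions×channels matrix.

    With the default orientation each repetition acts as a judge ranking
    the channels (agreement of the excitation *pattern* across
    repetitions); ``orientation="channels"`` transposes the roles.
    Mid-ranks are used for ties, with the standard per-judge correction
    ``sum(t^3 - t)`` subtracted from the denominator.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D repetitions×channels matrix")
    if orientation == "channels":
        values = values.T
    elif orientation != "repetitions":
        raise ValueError("orientation must be 'repetitions' or 'channels'")
    m, n = values.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 judges and 2 objects")

    ranks = stats.rankdata(values, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())

    tie_term = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts ** 3 - counts).sum())
    denom = m * m * (n ** 3 - n) - m * tie_term
    if denom <= 0:
        raise UndefinedStatisticError(
            "Kendall's W undefined: every judge ties all objects")
    return 12.0 * s / denom


def categorize_w(w: float) -> str:
    """Map a concordance value to its strength category."""
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"W must lie in [0, 1], got {w!r}")
    for upper, label in W_CATEGORIES:
        if w < upper:
            return label
    return "strong"


def assess_normality(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value for a small sample.

    Used only to justify the nonparametric path in reports; the rank-based
    statistics downstream are applied regardless of the outcome.
    """
    values = np.asarray(values, dtype=float)
    if not (3 <= values.size <= 5000):
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def consistency_table(feature_table: pd.DataFrame,
                      orientation: str = "repetitions") -> pd.DataFrame:
    """Per-movement Kendall's W of each limb and measure.

    Uses the normalised contraction-phase values: for every (limb,
    movement, measure) the repetitions×channels matrix of percentages is
    scored with :func:`kendalls_w` and banded with :func:`categorize_w`.
    """
    table = feature_table
    if not {"rms_norm", "mnf_norm"} <= set(table.columns):
        table = normalize_per_channel(table)
    contraction = table[table["phase"] == "contraction"]
    rows = []
    for (limb, movement), grp in contraction.groupby(
            ["limb", "movement"], sort=False):
        for measure, col in (("RMS", "rms_norm"), ("MNF", "mnf_norm")):
            mat = grp.pivot(index="repetition", columns="channel",
                            values=col).to_numpy()
            w = kendalls_w(mat, orientation=orientation)
            rows.append({"limb": limb, "movement": movement,
                         "measure": measure, "W": w,
                         "category": categorize_w(min(w, 1.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact paired Wilcoxon signed-rank

@dataclass
class LimbComparisonResult:
    """Paired comparison of per-movement consistency across limbs."""

    measure: str
    statistic: float          # smaller of the two signed-rank sums
    p: float
    median_unaffected: float
    median_affected: float
    direction: str            # limb with the larger median, or "tied"
    n_used: int               # pairs remaining after dropping zero diffs
    degenerate: bool = False


def _exact_signed_rank_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the signed-rank statistic of nonzero diffs.

    Enumerates the 2^n equiprobable sign patterns through a subset-sum
    count over doubled mid-ranks (exact also under tied |d|), and returns
    ``(min(W+, W-), p)`` with ``p = min(1, 2 P(T <= t_obs))``.
    """
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    t_obs = min(w_plus, w_minus)

    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    t2 = int(np.rint(2 * t_obs))
    p = 2.0 * counts[:t2 + 1].sum() / counts.sum()
    return t_obs, min(1.0, p)


def compare_limb_consistency(w_affected: np.ndarray,
                             w_unaffected: np.ndarray,
                             measure: str = "") -> LimbComparisonResult:
    """Exact Wilcoxon signed-rank test on paired per-movement W values.

    Pairs with zero difference are dropped before ranking (classical
    convention).  The test is two-sided; ``direction`` separately reports
    which limb had the larger median consistency.
    """
    wa = np.asarray(w_affected, dtype=float)
    wu = np.asarray(w_unaffected, dtype=float)
    if wa.shape != wu.shape or wa.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired vectors")
    if wa.size < 5:
        raise ValueError("need at least 5 paired values")

    med_a, med_u = float(np.median(wa)), float(np.median(wu))
    if med_u > med_a:
        direction = "unaffected"
    elif med_a > med_u:
        direction = "affected"
    else:
        direction = "tied"

    diffs = wu - wa
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return LimbComparisonResult(measure, 0.0, 1.0, med_u, med_a,
                                    direction, 0, degenerate=True)
    statistic, p = _exact_signed_rank_p(diffs)
    return LimbComparisonResult(measure, statistic, p, med_u, med_a,
                                direction, int(diffs.size))


def limb_comparison_table(consistency: pd.DataFrame) -> pd.DataFrame:
    """Run the across-limb test per measure on a consistency table."""
    rows = []
    for measure, grp in consistency.groupby("measure", sort=False):
        wide = grp.pivot(index="movement", columns="limb", values="W")
        if not {"affected", "unaffected"} <= set(wide.columns):
            raise ValueError("consistency table must cover both limbs")
        res = compare_limb_consistency(
            wide["affected"].to_numpy(), wide["unaffected"].to_numpy(),
            measure=measure)
        rows.append({
            "measure": measure, "statistic": res.statistic, "p": res.p,
            "median_unaffected": res.median_unaffected,
            "median_affected": res.median_affected,
            "direction": res.direction, "n_used": res.n_used,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)
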