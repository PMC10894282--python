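"""Representational dissimilarity analysis of movement excitation patterns.

The per-channel summary vector of each movement (median or IQR of
normalised RMS or MNF) is compared across movements with the rank
correlation distance 1 − Kendall's τb, giving a movement×movement
representational dissimilarity matrix (RDM).  Splitting the repetitions
into even and odd halves yields a non-symmetric split-data RDM (sdRDM)
whose diagonal measures within-movement reliability; the exemplar
discriminability index

    EDI = mean(between-movement entries) − mean(diagonal entries)

is tested against a condition-label randomisation null (row permutations
of the sdRDM).  Across limbs, the upper triangles of the two limbs' RDMs
are correlated with Kendall's τa and tested by jointly permuting the rows
and columns of one RDM.  Nonmetric MDS with the squared-stress (sstress)
criterion embeds an RDM in low dimensions for visualisation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .consistency import UndefinedStatisticError
from .features import channel_vector

#: The four summary measures an RDM can be built from.
RDM_MEASURES = ("RMS-median", "RMS-IQR", "MNF-median", "MNF-IQR")


def _parse_measure(measure: str) -> tuple[str, str]:
    try:
        feature, statistic = measure.split("-")
        if feature not in ("RMS", "MNF") or statistic not in (
                "median", "IQR"):
            raise ValueError
    except ValueError:
        raise ValueError(f"measure must be one of {RDM_MEASURES}, "
                         f"got {measure!r}") from None
    return feature, statistic.lower()


# ---------------------------------------------------------------------------
# rank correlations

def rank_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Rank-correlation distance 1 − τb between two channel vectors.

    τb uses the tie-adjusted denominator; the distance lies in [0, 2].
    A vector with all entries tied leaves τb undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors, n >= 2")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedStatisticError(
            "tau-b undefined for a fully tied vector")
    tau = stats.kendalltau(u, v).statistic
    return float(1.0 - tau)


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's τa: (concordant − discordant) / (n(n−1)/2); ties count
    in neither."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors, n >= 2")
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    concordance = float(np.triu(sx * sy, k=1).sum())
    return concordance / (n * (n - 1) / 2.0)


# ---------------------------------------------------------------------------
# RDM construction

@dataclass
class RDM:
    """Symmetric movement×movement rank-correlation distance matrix."""

    conditions: tuple[str, ...]
    matrix: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.conditions)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match condition count")

    @property
    def n(self) -> int:
        return len(self.conditions)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


@dataclass
class SplitRDM:
    """Non-symmetric RDM: rows from the even split, columns from the odd.

    The diagonal holds within-movement (even vs odd) distances; the
    off-diagonals between-movement distances.
    """

    conditions: tuple[str, ...]
    matrix: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.conditions)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match condition count")

    @property
    def n(self) -> int:
        return len(self.conditions)


def _movement_vectors(summary: pd.DataFrame, measure: str
                      ) -> tuple[tuple[str, ...], np.ndarray]:
    feature, statistic = _parse_measure(measure)
    limbs = summary["limb"].unique()
    if len(limbs) != 1:
        raise ValueError("summary must cover exactly one limb; "
                         "build one RDM per limb")
    movements = tuple(dict.fromkeys(summary["movement"]))
    vectors = np.vstack([
        channel_vector(summary, limbs[0], m, feature, statistic)
        for m in movements])
    return movements, vectors


def build_rdm(summary: pd.DataFrame, measure: str) -> RDM:
    """RDM over movements from an unsplit (split="all") channel summary."""
    movements, vectors = _movement_vectors(summary, measure)
    n = len(movements)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rank_distance(vectors[i], vectors[j])
    return RDM(movements, mat, measure)


def build_split_rdm(even_summary: pd.DataFrame, odd_summary: pd.DataFrame,
                    measure: str) -> SplitRDM:
    """sdRDM: entry (i, j) is the distance between movement i's even-split
    vector and movement j's odd-split vector."""
    movements_e, vec_e = _movement_vectors(even_summary, measure)
    movements_o, vec_o = _movement_vectors(odd_summary, measure)
    if movements_e != movements_o:
        raise ValueError("even and odd splits must cover the same "
                         "movements in the same order")
    if vec_e.shape != vec_o.shape:
        raise ValueError("splits must share the channel set")
    n = len(movements_e)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mat[i, j] = rank_distance(vec_e[i], vec_o[j])
    return SplitRDM(movements_e, mat, measure)


# ---------------------------------------------------------------------------
# exemplar discriminability

@dataclass
class EDIResult:
    """EDI permutation-test outcome.

    ``p`` counts null EDIs ≥ the observed one (ties included), which
    guarantees a valid test.  Because the rank-correlation distances of
    few-channel data are lattice-valued, the null is heavily tied and this
    p is conservative; ``p_mid`` is the tie-split mid-p (ties counted
    half), the standard calibrated choice for discrete permutation nulls
    and the decision rule used by the simulation studies.
    """

    edi: float
    null_size: int
    p: float
    mode: str
    p_mid: float = 1.0
    seed: int | None = None
    measure: str = ""


def compute_edi(sdrdm: SplitRDM | np.ndarray) -> float:
    """Mean off-diagonal minus mean diagonal of an sdRDM.

    Positive values indicate movements are more dissimilar between than
    within, i.e. discriminable excitation patterns.
    """
    mat = sdrdm.matrix if isinstance(sdrdm, SplitRDM) else np.asarray(
        sdrdm, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 conditions")
    diag = np.trace(mat)
    return float((mat.sum() - diag) / (n * n - n) - diag / n)


def _edi_from_diag_sums(diag_sums: np.ndarray, total: float,
                        n: int) -> np.ndarray:
    return (total - diag_sums) / (n * n - n) - diag_sums / n


def edi_randomization_test(
    sdrdm: SplitRDM | np.ndarray,
    mode: str = "exhaustive",
    n_draws: int = 10_000,
    seed: int | None = None,
) -> EDIResult:
    """Condition-label randomisation test of the EDI.

    The null permutes the rows of the sdRDM (relabelling which movement's
    even-split vector sits on the diagonal) and recomputes the EDI.  Under
    no movement structure all permutations are exchangeable.  Exhaustive
    mode enumerates all n! permutations (n ≤ 10); Monte-Carlo mode draws
    ``n_draws`` permutations with the identity included, so p is never 0.
    ``p`` is the fraction of null EDIs ≥ the observed EDI; ``p_mid``
    counts ties half (see :class:`EDIResult`).
    """
    mat = sdrdm.matrix if isinstance(sdrdm, SplitRDM) else np.asarray(
        sdrdm, dtype=float)
    n = mat.shape[0]
    observed = compute_edi(mat)
    total = float(mat.sum())
    measure = sdrdm.measure if isinstance(sdrdm, SplitRDM) else ""
    cols = np.arange(n)

    tol = 1e-9 * max(1.0, abs(observed))
    if mode == "exhaustive":
        if n > 10:
            raise ValueError("exhaustive enumeration limited to n <= 10; "
                             "use mode='monte_carlo'")
        null_size = int(np.prod(np.arange(1, n + 1)))
        n_gt = n_eq = 0
        perm_iter = itertools.permutations(range(n))
        chunk = 200_000
        while True:
            block = np.array(list(itertools.islice(perm_iter, chunk)),
                             dtype=np.intp)
            if block.size == 0:
                break
            diag_sums = mat[block, cols].sum(axis=1)
            null = _edi_from_diag_sums(diag_sums, total, n)
            n_gt += int((null > observed + tol).sum())
            n_eq += int((np.abs(null - observed) <= tol).sum())
        return EDIResult(observed, null_size, (n_gt + n_eq) / null_size,
                         "exhaustive", (n_gt + 0.5 * n_eq) / null_size,
                         seed, measure)

    if mode != "monte_carlo":
        raise ValueError("mode must be 'exhaustive' or 'monte_carlo'")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.vstack([cols] + [rng.permutation(n)
                                for _ in range(n_draws - 1)])
    diag_sums = mat[perms, cols].sum(axis=1)
    null = _edi_from_diag_sums(diag_sums, total, n)
    n_gt = int((null > observed + tol).sum())
    n_eq = int((np.abs(null - observed) <= tol).sum())
    return EDIResult(observed, int(n_draws), (n_gt + n_eq) / n_draws,
                     "monte_carlo", (n_gt + 0.5 * n_eq) / n_draws,
                     seed, measure)


# ---------------------------------------------------------------------------
# across-limb relatedness

@dataclass
class RelatednessResult:
    tau_a: float
    p: float
    n_permutations: int
    seed: int | None = None
    measure: str = ""


def rdm_relatedness_test(
    rdm_affected: RDM,
    rdm_unaffected: RDM,
    n_permutations: int = 50_000,
    seed: int | None = None,
) -> RelatednessResult:
    """Label-randomisation test of relatedness between two limbs' RDMs.

    The observed statistic is Kendall's τa between the upper triangles.
    Each null draw applies one random condition permutation simultaneously
    to the rows and columns of the affected RDM and recomputes τa against
    the (fixed) unaffected RDM; ``p = (#{null ≥ observed} + 1) /
    (n_permutations + 1)``.
    """
    if rdm_affected.conditions != rdm_unaffected.conditions:
        raise ValueError("RDMs must share the same condition set and order")
    n = rdm_affected.n
    iu, ju = np.triu_indices(n, k=1)
    a_mat = rdm_affected.matrix
    y = rdm_unaffected.matrix[iu, ju]
    x_obs = a_mat[iu, ju]
    observed = kendall_tau_a(x_obs, y)

    k = y.size
    pa, pb = np.triu_indices(k, k=1)
    sy = np.sign(y[pa] - y[pb])
    denom = k * (k - 1) / 2.0

    rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = 5_000
    remaining = int(n_permutations)
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        perms = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        xp = a_mat[perms[:, iu], perms[:, ju]]
        sx = np.sign(xp[:, pa] - xp[:, pb])
        taus = (sx * sy).sum(axis=1) / denom
        n_ge += int((taus >= observed - 1e-12).sum())
    p = (n_ge + 1) / (n_permutations + 1)
    return RelatednessResult(observed, float(p), int(n_permutations), seed,
                             rdm_affected.measure)


# ---------------------------------------------------------------------------
# nonmetric MDS (squared-stress criterion)

@dataclass
class MDSEmbedding:
    coordinates: np.ndarray
    stress: float
    iterations: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def _sstress(d2: np.ndarray, dhat2: np.ndarray) -> float:
    denom = float((d2 ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d2 - dhat2) ** 2).sum() / denom))


def _classical_init(mat: np.ndarray, dims: int) -> np.ndarray:
    n = mat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (mat ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _fit_config(delta_order: np.ndarray, x0: np.ndarray, dims: int,
                max_iterations: int, tolerance: float
                ) -> tuple[np.ndarray, float, int, bool, list[float]]:
    n = x0.shape[0]
    iso = IsotonicRegression(increasing=True)
    t = np.arange(delta_order.size, dtype=float)

    def objective(flat: np.ndarray, dhat2: np.ndarray):
        x = flat.reshape(n, dims)
        diff = x[:, None, :] - x[None, :, :]
        d2_full = (diff ** 2).sum(axis=-1)
        iu = np.triu_indices(n, k=1)
        resid_vec = np.zeros_like(d2_full)
        r = d2_full[iu] - dhat2
        resid_vec[iu] = r
        resid_vec += resid_vec.T
        obj = float((r ** 2).sum())
        grad = 4.0 * (resid_vec[:, :, None] * diff).sum(axis=1)
        return obj, grad.ravel()

    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    x = x0.copy()
    prev_stress = np.inf
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, max_iterations + 1):
        d2 = pdist(x, "sqeuclidean")
        dhat2 = np.empty_like(d2)
        dhat2[delta_order] = iso.fit_transform(t, d2[delta_order])
        res = minimize(objective, x.ravel(), args=(dhat2,), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 100, "ftol": 1e-14})
        x_new = res.x.reshape(n, dims)
        d2_new = pdist(x_new, "sqeuclidean")
        stress = _sstress(d2_new, dhat2)
        if stress > prev_stress:        # keep the better configuration
            converged = True
            break
        x = x_new
        history.append(stress)
        if prev_stress - stress < tolerance * max(prev_stress, 1e-12):
            prev_stress = stress
            converged = True
            break
        prev_stress = stress
    final = prev_stress if np.isfinite(prev_stress) else history[-1]
    return x, float(final), it, converged, history


def nonmetric_mds(
    rdm: RDM | np.ndarray,
    dims: int = 3,
    max_iterations: int = 300,
    tolerance: float = 1e-6,
    seed: int | None = 0,
    n_restarts: int = 4,
) -> MDSEmbedding:
    """Nonmetric MDS minimising the squared-stress (sstress) criterion.

    Alternates isotonic regression of squared configuration distances
    against the dissimilarity rank order (the monotone disparities) with
    gradient-based updates of the configuration.  Initialised from
    classical (metric) scaling plus ``n_restarts`` random restarts; the
    lowest-stress solution is returned.  Deterministic for a fixed seed.
    """
    mat = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm,
                                                             dtype=float)
    n = mat.shape[0]
    if n < dims + 1:
        raise ValueError("need at least dims + 1 conditions")
    delta = squareform(mat, checks=False)
    delta_order = np.argsort(delta, kind="stable")

    rng = np.random.default_rng(seed)
    inits = [_classical_init(mat, dims)]
    scale = max(delta.mean(), 1e-6)
    for _ in range(n_restarts):
        inits.append(rng.normal(scale=scale, size=(n, dims)))

    best = None
    for x0 in inits:
        fit = _fit_config(delta_order, x0, dims, max_iterations, tolerance)
        if best is None or fit[1] < best[1]:
            best = fit
    x, stress, iterations, converged, history = best
    return MDSEmbedding(x - x.mean(axis=0), stress, iterations, converged,
                        history)
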