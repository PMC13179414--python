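"""Covariate adjustment for the win odds via probabilistic index models.

The conditional probabilistic index (CPI) of an ordered pair,

    P(j beats i | A_i, A_j, X_i, X_j) = expit(tau_A (A_j - A_i)
                                              + tau_X' (X_j - X_i)),

is a probabilistic index model (PIM) with logit link, fitted by solving
the logistic-regression-type estimating equations over all n(n-1) ordered
pairs with the fractional win scores {0, 1/2, 1} as responses.  Averaging
the fitted CPI at (A_i, A_j) = (0, 1) over all covariate pairs gives the
standardization estimate of the marginal probabilistic index; adding the
fitted CPI as a mean-zero augmentation term to the direct estimate gives
the augmentation estimate.  Under the logit link and these estimating
equations the two coincide, which this module verifies numerically.

The variance is estimated by the Hajek projection of the order-2
U-statistic representation of the augmented estimator (a sandwich-type
estimator); a within-arm subject bootstrap is provided as an alternative.

The pairwise score vector and Fisher information are accumulated with
O(n^2) work and memory but never materialize the n(n-1) x (p+1) design:
because every design row is a difference z_j - z_i of subject-level rows
z_k = (A_k, X_k'), sums over pairs reduce to weighted row/column sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .comparison import (
    ComparisonRule,
    PairwiseScores,
    SubjectRecord,
    TrialArrays,
    compare_hierarchical,
    score_matrix,
)
from .estimation import WinOddsResult, _check_arms, wald_result, win_statistics

__all__ = [
    "PimFit",
    "AdjustedEstimate",
    "fit_pim",
    "standardize",
    "augment",
    "sandwich_variance",
    "bootstrap_variance",
    "adjusted_inference",
    "PimConvergenceError",
    "SeparationError",
    "RankDeficientError",
]

SCORE_TOL = 1e-8
STEP_TOL = 1e-10
MAX_ITER = 100
SEPARATION_GUARD = 30.0  # |coefficient| beyond this on standardized pair diffs


class PimConvergenceError(RuntimeError):
    """Fisher scoring failed to converge; carries the fit diagnostics."""

    def __init__(self, msg: str, fit: "PimFit | None" = None):
        super().__init__(msg)
        self.fit = fit


class SeparationError(RuntimeError):
    """Coefficients diverged, indicating (quasi-)separation of the
    pairwise pseudo-observations."""


class RankDeficientError(ValueError):
    """The pairwise-difference design is rank deficient (e.g. a constant
    covariate column, or duplicated columns)."""


@dataclass
class PimFit:
    """Fitted PIM coefficients with convergence diagnostics.

    ``tau_a`` is the treatment coefficient; with no covariates it equals
    logit of the direct MPI estimate.  ``max_score`` is the largest
    absolute component of the estimating equations at the solution.
    """

    tau_a: float
    tau_x: np.ndarray
    n_iter: int
    converged: bool
    max_score: float

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate(([self.tau_a], self.tau_x))


@dataclass
class AdjustedEstimate:
    """Covariate-adjusted MPI estimate in both algebraic forms.

    ``nu_stand`` (standardization) and ``nu_aug`` (augmentation) agree to
    numerical tolerance; ``result`` carries the Wald inference built on
    their common value.
    """

    nu_stand: float
    nu_aug: float
    se_nu: float
    pim: PimFit
    result: WinOddsResult


def _design_arrays(arms: np.ndarray, covariates: np.ndarray | None):
    arms = np.asarray(arms, dtype=float)
    n = arms.shape[0]
    if covariates is None:
        X = np.empty((n, 0))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if X.shape[0] != n:
            raise ValueError("covariates and arms have incompatible shapes")
    Z = np.column_stack([arms, X])  # subject-level rows; pair design = z_j - z_i
    return arms, X, Z


def fit_pim(
    scores: PairwiseScores,
    arms: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    tol: float = SCORE_TOL,
    step_tol: float = STEP_TOL,
    max_iter: int = MAX_ITER,
) -> PimFit:
    """Fit the logit-link PIM by Fisher scoring on all ordered pairs.

    Solves  sum_{i != j} d_ij (S_ij - expit(beta' d_ij)) = 0  with
    d_ij = (A_j - A_i, (X_j - X_i)'), no intercept, starting from beta = 0.
    Convergence when the largest absolute score component falls below
    ``tol`` or the Newton step norm below ``step_tol``.

    The score reduces to Z' (c - r) where c and r are the column and row
    sums of the residual matrix, and the expected information to
    sum_j cw_j z_j z_j' + sum_i rw_i z_i z_i' - Z'WZ - (Z'WZ)', so each
    iteration costs O(n^2 p) time and O(n^2 + np) memory.
    """
    arms_f, X, Z = _design_arrays(arms, covariates)
    n, q = Z.shape
    if n < q + 2:
        raise ValueError(f"need n >= p + 2 subjects (n={n}, p={q - 1})")
    Zc = Z - Z.mean(axis=0)
    if np.linalg.matrix_rank(Zc) < q:
        raise RankDeficientError(
            "pairwise-difference design is rank deficient: some column of "
            "(arm, covariates) is constant or a linear combination of others"
        )
    S = scores.scores
    beta = np.zeros(q)
    off_diag = ~np.eye(n, dtype=bool)
    for it in range(1, max_iter + 1):
        lin = Z @ beta                      # beta' z_k
        eta = lin[None, :] - lin[:, None]   # beta' (z_j - z_i)
        mu = expit(eta)
        resid = np.where(off_diag, S - mu, 0.0)
        score = Z.T @ (resid.sum(axis=0) - resid.sum(axis=1))
        max_score = float(np.max(np.abs(score)))
        if max_score <= tol:
            return PimFit(float(beta[0]), beta[1:].copy(), it - 1, True, max_score)
        W = np.where(off_diag, mu * (1.0 - mu), 0.0)
        WZ = W @ Z
        cross = Z.T @ WZ
        info = (
            Z.T * W.sum(axis=0) @ Z
            + Z.T * W.sum(axis=1) @ Z
            - cross
            - cross.T
        )
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise PimConvergenceError(
                f"singular information matrix at iteration {it}",
                PimFit(float(beta[0]), beta[1:].copy(), it, False, max_score),
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_GUARD:
            raise SeparationError(
                f"coefficient magnitude exceeded {SEPARATION_GUARD}; the "
                "pairwise pseudo-observations appear separated"
            )
        if np.linalg.norm(step) <= step_tol:
            break
    # recompute the score at the final beta
    lin = Z @ beta
    mu = expit(lin[None, :] - lin[:, None])
    resid = np.where(off_diag, S - mu, 0.0)
    score = Z.T @ (resid.sum(axis=0) - resid.sum(axis=1))
    max_score = float(np.max(np.abs(score)))
    fit = PimFit(float(beta[0]), beta[1:].copy(), it, max_score <= tol, max_score)
    if not fit.converged:
        raise PimConvergenceError(
            f"Fisher scoring did not converge in {it} iterations "
            f"(max |score| = {max_score:.3e})",
            fit,
        )
    return fit


def _cpi_matrix(pim: PimFit, covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Fitted CPI at (A_i, A_j) = (0, 1): expit(tau_A + tau_X'(X_j - X_i))."""
    if covariates is None or pim.tau_x.size == 0:
        return np.full((n, n), float(expit(pim.tau_a)))
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    g = X @ pim.tau_x
    return expit(pim.tau_a + g[None, :] - g[:, None])


def standardize(pim: PimFit, covariates: np.ndarray | None, n: int | None = None) -> float:
    """Standardization estimate: the fitted CPI at arms (0, 1) averaged
    over all n(n-1) ordered covariate pairs."""
    if covariates is not None:
        n = np.atleast_2d(np.asarray(covariates)).shape[0]
    if n is None:
        raise ValueError("n is required when there are no covariates")
    H = _cpi_matrix(pim, covariates, n)
    total = H.sum() - np.trace(H)
    return float(total / (n * (n - 1)))


def augment(
    scores: PairwiseScores,
    arms: np.ndarray,
    pim: PimFit,
    covariates: np.ndarray | None = None,
    *,
    h_matrix: np.ndarray | None = None,
) -> float:
    """Augmentation estimate: nu_direct plus the mean-zero augmentation
    term built from the fitted CPI (or any supplied pair function H).

        nu_direct + sum_{i!=j} [1/(n(n-1)) - (1-A_i)A_j/(N0 N1)] H_ij
    """
    ctrl, trt = _check_arms(arms)
    n = scores.n
    n0, n1 = ctrl.size, trt.size
    H = h_matrix if h_matrix is not None else _cpi_matrix(pim, covariates, n)
    total = H.sum() - np.trace(H)
    ct_total = H[np.ix_(ctrl, trt)].sum()
    nu_direct = win_statistics(scores, arms).nu_direct
    return float(nu_direct + total / (n * (n - 1)) - ct_total / (n0 * n1))


def sandwich_variance(
    scores: PairwiseScores,
    arms: np.ndarray,
    pim: PimFit,
    covariates: np.ndarray | None = None,
) -> float:
    """Hajek-projection variance of the augmented MPI estimator.

    With p_a = N_a / n and H the fitted CPI at arms (0, 1), the estimator
    is the average over ordered pairs of the kernel

        h_ij = (1 - A_i) A_j (S_ij - H_ij) / (p_0 p_1) + H_ij,

    and the projection variance is (4/n) times the sample variance of the
    per-subject projections g_k = mean over j != k of (h_kj + h_jk)/2.
    """
    arms = np.asarray(arms)
    ctrl, trt = _check_arms(arms)
    n = scores.n
    if ctrl.size < 2 or trt.size < 2:
        raise ValueError("need at least two subjects per arm")
    p0 = ctrl.size / n
    p1 = trt.size / n
    H = _cpi_matrix(pim, covariates, n)
    ct = np.outer(arms == 0, arms == 1).astype(float)  # (1-A_i) A_j
    h = ct * (scores.scores - H) / (p0 * p1) + H
    np.fill_diagonal(h, 0.0)
    g = (h.sum(axis=1) + h.sum(axis=0)) / (2.0 * (n - 1))
    var = float(4.0 / n * g.var(ddof=1))
    return var


def bootstrap_variance(
    data: TrialArrays,
    adjustment: np.ndarray | None,
    *,
    rule: ComparisonRule = compare_hierarchical,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> float:
    """Within-arm subject bootstrap variance of the adjusted MPI.

    Controls and treated are resampled with replacement separately (so
    both group sizes are preserved), the PIM is refitted and the
    standardization estimate recomputed per resample; returns the sample
    variance of the resampled estimates.  Resamples on which the fit
    fails are dropped (this is rare and reported via the returned count
    only in :func:`adjusted_inference`).
    """
    rng = np.random.default_rng(rng)
    ctrl = np.flatnonzero(data.arm == 0)
    trt = np.flatnonzero(data.arm == 1)
    estimates = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(ctrl, ctrl.size, replace=True),
             rng.choice(trt, trt.size, replace=True)]
        )
        boot = data.subset(idx)
        X = boot.covariates[:, adjustment] if adjustment is not None else None
        try:
            sc = score_matrix(boot, rule)
            fit = fit_pim(sc, boot.arm, X)
            estimates.append(standardize(fit, X, n=boot.n))
        except (PimConvergenceError, SeparationError):
            continue
    if len(estimates) < 2:
        raise RuntimeError("bootstrap produced fewer than 2 successful fits")
    return float(np.var(estimates, ddof=1))


def adjusted_inference(
    records,
    rule: ComparisonRule = compare_hierarchical,
    adjustment: np.ndarray | list[int] | None = None,
    alpha: float = 0.05,
    *,
    variance_method: str = "sandwich",
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
    scores: PairwiseScores | None = None,
) -> AdjustedEstimate:
    """End-to-end covariate-adjusted MPI / win-odds analysis.

    Parameters
    ----------
    records
        Sequence of :class:`SubjectRecord` or a :class:`TrialArrays`.
    rule
        Pairwise win/loss/tie rule (defaults to the hierarchical
        death-then-nonfatal rule).
    adjustment
        Covariate column indices to adjust for; ``None`` adjusts for all
        columns, an empty list for none (which collapses to the direct
        estimator).
    variance_method
        ``"sandwich"`` (projection) or ``"bootstrap"`` (within-arm
        subject resampling with ``n_boot`` resamples).
    scores
        Pre-computed score matrix, to avoid recomputation when several
        adjustment sets are analyzed on the same data.
    """
    data = records if isinstance(records, TrialArrays) else TrialArrays.from_records(records)
    if adjustment is None:
        cols = np.arange(data.p)
    else:
        cols = np.asarray(adjustment, dtype=int)
    X = data.covariates[:, cols] if cols.size else None
    if scores is None:
        scores = score_matrix(data, rule)
    pim = fit_pim(scores, data.arm, X)
    nu_stand = standardize(pim, X, n=data.n)
    nu_aug = augment(scores, data.arm, pim, X)
    if abs(nu_stand - nu_aug) > 1e-8:
        raise AssertionError(
            f"standardization/augmentation identity violated: "
            f"{nu_stand} vs {nu_aug}"
        )
    if variance_method == "sandwich":
        var = sandwich_variance(scores, data.arm, pim, X)
    elif variance_method == "bootstrap":
        var = bootstrap_variance(
            data, cols if cols.size else None, rule=rule, n_boot=n_boot,
            rng=np.random.default_rng(rng),
        )
    else:
        raise ValueError(f"unknown variance method {variance_method!r}")
    se = math.sqrt(var)
    ws = win_statistics(scores, data.arm)
    extra = {
        "n_wins": ws.n_wins,
        "n_losses": ws.n_losses,
        "n_ties": ws.n_ties,
        "n0": ws.n0,
        "n1": ws.n1,
        "nu_direct": ws.nu_direct,
        "tau_a": pim.tau_a,
        "n_adjusted_covariates": int(cols.size),
        "variance_method": variance_method,
    }
    result = wald_result(nu_stand, se, alpha, method="adjusted", extra=extra)
    return AdjustedEstimate(nu_stand=nu_stand, nu_aug=nu_aug, se_nu=se, pim=pim, result=result)


def pim_closed_form_check(scores: PairwiseScores, arms: np.ndarray) -> float:
    """With no covariates the estimating equations have the closed form
    tau_A = logit(nu_direct); exposed for diagnostics and testing."""
    return float(logit(win_statistics(scores, arms).nu_direct))
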