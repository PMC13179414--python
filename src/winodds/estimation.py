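"""Unadjusted win-odds estimation with two-sample U-statistic inference.

The marginal probabilistic index (MPI)

    nu = P(treated wins) + 0.5 * P(tie)

over a random treatment-control pair is estimated directly from the pair
counts; the win odds is its odds transform theta = nu / (1 - nu), which
equals (#wins + 0.5 #ties) / (#losses + 0.5 #ties).  Equivalently, with
the net benefit Delta = P(win) - P(loss), theta = (1 + Delta)/(1 - Delta).

Inference treats Delta-hat as a two-sample U-statistic with win/tie/loss
kernel in {+1, 0, -1} and uses the standard projection variance estimate;
the Wald test and confidence interval are formed on the nu scale and
mapped monotonically to theta, and delta-method results on the log-theta
scale are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .comparison import PairwiseScores

__all__ = [
    "WinStatistics",
    "WinOddsResult",
    "win_statistics",
    "direct_inference",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """The data admit no variance estimate (e.g. zero estimated variance
    away from the null)."""


@dataclass
class WinStatistics:
    """Pair counts and point estimates over treatment-vs-control pairs."""

    n_wins: float
    n_losses: float
    n_ties: float
    n0: int
    n1: int
    nu_direct: float
    delta: float
    theta: float

    @property
    def n_pairs(self) -> int:
        return self.n0 * self.n1


@dataclass
class WinOddsResult:
    """Point estimate and Wald inference for the MPI / win odds.

    Confidence intervals on theta are the nu-interval endpoints mapped
    through nu -> nu/(1-nu); the log-theta interval comes from the delta
    method with sigma_logtheta = sigma_nu / (nu (1 - nu)).  ``p_one_sided``
    tests H0: theta <= 1 (i.e. nu <= 1/2) against the treatment-favoring
    alternative.
    """

    nu_hat: float
    se_nu: float
    theta_hat: float
    z: float
    ci_nu: tuple[float, float]
    ci_theta: tuple[float, float]
    ci_log_theta: tuple[float, float]
    se_log_theta: float
    p_two_sided: float
    p_one_sided: float
    p_two_sided_log_theta: float
    p_one_sided_log_theta: float
    alpha: float
    method: str
    boundary: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "nu_hat": self.nu_hat,
            "se_nu": self.se_nu,
            "theta_hat": self.theta_hat,
            "z": self.z,
            "ci_nu_lower": self.ci_nu[0],
            "ci_nu_upper": self.ci_nu[1],
            "ci_theta_lower": self.ci_theta[0],
            "ci_theta_upper": self.ci_theta[1],
            "ci_log_theta_lower": self.ci_log_theta[0],
            "ci_log_theta_upper": self.ci_log_theta[1],
            "se_log_theta": self.se_log_theta,
            "p_two_sided": self.p_two_sided,
            "p_one_sided": self.p_one_sided,
            "p_two_sided_log_theta": self.p_two_sided_log_theta,
            "p_one_sided_log_theta": self.p_one_sided_log_theta,
            "alpha": self.alpha,
            "boundary": self.boundary,
        }
        d.update(self.extra)
        return d


def _check_arms(arms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arms = np.asarray(arms)
    if not np.isin(arms, (0, 1)).all():
        raise ValueError("arms must contain only 0 and 1")
    ctrl = np.flatnonzero(arms == 0)
    trt = np.flatnonzero(arms == 1)
    if ctrl.size == 0 or trt.size == 0:
        raise ValueError("both arms must be non-empty")
    return ctrl, trt


def win_statistics(scores: PairwiseScores, arms: np.ndarray) -> WinStatistics:
    """Tally wins/losses/ties over ordered (control i, treated j) pairs.

    nu_direct = (#wins + 0.5 #ties) / (N0 N1) is the direct MPI estimate;
    theta = nu/(1-nu) is flagged infinite when every pair is a treated win.
    """
    ctrl, trt = _check_arms(arms)
    block = scores.scores[np.ix_(ctrl, trt)]  # S_ij, i control, j treated
    n_wins = float(np.count_nonzero(block == 1.0))
    n_losses = float(np.count_nonzero(block == 0.0))
    n_ties = float(block.size - n_wins - n_losses)
    n_pairs = block.size
    nu = (n_wins + 0.5 * n_ties) / n_pairs
    delta = (n_wins - n_losses) / n_pairs
    theta = nu / (1.0 - nu) if nu < 1.0 else math.inf
    return WinStatistics(
        n_wins=n_wins,
        n_losses=n_losses,
        n_ties=n_ties,
        n0=ctrl.size,
        n1=trt.size,
        nu_direct=nu,
        delta=delta,
        theta=theta,
    )


def wald_result(
    nu_hat: float,
    se_nu: float,
    alpha: float,
    method: str,
    extra: dict | None = None,
) -> WinOddsResult:
    """Package Wald inference for nu into a :class:`WinOddsResult`.

    At the boundary (nu in {0, 1}) no interval or p-value is produced and
    the ``boundary`` flag is set.
    """
    extra = dict(extra or {})
    boundary = nu_hat in (0.0, 1.0)
    if boundary:
        theta = math.inf if nu_hat == 1.0 else 0.0
        nan = float("nan")
        return WinOddsResult(
            nu_hat=nu_hat, se_nu=se_nu, theta_hat=theta, z=nan,
            ci_nu=(nan, nan), ci_theta=(nan, nan), ci_log_theta=(nan, nan),
            se_log_theta=nan, p_two_sided=nan, p_one_sided=nan,
            p_two_sided_log_theta=nan, p_one_sided_log_theta=nan,
            alpha=alpha, method=method, boundary=True, extra=extra,
        )
    if se_nu <= 0:
        if nu_hat != 0.5:
            raise DegenerateDataError(
                f"zero estimated variance with nu_hat = {nu_hat} != 1/2"
            )
        se_nu = 0.0
    theta = nu_hat / (1.0 - nu_hat)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    if se_nu > 0:
        z = (nu_hat - 0.5) / se_nu
        lo, hi = nu_hat - zcrit * se_nu, nu_hat + zcrit * se_nu
        se_log = se_nu / (nu_hat * (1.0 - nu_hat))
        z_log = math.log(theta) / se_log
    else:
        z = 0.0
        lo = hi = nu_hat
        se_log = 0.0
        z_log = 0.0

    def odds(v: float) -> float:
        return v / (1.0 - v) if v < 1.0 else math.inf

    ci_theta = (odds(max(lo, 0.0)), odds(min(hi, 1.0)))
    ci_log = (
        math.log(theta) - zcrit * se_log,
        math.log(theta) + zcrit * se_log,
    )
    return WinOddsResult(
        nu_hat=nu_hat,
        se_nu=se_nu,
        theta_hat=theta,
        z=z,
        ci_nu=(lo, hi),
        ci_theta=ci_theta,
        ci_log_theta=ci_log,
        se_log_theta=se_log,
        p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
        p_one_sided=float(stats.norm.sf(z)),
        p_two_sided_log_theta=float(2.0 * stats.norm.sf(abs(z_log))),
        p_one_sided_log_theta=float(stats.norm.sf(z_log)),
        alpha=alpha,
        method=method,
        extra=extra,
    )


def direct_inference(
    scores: PairwiseScores, arms: np.ndarray, alpha: float = 0.05
) -> WinOddsResult:
    """Unadjusted MPI / win-odds inference.

    The net benefit Delta-hat is a two-sample U-statistic with kernel
    K_ij in {+1, 0, -1} (treated win / tie / loss).  Its variance is
    estimated by the projection components

        zeta_10 = var over control subjects of their row means of K,
        zeta_01 = var over treated subjects of their column means of K,
        Var(Delta-hat) = zeta_10 / N0 + zeta_01 / N1,

    and sigma_nu = sqrt(Var(Delta-hat)) / 2 since nu = (1 + Delta)/2.
    """
    ctrl, trt = _check_arms(arms)
    if ctrl.size < 2 or trt.size < 2:
        raise ValueError("need at least two subjects per arm for inference")
    ws = win_statistics(scores, arms)
    kernel = 2.0 * scores.scores[np.ix_(ctrl, trt)] - 1.0  # +1 win / 0 tie / -1 loss
    row_means = kernel.mean(axis=1)  # per control subject
    col_means = kernel.mean(axis=0)  # per treated subject
    zeta10 = row_means.var(ddof=1)
    zeta01 = col_means.var(ddof=1)
    var_delta = zeta10 / ctrl.size + zeta01 / trt.size
    se_nu = 0.5 * math.sqrt(var_delta)
    extra = {
        "n_wins": ws.n_wins,
        "n_losses": ws.n_losses,
        "n_ties": ws.n_ties,
        "n0": ws.n0,
        "n1": ws.n1,
        "delta": ws.delta,
    }
    return wald_result(ws.nu_direct, se_nu, alpha, method="direct", extra=extra)
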