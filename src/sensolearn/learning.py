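"""Perceptual (learning) models: binary hierarchical Gaussian filters and
associative learning rules.

All filters map a binary input series ``u`` to a belief trajectory.  The
hierarchical Gaussian filter (HGF) represents beliefs at L levels: x1 is
the binary outcome, x2 its tendency in logit units, x3 the log-volatility
of x2, and (for the 4-level variant) x4 the log-volatility of x3.  Each
level evolves as a Gaussian random walk whose step variance is controlled
by the level above, so that belief updates are precision-weighted
prediction errors.  The associative models (Rescorla-Wagner and Sutton's
K1) update a single value estimate in proportion to the prediction error,
with a fixed or error-modulated learning rate respectively.

Filters are written as plain-float loops: series are short (tens of
trials) and the inverter evaluates them inside an optimiser, where NumPy
scalar overhead dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from sensolearn.errors import ModelDivergenceError

__all__ = [
    "HGFParameters",
    "BeliefTrajectory",
    "hgf_filter",
    "rw_filter",
    "k1_filter",
    "compute_learning_rates",
    "trajectory_table",
]

_SIGMOID_CLIP = 700.0  # exp overflow guard; logits beyond this are saturated


def _sgm(x: float) -> float:
    if x < -_SIGMOID_CLIP:
        return math.exp(-_SIGMOID_CLIP) / (1.0 + math.exp(-_SIGMOID_CLIP))
    if x > _SIGMOID_CLIP:
        return 1.0 / (1.0 + math.exp(-_SIGMOID_CLIP))
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class HGFParameters:
    """Parameters of the binary HGF.

    Parameters
    ----------
    levels:
        Number of hierarchical levels, 3 or 4.
    omega2:
        Tonic log-volatility of x2 (log-variance units).
    omega3:
        Tonic log-volatility of x3; only meaningful for ``levels=4``
        (for the 3-level filter the x3 walk variance is ``theta``).
    theta:
        Variance of the top-level Gaussian random walk, > 0.  Exposed in
        log-space as ``omega_top`` for reporting symmetry with the omegas.
    kappa2, kappa3:
        Coupling strengths between adjacent levels (>= 0); fixed at 1 by
        default, the standard binary-HGF convention.
    mu0, sigma0:
        Initial means and variances for levels 2..L, ordered from level 2
        upward.  All variances must be positive.
    """

    levels: int = 3
    omega2: float = -3.0
    omega3: float = -6.0
    theta: float = 0.0025
    kappa2: float = 1.0
    kappa3: float = 1.0
    mu0: tuple[float, ...] = None  # type: ignore[assignment]
    sigma0: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.levels not in (3, 4):
            raise ValueError(f"levels must be 3 or 4, got {self.levels}")
        if not (self.theta > 0 and math.isfinite(self.theta)):
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.kappa2 < 0 or self.kappa3 < 0:
            raise ValueError("kappa couplings must be non-negative")
        n = self.levels - 1
        if self.mu0 is None:
            object.__setattr__(self, "mu0", (0.0,) + (1.0,) * (n - 1))
        if self.sigma0 is None:
            object.__setattr__(self, "sigma0", (0.1,) + (1.0,) * (n - 1))
        if len(self.mu0) != n or len(self.sigma0) != n:
            raise ValueError(
                f"mu0/sigma0 must cover levels 2..{self.levels} ({n} values)"
            )
        if any(s <= 0 for s in self.sigma0):
            raise ValueError("initial variances must be positive")

    @property
    def omega_top(self) -> float:
        """The top-level walk variance in log space (log theta)."""
        return math.log(self.theta)


@dataclass
class BeliefTrajectory:
    """Per-trial posterior beliefs of a filter run on an input series.

    ``mu[i]``/``sigma[i]`` hold the posterior mean/variance of level
    ``i`` (2..L) after each trial.  ``muhat1`` is the first-level
    prediction for each trial — the logistic of the *previous* trial's
    level-2 mean — which is also the belief the response model consumes.
    ``delta[1]`` is the outcome prediction error u - muhat1; ``delta[i]``
    for i >= 2 are volatility prediction errors.  ``lr`` holds per-trial
    effective learning rates (see :func:`compute_learning_rates`).
    """

    u: np.ndarray
    muhat1: np.ndarray
    mu: dict[int, np.ndarray]
    sigma: dict[int, np.ndarray]
    delta: dict[int, np.ndarray]
    lr: dict[int, np.ndarray] = field(default_factory=dict)
    params: HGFParameters | None = None

    @property
    def n_trials(self) -> int:
        return len(self.u)

    @property
    def levels(self) -> int:
        return max(self.mu) if self.mu else 1

    @property
    def predictions(self) -> np.ndarray:
        """Belief p(u=1) driving each trial's response (previous-trial)."""
        return self.muhat1


def hgf_filter(u: Sequence[int], params: HGFParameters) -> BeliefTrajectory:
    """Run the binary HGF forward over an input series.

    Implements the standard variational update equations for the binary
    HGF: the level-2 posterior moves by the outcome prediction error
    weighted by the ratio of prediction precisions, and each higher level
    moves by a precision-weighted volatility prediction error from the
    level below.

    Raises
    ------
    ModelDivergenceError
        If any posterior precision becomes non-positive or any state
        non-finite; the exception carries the offending trial index.
    """
    L = params.levels
    u_arr = np.asarray(u, dtype=float)
    if u_arr.ndim != 1:
        raise ValueError("u must be a 1-D binary series")
    if not np.all((u_arr == 0) | (u_arr == 1)):
        raise ValueError("u must be binary (0/1)")
    K = len(u_arr)

    k2, k3 = params.kappa2, params.kappa3
    om2, om3, th = params.omega2, params.omega3, params.theta

    mu = {i: params.mu0[i - 2] for i in range(2, L + 1)}
    sa = {i: params.sigma0[i - 2] for i in range(2, L + 1)}

    out_muhat1 = np.empty(K)
    out_mu = {i: np.empty(K) for i in range(2, L + 1)}
    out_sa = {i: np.empty(K) for i in range(2, L + 1)}
    out_da = {i: np.empty(K) for i in range(1, L)}

    for k in range(K):
        uk = float(u_arr[k])
        try:
            # --- predictions ---------------------------------------------
            muhat1 = _sgm(mu[2])
            da1 = uk - muhat1

            # level-2 prediction variance: prior spread plus the
            # volatility increment set by the level above
            sahat2 = sa[2] + math.exp(k2 * mu[3] + om2)
            pihat2 = 1.0 / sahat2
            pi2 = pihat2 + muhat1 * (1.0 - muhat1)
            sa2_new = 1.0 / pi2
            mu2_new = mu[2] + sa2_new * da1
            da2 = (sa2_new + (mu2_new - mu[2]) ** 2) / sahat2 - 1.0

            # level 3
            vol3 = th if L == 3 else math.exp(k3 * mu[4] + om3)
            sahat3 = sa[3] + vol3
            pihat3 = 1.0 / sahat3
            v2 = math.exp(k2 * mu[3] + om2)
            w2 = v2 * pihat2
            pi3 = pihat3 + 0.5 * k2 * k2 * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
            if not (pi3 > 0 and math.isfinite(pi3)):
                raise ModelDivergenceError(
                    f"level-3 precision non-positive at trial {k}", trial=k
                )
            sa3_new = 1.0 / pi3
            mu3_new = mu[3] + 0.5 * sa3_new * k2 * w2 * da2

            if L == 4:
                da3 = (sa3_new + (mu3_new - mu[3]) ** 2) / sahat3 - 1.0
                sahat4 = sa[4] + th
                pihat4 = 1.0 / sahat4
                v3 = math.exp(k3 * mu[4] + om3)
                w3 = v3 * pihat3
                pi4 = pihat4 + 0.5 * k3 * k3 * w3 * (
                    w3 + (2.0 * w3 - 1.0) * da3)
                if not (pi4 > 0 and math.isfinite(pi4)):
                    raise ModelDivergenceError(
                        f"level-4 precision non-positive at trial {k}",
                        trial=k,
                    )
                sa4_new = 1.0 / pi4
                mu4_new = mu[4] + 0.5 * sa4_new * k3 * w3 * da3
                mu[4], sa[4] = mu4_new, sa4_new
                out_da[3][k] = da3
        except OverflowError:
            raise ModelDivergenceError(
                f"state overflow at trial {k}", trial=k
            ) from None

        mu[2], sa[2] = mu2_new, sa2_new
        mu[3], sa[3] = mu3_new, sa3_new

        states = [mu[i] for i in range(2, L + 1)] \
            + [sa[i] for i in range(2, L + 1)]
        if not all(math.isfinite(s) for s in states):
            raise ModelDivergenceError(
                f"non-finite state at trial {k}", trial=k)
        if any(sa[i] <= 0 for i in range(2, L + 1)):
            raise ModelDivergenceError(
                f"non-positive variance at trial {k}", trial=k
            )

        out_muhat1[k] = muhat1
        out_da[1][k] = da1
        out_da[2][k] = da2
        for i in range(2, L + 1):
            out_mu[i][k] = mu[i]
            out_sa[i][k] = sa[i]

    traj = BeliefTrajectory(
        u=u_arr, muhat1=out_muhat1, mu=out_mu, sigma=out_sa, delta=out_da,
        params=params,
    )
    compute_learning_rates(traj)
    return traj


def compute_learning_rates(traj: BeliefTrajectory) -> dict[int, np.ndarray]:
    """Per-trial effective learning rates, stored on the trajectory.

    The level-2 rate is the fraction of the outcome prediction error
    absorbed into the first-level prediction:
    ``lr2[k] = (s(mu2[k]) - muhat1[k]) / delta1[k]``.  The level-3 (and
    level-4) rates are the analogous update/PE ratios for the volatility
    prediction errors.  Trials with a zero prediction error are NaN and
    skipped in summaries.
    """
    K = traj.n_trials
    L = traj.levels
    eps = 1e-12

    lr2 = np.full(K, np.nan)
    da1 = traj.delta[1]
    mu2 = traj.mu[2]
    for k in range(K):
        if abs(da1[k]) > eps:
            lr2[k] = (_sgm(mu2[k]) - traj.muhat1[k]) / da1[k]
    traj.lr[2] = lr2

    for lev in range(3, L + 1):
        lr = np.full(K, np.nan)
        da = traj.delta[lev - 1]
        mu = traj.mu[lev]
        prev = traj.params.mu0[lev - 2] if traj.params else np.nan
        for k in range(K):
            base = prev if k == 0 else mu[k - 1]
            if abs(da[k]) > eps:
                lr[k] = (mu[k] - base) / da[k]
        traj.lr[lev] = lr
    return traj.lr


def mean_learning_rate(traj: BeliefTrajectory, level: int,
                       mask: np.ndarray | None = None) -> float:
    """Subject summary: mean learning rate over valid trials."""
    lr = traj.lr[level]
    keep = np.isfinite(lr)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        return float("nan")
    return float(np.mean(lr[keep]))


@dataclass
class ValueTrajectory:
    """Trajectory of a single-level associative model.

    ``v`` is the post-update value estimate per trial; ``predictions``
    holds the pre-update value v^(k-1) that drives trial k's response;
    ``delta`` the prediction errors; ``alpha`` the (possibly varying)
    learning rate applied on each trial.
    """

    u: np.ndarray
    v: np.ndarray
    predictions: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.u)


def rw_filter(u: Sequence[int], alpha: float, v0: float = 0.5) -> ValueTrajectory:
    """Rescorla-Wagner delta rule: v <- v + alpha * (u - v)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not 0.0 <= v0 <= 1.0:
        raise ValueError(f"v0 must lie in [0, 1], got {v0}")
    u_arr = np.asarray(u, dtype=float)
    K = len(u_arr)
    v = np.empty(K)
    pred = np.empty(K)
    delta = np.empty(K)
    cur = v0
    for k in range(K):
        pred[k] = cur
        delta[k] = u_arr[k] - cur
        cur = cur + alpha * delta[k]
        v[k] = cur
    return ValueTrajectory(u=u_arr, v=v, predictions=pred, delta=delta,
                           alpha=np.full(K, alpha))


def k1_filter(u: Sequence[int], alpha0: float, mu_meta: float,
              v0: float = 0.5) -> ValueTrajectory:
    """Sutton's K1 (scalar IDBD) rule with an error-driven learning rate.

    The log learning rate beta accumulates the correlation between the
    current prediction error and an eligibility trace h of recent
    updates; alpha = exp(beta) is bounded to (0, 1].  With ``mu_meta=0``
    the scheme reduces exactly to Rescorla-Wagner with ``alpha0``.
    """
    if not 0.0 < alpha0 <= 1.0:
        raise ValueError(f"alpha0 must lie in (0, 1], got {alpha0}")
    if mu_meta < 0:
        raise ValueError(f"mu_meta must be non-negative, got {mu_meta}")
    if not 0.0 <= v0 <= 1.0:
        raise ValueError(f"v0 must lie in [0, 1], got {v0}")
    u_arr = np.asarray(u, dtype=float)
    K = len(u_arr)
    v = np.empty(K)
    pred = np.empty(K)
    delta = np.empty(K)
    alphas = np.empty(K)
    cur = v0
    dbeta = 0.0  # log-rate increment relative to log(alpha0)
    h = 0.0
    for k in range(K):
        pred[k] = cur
        d = u_arr[k] - cur
        delta[k] = d
        dbeta = dbeta + mu_meta * d * h
        a = min(alpha0 * math.exp(dbeta), 1.0)  # bound alpha to (0, 1]
        alphas[k] = a
        cur = cur + a * d
        v[k] = cur
        h = h * max(0.0, 1.0 - a) + a * d
    return ValueTrajectory(u=u_arr, v=v, predictions=pred,
                           delta=delta, alpha=alphas)


def trajectory_table(traj: BeliefTrajectory, subject: str = "",
                     model: str = "") -> pd.DataFrame:
    """Long-format export (subject, model, trial, level, mu, sigma,
    delta, alpha) for plotting and group analysis."""
    rows = []
    for lev in sorted(traj.mu):
        da = traj.delta.get(lev - 1)
        lr = traj.lr.get(lev)
        for k in range(traj.n_trials):
            rows.append({
                "subject": subject, "model": model, "trial": k,
                "level": lev, "mu": traj.mu[lev][k],
                "sigma": traj.sigma[lev][k],
                "delta": da[k] if da is not None else np.nan,
                "alpha": lr[k] if lr is not None else np.nan,
            })
    return pd.DataFrame(rows)
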