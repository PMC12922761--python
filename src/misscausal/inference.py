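"""Influence-function evaluation, asymptotic variance, and the bootstrap.

The targeted estimators solve the influence-function estimating equation,
so after targeting the per-record influence values average to ~0 and their
empirical second moment over n estimates the asymptotic variance of
sqrt(n) (psi_hat - psi).  The nonparametric bootstrap (resampling records,
refitting every nuisance per resample) is the recommended interval when the
nuisances are parametric; the influence-function Wald interval is the
default when they are estimated flexibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .nuisance import ConvergenceError, PositivityError

__all__ = [
    "InfluenceVector",
    "eif_ia",
    "eif_ib",
    "eif_ia_values",
    "eif_ib_values",
    "if_variance",
    "bootstrap_ci",
    "BootstrapResult",
]


@dataclass
class InfluenceVector:
    values: np.ndarray
    assumption: str  # "IA" | "IB"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("influence values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _gated(ind: np.ndarray, values: np.ndarray) -> np.ndarray:
    """ind * values with 0 wherever the indicator gates out a NaN."""
    return np.where(ind, np.nan_to_num(values, nan=0.0), 0.0)


def eif_ia_values(ind_complete_a, ind_rl, y, pi_a, pi_ra, pi_rl, t1, t0, psi) -> np.ndarray:
    """Influence values for the IA functional.

    ``1{A=a, R_A=1, R_L=1} / (pi_A pi_RA pi_RL) * (Y - T1)
    + 1{R_L=1} / pi_RL * (T1 - T0) + T0 - psi``
    with T1, T0 the post-targeting fits.  NaN values of T1 on records gated
    out by the indicators are ignored.
    """
    ind1 = np.asarray(ind_complete_a, dtype=bool)
    ind2 = np.asarray(ind_rl, dtype=bool)
    term1 = _gated(ind1, (y - t1) / (pi_a * pi_ra * pi_rl))
    term2 = _gated(ind2, (t1 - t0) / pi_rl)
    return term1 + term2 + t0 - psi


def eif_ib_values(ind_top, prefix_masks, y, pi_a, pi_ra, pi_rl_list, t_list, psi) -> np.ndarray:
    """Influence values for the IB functional.

    ``prefix_masks[k]`` is 1{Rbar_Lk = 1_k} for k = 1..q; ``t_list`` holds
    the post-targeting sequential fits ``[T~_0, T~_1, ..., T~_q]``.
    """
    q = len(pi_rl_list)
    prod_all = np.ones_like(np.asarray(y, dtype=float))
    for arr in pi_rl_list:
        prod_all = prod_all * arr
    term = _gated(np.asarray(ind_top, dtype=bool), (y - t_list[q]) / (pi_a * pi_ra * prod_all))
    prod_k = np.ones_like(prod_all)
    for k in range(1, q + 1):
        prod_k = prod_k * pi_rl_list[k - 1]
        term = term + _gated(np.asarray(prefix_masks[k], dtype=bool),
                             (t_list[k] - t_list[k - 1]) / prod_k)
    return term + t_list[0] - psi


def eif_ia(table, fit, psi: float, a: float) -> InfluenceVector:
    """Evaluate the IA influence function on a table with a post-targeting fit.

    ``fit`` must carry the updated sequential predictions in ``fit.t_star``
    (``[T1*, T0*]`` aligned with the table); raises otherwise.
    """
    t_star = getattr(fit, "t_star", None)
    if not t_star or len(t_star) != 2:
        raise ValueError("fit lacks updated (post-targeting) predictions t_star=[t1*, t0*]")
    t1, t0 = t_star
    rl = table.r_l_joint == 1
    ind1 = rl & (table.r_a == 1) & (table.a == a)
    vals = eif_ia_values(ind1, rl, table.y, fit.pi_a, fit.pi_ra, fit.pi_rl[0], t1, t0, psi)
    return InfluenceVector(vals, "IA")


def eif_ib(table, fit, psi: float, a: float, ordering) -> InfluenceVector:
    """Evaluate the IB influence function; ``fit.t_star`` is ``[T~0*..T~q*]``."""
    t_star = getattr(fit, "t_star", None)
    q = len(fit.pi_rl)
    if not t_star or len(t_star) != q + 1:
        raise ValueError("fit lacks updated predictions t_star=[t~0*, ..., t~q*]")
    idx = [table.roles.l_m_cols.index(c) for c in ordering]
    prefix = {0: np.ones(table.n, dtype=bool)}
    for k in range(1, q + 1):
        prefix[k] = prefix[k - 1] & (table.r_l[:, idx[k - 1]] == 1)
    ind_top = prefix[q] & (table.r_a == 1) & (table.a == a)
    vals = eif_ib_values(ind_top, prefix, table.y, fit.pi_a, fit.pi_ra, fit.pi_rl, t_star, psi)
    return InfluenceVector(vals, "IB")


def if_variance(iv, psi: float | None = None, level: float = 0.95):
    """Empirical second moment of the influence values as variance estimate.

    Returns ``(sigma2, se, ci)``: ``sigma2 = P_n[phi^2]``, ``se =
    sqrt(sigma2 / n)``, and the Wald interval ``psi ± z se`` (``None`` when
    no point estimate is supplied).
    """
    vals = iv.values if isinstance(iv, InfluenceVector) else np.asarray(iv, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("need at least two influence values")
    sigma2 = float(np.mean(vals**2))
    se = float(np.sqrt(sigma2 / n))
    ci = None
    if psi is not None:
        z = norm.ppf(0.5 + level / 2)
        ci = (psi - z * se, psi + z * se)
    return sigma2, se, ci


@dataclass
class BootstrapResult:
    ci: tuple[float, float]
    se: float
    estimates: np.ndarray
    n_failed: int


def bootstrap_ci(table, estimator, b: int = 1000, seed: int | None = None,
                 level: float = 0.95, max_fail_frac: float = 0.05) -> BootstrapResult:
    """Nonparametric bootstrap percentile interval.

    Records are resampled with replacement and ``estimator(table)`` (a
    closure returning a point estimate or an object with ``.psi``) is
    re-run on each resample, refitting all nuisances.  Resamples that raise
    positivity/convergence errors are skipped and counted; more than
    ``max_fail_frac`` failures is an error.  The same seed reproduces the
    interval bit-for-bit.
    """
    if b < 50:
        raise ValueError("bootstrap needs at least 50 resamples")
    rng = np.random.default_rng(seed)
    n = table.n
    estimates = []
    failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        try:
            est = estimator(table.take(idx))
        except (PositivityError, ConvergenceError):
            failed += 1
            continue
        estimates.append(float(getattr(est, "psi", est)))
    if failed > max_fail_frac * b:
        raise RuntimeError(f"{failed}/{b} bootstrap resamples failed")
    vals = np.asarray(estimates)
    alpha = 1 - level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult((float(lo), float(hi)), float(vals.std(ddof=1)), vals, failed)
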