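"""The estimator roster for E(Y^a) under partially missing exposure/confounders.

Targeted estimators
    * :class:`CompleteDataTMLE` — standard one-step-targeted estimate on
      fully observed data (also the building block for the complete-case and
      multiple-imputation pathways).
    * :class:`TMLEA` — TMLE for the IA functional (single block indicator
      for L_M): initial outcome regression, a weighted intercept fluctuation
      among complete exposed-at-a records, a second regression onto L_O and
      a second fluctuation.  Multiply robust.
    * :class:`TMLEB` — TMLE for the IB functional with per-covariate
      indicators: a top-level fluctuation followed by a backward recursion of
      regression + fluctuation through the monotone coarsening levels.

Plug-in comparators
    * :class:`ICEEstimator` — iterated conditional expectations (sequential
      regressions, no weighting); consistent only when the outcome
      regressions are correct.
    * :class:`IPWEstimator` — Horvitz-Thompson weighting by the inverse
      exposure/observation probabilities; consistent only when those models
      are correct.
    * :class:`CompleteCaseTMLE` and :class:`MITMLE` — the complete-case and
      multiple-imputation (chained equations + Rubin's rules) pathways.

All classes follow the scikit-learn estimator protocol: parameters are set
in ``__init__``, ``fit(data)`` consumes a DataFrame (with
``roles``) or an :class:`~misscausal.data.ObservedTable`, and fitted
attributes carry a trailing underscore (``psi_``, ``se_``, ``ci_``, ...).
Module-level functions (`tmle_a`, `ipw`, ...) are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist
from sklearn.base import BaseEstimator

from .data import ObservedTable, VariableRoles, coarsen_monotone, summarize_missingness
from .inference import (
    InfluenceVector,
    bootstrap_ci,
    eif_ia,
    eif_ib,
    if_variance,
)
from .nuisance import (
    PSEUDO_CLIP,
    NuisanceSpecs,
    PositivityError,
    RegressionSpec,
    estimate_nuisances_ia,
    estimate_nuisances_ib,
    fit_weighted_regression,
    solve_fluctuation,
)

__all__ = [
    "EstimateResult",
    "tmle_complete",
    "tmle_a",
    "tmle_b",
    "ice",
    "ipw",
    "ipw_from_nuisances",
    "estimate_contrast",
    "mi_then_tmle",
    "CompleteDataTMLE",
    "CompleteCaseTMLE",
    "TMLEA",
    "TMLEB",
    "ICEEstimator",
    "IPWEstimator",
    "MITMLE",
]


@dataclass
class EstimateResult:
    """Point estimate of E(Y^a) with inference and diagnostics."""

    psi: float
    estimator: str
    assumption: str  # "MAR" | "IA" | "IB" | "complete"
    n: int
    influence: np.ndarray | None = None
    sigma2: float | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None
    ci_method: str | None = None
    epsilons: tuple[float, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "assumption": self.assumption,
            "psi": self.psi,
            "se": self.se,
            "ci_lower": None if self.ci is None else self.ci[0],
            "ci_upper": None if self.ci is None else self.ci[1],
            "ci_method": self.ci_method,
            "n": self.n,
        }


def _clip01(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PSEUDO_CLIP, 1 - PSEUDO_CLIP)


def _attach_if_inference(res: EstimateResult, iv: InfluenceVector) -> EstimateResult:
    res.influence = iv.values
    res.sigma2, res.se, res.ci = if_variance(iv, psi=res.psi)
    res.ci_method = "if-wald"
    return res


def _default_specs(specs: NuisanceSpecs | None) -> NuisanceSpecs:
    return specs if specs is not None else NuisanceSpecs()


# ----------------------------------------------------------------------
# complete-data TMLE


def tmle_complete(table: ObservedTable, specs: NuisanceSpecs | None = None, a: float = 1.0) -> EstimateResult:
    """One-step-targeted estimate of E(Y^a) on fully observed data."""
    specs = _default_specs(specs)
    if not table.complete_mask.all():
        raise ValueError("tmle_complete requires fully observed data (take the complete cases first)")
    roles = table.roles
    df = table.frame()
    l_cols = list(roles.l_cols)
    ind_a = table.a == a
    if not ind_a.any():
        raise PositivityError(f"no records with A = {a}")

    fit_a = fit_weighted_regression(df, ind_a.astype(float), specs.exposure, l_cols)
    pi_a = np.clip(fit_a.predict(df), specs.truncation, 1 - specs.truncation) \
        if specs.truncation > 0 else fit_a.predict(df)
    if (pi_a[ind_a] <= 0).any():
        raise PositivityError("zero estimated exposure probability among exposed records")

    fit_q = fit_weighted_regression(df, table.y, specs.outcome, [roles.exposure_col] + l_cols)
    df_a = df.copy()
    df_a[roles.exposure_col] = float(a)
    q0 = _clip01(fit_q.predict(df_a))
    fluct = solve_fluctuation(table.y[ind_a], logit(q0[ind_a]), 1.0 / pi_a[ind_a])
    q_star = expit(logit(q0) + fluct.epsilon)
    psi = float(q_star.mean())
    iv = np.where(ind_a, (table.y - q_star) / pi_a, 0.0) + q_star - psi
    res = EstimateResult(
        psi=psi, estimator="cc-tmle", assumption="complete", n=table.n,
        epsilons=(fluct.epsilon,),
        diagnostics={"fluctuation_converged": fluct.converged,
                     "pi_a_range": (float(pi_a.min()), float(pi_a.max()))},
    )
    return _attach_if_inference(res, InfluenceVector(iv, "IA"))


# ----------------------------------------------------------------------
# TMLE-A


def tmle_a(table: ObservedTable, specs: NuisanceSpecs | None = None, a: float = 1.0) -> EstimateResult:
    """TMLE for the IA functional (joint block indicator R_L for L_M).

    Steps: fit pi_A, pi_RA, pi_RL and the initial outcome regression; a
    weighted intercept fluctuation of T1 among (A=a, R_A=1, R_L=1) with
    weight 1/(pi_A pi_RA pi_RL); regress the update onto L_O among R_L=1;
    fluctuate again with weight 1/pi_RL; average.
    """
    specs = _default_specs(specs)
    roles = table.roles
    fit = estimate_nuisances_ia(table, specs, a)
    rl = table.r_l_joint == 1
    ind1 = rl & (table.r_a == 1) & (table.a == a)
    if not ind1.any():
        raise PositivityError(f"no complete records with A = {a}")

    t1_0 = np.full(table.n, np.nan)
    t1_0[rl] = _clip01(fit.t_init[rl])
    w1 = 1.0 / (fit.pi_a * fit.pi_ra * fit.pi_rl[0])
    fl1 = solve_fluctuation(table.y[ind1], logit(t1_0[ind1]), w1[ind1])
    t1_star = np.full(table.n, np.nan)
    t1_star[rl] = expit(logit(t1_0[rl]) + fl1.epsilon)

    df = table.frame()
    fit_t0 = fit_weighted_regression(df[rl], t1_star[rl], specs.outcome_seq, list(roles.l_o_cols))
    t0_0 = _clip01(fit_t0.predict(df))
    fl0 = solve_fluctuation(t1_star[rl], logit(t0_0[rl]), 1.0 / fit.pi_rl[0][rl])
    t0_star = expit(logit(t0_0) + fl0.epsilon)

    psi = float(t0_star.mean())
    fit.t_star = [t1_star, t0_star]
    iv = eif_ia(table, fit, psi, a)
    res = EstimateResult(
        psi=psi, estimator="tmle-a", assumption="IA", n=table.n,
        epsilons=(fl1.epsilon, fl0.epsilon),
        diagnostics={
            **fit.diagnostics,
            "fluctuations_converged": (fl1.converged, fl0.converged),
            "weight_max": float(w1[ind1].max()),
        },
    )
    return _attach_if_inference(res, iv)


# ----------------------------------------------------------------------
# TMLE-B


def _resolve_ordering(table: ObservedTable, ordering: Sequence[str] | None) -> list[str]:
    if ordering is not None:
        order = list(ordering)
        if sorted(order) != sorted(table.roles.l_m_cols):
            raise ValueError(f"ordering must be a permutation of {table.roles.l_m_cols}")
        return order
    summary = summarize_missingness(table)
    order = sorted(table.roles.l_m_cols, key=lambda c: summary.frac_missing[c])
    warnings.warn(
        "no L_M ordering supplied: defaulting to increasing missingness "
        f"fraction {order}; a known causal ordering of the missingness "
        "process should override this",
        UserWarning,
        stacklevel=3,
    )
    return order


def tmle_b(
    table: ObservedTable,
    specs: NuisanceSpecs | None = None,
    a: float = 1.0,
    ordering: Sequence[str] | None = None,
) -> EstimateResult:
    """TMLE for the IB functional (per-covariate indicators, monotone order).

    Non-monotone input is coarsened automatically (with a logged count of
    dropped cells).  The top fluctuation targets the outcome regression
    among fully observed records at A=a; the backward recursion then
    alternates sequential regression and fluctuation down to a function of
    L_O alone, whose average is the estimate.
    """
    specs = _default_specs(specs)
    roles = table.roles
    if roles.q == 0:
        raise ValueError("IB estimators require at least one partially observed covariate")
    order = _resolve_ordering(table, ordering)
    n_cells_before = int(table.r_l.sum())
    work = table if table.is_monotone(order) else coarsen_monotone(table, order)
    n_coarsened = n_cells_before - int(work.r_l.sum())

    fit = estimate_nuisances_ib(work, specs, a, order)
    q = len(order)
    idx = [roles.l_m_cols.index(c) for c in order]
    prefix = {0: np.ones(work.n, dtype=bool)}
    for k in range(1, q + 1):
        prefix[k] = prefix[k - 1] & (work.r_l[:, idx[k - 1]] == 1)
    ind_top = prefix[q] & (work.r_a == 1) & (work.a == a)
    if not ind_top.any():
        raise PositivityError(f"no fully observed records with A = {a}")

    df = work.frame()
    pi_rl_cum = [None] * (q + 1)
    prod = np.ones(work.n)
    for k in range(1, q + 1):
        prod = prod * fit.pi_rl[k - 1]
        pi_rl_cum[k] = prod.copy()

    t_cur0 = np.full(work.n, np.nan)
    t_cur0[prefix[q]] = _clip01(fit.t_init[prefix[q]])
    w_top = 1.0 / (fit.pi_a * fit.pi_ra * pi_rl_cum[q])
    fl = solve_fluctuation(work.y[ind_top], logit(t_cur0[ind_top]), w_top[ind_top])
    epsilons = [fl.epsilon]
    converged = [fl.converged]
    t_star: dict[int, np.ndarray] = {}
    t_cur = np.full(work.n, np.nan)
    t_cur[prefix[q]] = expit(logit(t_cur0[prefix[q]]) + fl.epsilon)
    t_star[q] = t_cur

    for k in range(q, 0, -1):
        cond = list(roles.l_o_cols) + order[: k - 1]
        m_k, m_km1 = prefix[k], prefix[k - 1]
        fit_k = fit_weighted_regression(df[m_k], t_star[k][m_k], specs.outcome_seq, cond)
        t_km1_0 = np.full(work.n, np.nan)
        t_km1_0[m_km1] = _clip01(fit_k.predict(df[m_km1]))
        fl_k = solve_fluctuation(
            t_star[k][m_k], logit(t_km1_0[m_k]), 1.0 / pi_rl_cum[k][m_k]
        )
        epsilons.append(fl_k.epsilon)
        converged.append(fl_k.converged)
        t_new = np.full(work.n, np.nan)
        t_new[m_km1] = expit(logit(t_km1_0[m_km1]) + fl_k.epsilon)
        t_star[k - 1] = t_new

    psi = float(t_star[0].mean())
    fit.t_star = [t_star[k] for k in range(q + 1)]
    iv = eif_ib(work, fit, psi, a, order)
    res = EstimateResult(
        psi=psi, estimator="tmle-b", assumption="IB", n=work.n,
        epsilons=tuple(epsilons),
        diagnostics={
            **fit.diagnostics,
            "ordering": tuple(order),
            "cells_coarsened": n_coarsened,
            "fluctuations_converged": tuple(converged),
            "weight_max": float(w_top[ind_top].max()),
        },
    )
    return _attach_if_inference(res, iv)


# ----------------------------------------------------------------------
# ICE and IPW plug-ins


def ice(
    table: ObservedTable,
    specs: NuisanceSpecs | None = None,
    a: float = 1.0,
    mode: str = "ia",
    ordering: Sequence[str] | None = None,
) -> EstimateResult:
    """Iterated-conditional-expectation plug-in (no weighting, no targeting).

    Consistent when the sequential outcome regressions are correct; carries
    no influence-function standard error (bootstrap only).
    """
    specs = _default_specs(specs)
    roles = table.roles
    df = table.frame()
    l_cols = list(roles.l_cols)
    if mode == "ia":
        rl = table.r_l_joint == 1
        r = rl & (table.r_a == 1)
        fit_t1 = fit_weighted_regression(df[r], table.y[r], specs.outcome, [roles.exposure_col] + l_cols)
        df_a = df.copy()
        df_a[roles.exposure_col] = float(a)
        t1 = np.full(table.n, np.nan)
        t1[rl] = fit_t1.predict(df_a[rl])
        fit_t0 = fit_weighted_regression(df[rl], t1[rl], specs.outcome_seq, list(roles.l_o_cols))
        psi = float(fit_t0.predict(df).mean())
        label, assumption = "ice-a", "IA"
    elif mode == "ib":
        order = _resolve_ordering(table, ordering)
        work = table if table.is_monotone(order) else coarsen_monotone(table, order)
        df = work.frame()
        idx = [roles.l_m_cols.index(c) for c in order]
        q = len(order)
        prefix = {0: np.ones(work.n, dtype=bool)}
        for k in range(1, q + 1):
            prefix[k] = prefix[k - 1] & (work.r_l[:, idx[k - 1]] == 1)
        r = prefix[q] & (work.r_a == 1)
        fit_t = fit_weighted_regression(
            df[r], work.y[r], specs.outcome, [roles.exposure_col] + list(roles.l_o_cols) + order
        )
        df_a = df.copy()
        df_a[roles.exposure_col] = float(a)
        t = np.full(work.n, np.nan)
        t[prefix[q]] = fit_t.predict(df_a[prefix[q]])
        for k in range(q, 0, -1):
            cond = list(roles.l_o_cols) + order[: k - 1]
            fit_k = fit_weighted_regression(df[prefix[k]], t[prefix[k]], specs.outcome_seq, cond)
            t_new = np.full(work.n, np.nan)
            t_new[prefix[k - 1]] = fit_k.predict(df[prefix[k - 1]])
            t = t_new
        psi = float(t.mean())
        label, assumption = "ice-b", "IB"
    else:
        raise ValueError("mode must be 'ia' or 'ib'")
    return EstimateResult(psi=psi, estimator=label, assumption=assumption, n=table.n)


def ipw_from_nuisances(table: ObservedTable, fit, a: float) -> EstimateResult:
    """Horvitz-Thompson estimate from an already-fitted nuisance set."""
    if fit.mode == "ia":
        obs = (table.r_l_joint == 1) & (table.r_a == 1)
    else:
        obs = table.complete_mask
    ind = obs & (table.a == a)
    denom = fit.pi_a * fit.pi_ra * fit.pi_rl_prod
    if (denom[ind] <= 0).any():
        raise PositivityError("zero probability weight; increase truncation")
    w = np.where(ind, 1.0 / denom, 0.0)
    psi = float(np.mean(w * table.y))
    return EstimateResult(
        psi=psi, estimator=f"ipw-{fit.mode[-1]}", assumption=fit.mode.upper(), n=table.n,
        diagnostics={"weight_range": (float(w[ind].min()), float(w[ind].max())),
                     "sum_weights": float(w.sum())},
    )


def ipw(
    table: ObservedTable,
    specs: NuisanceSpecs | None = None,
    a: float = 1.0,
    mode: str = "ia",
    ordering: Sequence[str] | None = None,
) -> EstimateResult:
    """Inverse-probability-weighted plug-in for the IA or IB functional.

    Weights complete records at A=a by the inverse of the estimated
    exposure and observation probabilities; consistent when those models
    are correct.  Diagnostics report the weight extremes.
    """
    specs = _default_specs(specs)
    if mode == "ia":
        fit = estimate_nuisances_ia(table, specs, a)
        return ipw_from_nuisances(table, fit, a)
    if mode == "ib":
        order = _resolve_ordering(table, ordering)
        work = table if table.is_monotone(order) else coarsen_monotone(table, order)
        fit = estimate_nuisances_ib(work, specs, a, order)
        return ipw_from_nuisances(work, fit, a)
    raise ValueError("mode must be 'ia' or 'ib'")


# ----------------------------------------------------------------------
# multiple imputation


def _fcs_impute(table: ObservedTable, spec: RegressionSpec, rng: np.random.Generator,
                iterations: int) -> ObservedTable:
    """One chained-equations completion of the table (proper draws).

    Each partially observed variable is imputed in turn from a conditional
    model given all other analysis variables (including the outcome); model
    parameters are drawn from an approximate posterior — exact conjugate
    Beta draws per stratum for saturated specs on binary data, a normal
    approximation around the MLE otherwise.
    """
    roles = table.roles
    work: dict[str, np.ndarray] = {roles.outcome_col: table.y.copy(),
                                   roles.exposure_col: table.a.copy()}
    for c in roles.l_o_cols:
        work[c] = table.l_o[c].to_numpy(dtype=float)
    for c in roles.l_m_cols:
        work[c] = table.l_m[c].to_numpy(dtype=float)
    targets = []
    if (table.r_a == 0).any():
        targets.append((roles.exposure_col, table.r_a == 1))
    for k, c in enumerate(roles.l_m_cols):
        if (table.r_l[:, k] == 0).any():
            targets.append((c, table.r_l[:, k] == 1))
    all_cols = [roles.outcome_col, roles.exposure_col, *roles.l_cols]
    # initialize by resampling observed values
    for col, obs in targets:
        work[col] = work[col].copy()
        work[col][~obs] = rng.choice(work[col][obs], size=int((~obs).sum()), replace=True)

    from .nuisance import StratumCoder, _design, _irls_logit

    for _ in range(iterations):
        for col, obs in targets:
            cond = [c for c in all_cols if c != col]
            miss = ~obs
            y_obs = work[col][obs]
            binary = set(np.unique(y_obs)) <= {0.0, 1.0}
            if not binary:
                # linear model with posterior-perturbed coefficients
                X = np.column_stack([np.ones(int(obs.sum()))] + [work[c][obs] for c in cond])
                coef, *_ = np.linalg.lstsq(X, y_obs, rcond=None)
                resid = y_obs - X @ coef
                dof = max(len(y_obs) - X.shape[1], 1)
                sigma2 = float(resid @ resid) / dof
                cov = sigma2 * np.linalg.pinv(X.T @ X)
                draw = rng.multivariate_normal(coef, cov)
                Xm = np.column_stack([np.ones(int(miss.sum()))] + [work[c][miss] for c in cond])
                work[col][miss] = Xm @ draw + rng.normal(0, np.sqrt(sigma2), int(miss.sum()))
                continue
            if spec.flavor == "saturated":
                cols = spec.resolve_columns(cond)
                keys = np.column_stack([work[c] for c in cols])
                coder = StratumCoder(keys)
                codes = coder.encode(keys)
                n1 = np.bincount(codes[obs], weights=y_obs, minlength=coder.n_codes)
                n_tot = np.bincount(codes[obs], minlength=coder.n_codes)
                p_draw = rng.beta(n1 + 0.5, n_tot - n1 + 0.5)
                probs = p_draw[codes[miss]]
            else:
                terms = spec.resolve_terms(cond)
                obs_frame = {c: work[c][obs] for c in cond}
                X = _design(obs_frame, terms)
                beta = _irls_logit(X, y_obs, np.ones(len(y_obs)), np.zeros(len(y_obs)))
                mu = expit(X @ beta)
                W = np.clip(mu * (1 - mu), 1e-10, None)
                cov = np.linalg.pinv(X.T @ (X * W[:, None]))
                draw = rng.multivariate_normal(beta, cov)
                miss_frame = {c: work[c][miss] for c in cond}
                probs = expit(_design(miss_frame, terms) @ draw)
            work[col][miss] = (rng.random(int(miss.sum())) < probs).astype(float)

    return ObservedTable.from_dataframe(pd.DataFrame(work), roles)


def mi_then_tmle(
    table: ObservedTable,
    specs: NuisanceSpecs | None = None,
    a: float = 1.0,
    m: int = 25,
    seed: int | None = None,
    fcs_iterations: int = 10,
) -> EstimateResult:
    """Multiple imputation of A and L_M, complete-data TMLE, Rubin pooling.

    Valid under MAR.  Point estimate is the mean over the ``m`` completed
    datasets; the variance combines within-imputation influence-function
    variance and between-imputation spread with the usual (1 + 1/m) factor;
    the interval uses the Rubin t reference distribution.
    """
    specs = _default_specs(specs)
    if m < 2:
        raise ValueError("multiple imputation requires m >= 2")
    rng = np.random.default_rng(seed)
    psis, variances = [], []
    for _ in range(m):
        completed = _fcs_impute(table, specs.imputation, rng, fcs_iterations)
        res = tmle_complete(completed, specs, a)
        psis.append(res.psi)
        variances.append(res.se**2)
    psis = np.asarray(psis)
    psi = float(psis.mean())
    w_var = float(np.mean(variances))
    b_var = float(psis.var(ddof=1))
    total = w_var + (1 + 1 / m) * b_var
    se = float(np.sqrt(total))
    if b_var > 0:
        dof = (m - 1) * (1 + w_var / ((1 + 1 / m) * b_var)) ** 2
        crit = t_dist.ppf(0.975, dof)
    else:
        crit = norm.ppf(0.975)
    return EstimateResult(
        psi=psi, estimator="mi-tmle", assumption="MAR", n=table.n,
        se=se, ci=(psi - crit * se, psi + crit * se), ci_method="rubin",
        diagnostics={"m": m, "within_var": w_var, "between_var": b_var},
    )


def estimate_contrast(res1: EstimateResult, res0: EstimateResult) -> EstimateResult:
    """Difference of two average-potential-outcome estimates, e.g. the
    causal risk difference E(Y^1) - E(Y^0).

    When both results carry influence values (TMLEs), the delta-method
    influence function is their per-record difference, giving a joint
    Wald interval; otherwise only the point estimate is returned.
    """
    psi = res1.psi - res0.psi
    res = EstimateResult(
        psi=psi, estimator=f"{res1.estimator}-contrast",
        assumption=res1.assumption, n=res1.n,
        diagnostics={"psi_1": res1.psi, "psi_0": res0.psi},
    )
    if res1.influence is not None and res0.influence is not None:
        if len(res1.influence) != len(res0.influence):
            raise ValueError("contrast requires results fit on the same records")
        return _attach_if_inference(res, InfluenceVector(res1.influence - res0.influence,
                                                         res1.assumption))
    return res


# ----------------------------------------------------------------------
# scikit-learn style classes


class _BaseAPOEstimator(BaseEstimator):
    """Shared fit plumbing: table coercion, CI dispatch, fitted attributes."""

    _label = "base"

    def __init__(self, roles=None, a=1.0, specs=None, ci="if", n_boot=1000, random_state=None):
        self.roles = roles
        self.a = a
        self.specs = specs
        self.ci = ci
        self.n_boot = n_boot
        self.random_state = random_state

    def _as_table(self, data) -> ObservedTable:
        if isinstance(data, ObservedTable):
            return data
        if self.roles is None:
            raise ValueError("roles must be supplied to fit a raw DataFrame")
        return ObservedTable.from_dataframe(pd.DataFrame(data), self.roles)

    def _estimate(self, table: ObservedTable) -> EstimateResult:  # pragma: no cover
        raise NotImplementedError

    def fit(self, data, y=None):
        table = self._as_table(data)
        result = self._estimate(table)
        if self.ci == "boot":
            boot = bootstrap_ci(
                table, lambda t: self._estimate(t).psi, b=self.n_boot, seed=self.random_state
            )
            if result.ci is not None:
                result.diagnostics["wald_ci"] = result.ci
            result.se, result.ci, result.ci_method = boot.se, boot.ci, "boot-percentile"
            result.diagnostics["boot_failed"] = boot.n_failed
        self.result_ = result
        self.psi_ = result.psi
        self.se_ = result.se
        self.ci_ = result.ci
        self.sigma2_ = result.sigma2
        self.influence_ = result.influence
        self.epsilons_ = result.epsilons
        self.diagnostics_ = result.diagnostics
        self.n_ = result.n
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "result_")


class CompleteDataTMLE(_BaseAPOEstimator):
    """Standard TMLE of E(Y^a) on fully observed data."""

    _label = "cc-tmle"

    def _estimate(self, table):
        return tmle_complete(table, self.specs, self.a)


class CompleteCaseTMLE(_BaseAPOEstimator):
    """Complete-case analysis: drop incomplete records, then complete-data TMLE.

    Valid under MCAR; biased whenever missingness depends on variables
    related to the outcome.
    """

    _label = "cc-tmle"

    def _estimate(self, table):
        idx = np.flatnonzero(table.complete_mask)
        if len(idx) == 0:
            raise PositivityError("no complete cases")
        res = tmle_complete(table.take(idx), self.specs, self.a)
        res.diagnostics["n_complete"] = len(idx)
        return res


class TMLEA(_BaseAPOEstimator):
    """TMLE for the IA functional; multiply robust (see module docstring)."""

    _label = "tmle-a"

    def _estimate(self, table):
        return tmle_a(table, self.specs, self.a)


class TMLEB(_BaseAPOEstimator):
    """TMLE for the IB functional with a monotone L_M ordering."""

    _label = "tmle-b"

    def __init__(self, roles=None, a=1.0, specs=None, ordering=None, ci="if",
                 n_boot=1000, random_state=None):
        super().__init__(roles=roles, a=a, specs=specs, ci=ci, n_boot=n_boot,
                         random_state=random_state)
        self.ordering = ordering

    def _estimate(self, table):
        return tmle_b(table, self.specs, self.a, self.ordering)


class ICEEstimator(_BaseAPOEstimator):
    """Sequential-regression plug-in; bootstrap is the only available CI."""

    _label = "ice"

    def __init__(self, roles=None, a=1.0, specs=None, mode="ia", ordering=None,
                 ci=None, n_boot=1000, random_state=None):
        super().__init__(roles=roles, a=a, specs=specs, ci=ci, n_boot=n_boot,
                         random_state=random_state)
        self.mode = mode
        self.ordering = ordering

    def _estimate(self, table):
        return ice(table, self.specs, self.a, self.mode, self.ordering)


class IPWEstimator(_BaseAPOEstimator):
    """Horvitz-Thompson plug-in; bootstrap is the only available CI."""

    _label = "ipw"

    def __init__(self, roles=None, a=1.0, specs=None, mode="ia", ordering=None,
                 ci=None, n_boot=1000, random_state=None):
        super().__init__(roles=roles, a=a, specs=specs, ci=ci, n_boot=n_boot,
                         random_state=random_state)
        self.mode = mode
        self.ordering = ordering

    def _estimate(self, table):
        return ipw(table, self.specs, self.a, self.mode, self.ordering)


class MITMLE(_BaseAPOEstimator):
    """Multiple imputation + complete-data TMLE with Rubin's rules."""

    _label = "mi-tmle"

    def __init__(self, roles=None, a=1.0, specs=None, m=25, fcs_iterations=10,
                 ci="rubin", n_boot=1000, random_state=None):
        super().__init__(roles=roles, a=a, specs=specs, ci=ci, n_boot=n_boot,
                         random_state=random_state)
        self.m = m
        self.fcs_iterations = fcs_iterations

    def _estimate(self, table):
        return mi_then_tmle(table, self.specs, self.a, m=self.m,
                            seed=self.random_state, fcs_iterations=self.fcs_iterations)

    def fit(self, data, y=None):
        table = self._as_table(data)
        self.result_ = self._estimate(table)
        self.psi_ = self.result_.psi
        self.se_ = self.result_.se
        self.ci_ = self.result_.ci
        self.sigma2_ = self.result_.sigma2
        self.influence_ = self.result_.influence
        self.epsilons_ = self.result_.epsilons
        self.diagnostics_ = self.result_.diagnostics
        self.n_ = self.result_.n
        return self
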