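"""Nuisance-function fitting and the one-dimensional fluctuation solver.

Every estimator in the package is built from three ingredients fitted here:

* exposure and missingness probability models ``pi_A(L)``,
  ``pi_RA(L)``, ``pi_RL(L_O)`` (IA mode: one block indicator) or
  ``pi_RLk(Lbar_M,k-1, L_O)`` for ``k = 1..q`` (IB mode),
* initial sequential outcome regressions (``T1/T0`` or ``T~_q..T~_0``), and
* an intercept-only "fluctuation" regression with observational weights and
  an offset on the link scale, whose root is the targeting update.

Three regression flavors are supported: ``parametric`` (weighted
iteratively-reweighted least squares for the logit link, weighted least
squares for the identity link), ``saturated`` (exact stratum means over a
fully discrete conditioning set, equivalent to a fully interacted GLM), and
``learner`` (any object with fit/predict for the initial outcome fits).
Probability predictions are truncated to ``[trunc, 1 - trunc]`` for
finite-sample stability of the inverse weights; the default 0.01 can be set
to 0 for exact saturated-model checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "PositivityError",
    "ConvergenceError",
    "RegressionSpec",
    "NuisanceSpecs",
    "NuisanceFit",
    "FluctuationResult",
    "fit_weighted_regression",
    "solve_fluctuation",
    "estimate_nuisances_ia",
    "estimate_nuisances_ib",
]

PSEUDO_CLIP = 1e-6  # pseudo-outcomes are clipped to [clip, 1-clip] before the link
EPS_MAX = 10.0  # bound for the fluctuation parameter when no finite root exists


class PositivityError(RuntimeError):
    """An estimator needed a conditioning stratum with no (or zero) mass."""


class ConvergenceError(RuntimeError):
    """A regression or root-finding step failed to converge."""


@dataclass(frozen=True)
class RegressionSpec:
    """How one nuisance regression is fit.

    ``terms`` lists predictors (strings, or tuples of columns for products);
    ``None`` means main effects of the conditioning set stated in the
    estimator definition.  ``exclude`` drops columns from the conditioning
    set first — the hook used to misspecify a model deliberately.
    """

    terms: tuple | None = None
    flavor: str = "parametric"  # "parametric" | "saturated" | "learner"
    link: str = "logit"  # "logit" | "identity"
    learner: object = None
    exclude: tuple[str, ...] = ()

    def resolve_columns(self, conditioning: Sequence[str]) -> list[str]:
        return [c for c in conditioning if c not in self.exclude]

    def resolve_terms(self, conditioning: Sequence[str]) -> list:
        if self.terms is not None:
            return [t for t in self.terms if not (set([t] if isinstance(t, str) else t) & set(self.exclude))]
        return list(self.resolve_columns(conditioning))


@dataclass(frozen=True)
class NuisanceSpecs:
    """Specs for the full nuisance roster plus the truncation bound."""

    outcome: RegressionSpec = field(default_factory=RegressionSpec)       # T1 / T~q : Y ~ A + L
    outcome_seq: RegressionSpec = field(default_factory=RegressionSpec)   # T0 / T~k
    exposure: RegressionSpec = field(default_factory=RegressionSpec)      # pi_A
    r_a: RegressionSpec = field(default_factory=RegressionSpec)           # pi_RA
    r_l: RegressionSpec = field(default_factory=RegressionSpec)           # pi_RL(k)
    imputation: RegressionSpec = field(default_factory=RegressionSpec)    # MI conditional models
    truncation: float = 0.01

    @classmethod
    def saturated(cls, truncation: float = 0.01) -> "NuisanceSpecs":
        sat = RegressionSpec(flavor="saturated")
        return cls(outcome=sat, outcome_seq=sat, exposure=sat, r_a=sat, r_l=sat,
                   imputation=sat, truncation=truncation)

    def replace(self, **kw) -> "NuisanceSpecs":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# fitted prediction functions


def _col(df, name: str) -> np.ndarray:
    col = df[name]
    return col.to_numpy(dtype=float) if hasattr(col, "to_numpy") else np.asarray(col, dtype=float)


def _design(df, terms: Sequence) -> np.ndarray:
    n = len(next(iter(df.values()))) if isinstance(df, dict) else len(df)
    cols = [np.ones(n)]
    for t in terms:
        if isinstance(t, str):
            cols.append(_col(df, t))
        else:
            prod = np.ones(n)
            for c in t:
                prod = prod * _col(df, c)
            cols.append(prod)
    return np.column_stack(cols)


class StratumCoder:
    """Mixed-radix integer codes for rows of a discrete covariate matrix."""

    def __init__(self, keys: np.ndarray):
        self.col_values = [np.unique(keys[:, j]) for j in range(keys.shape[1])]
        self.n_codes = int(np.prod([len(v) for v in self.col_values]))

    def encode(self, keys: np.ndarray, strict: bool = True) -> np.ndarray:
        code = np.zeros(len(keys), dtype=np.int64)
        mult = 1
        for j, vals in enumerate(self.col_values):
            idx = np.searchsorted(vals, keys[:, j])
            idx_c = np.clip(idx, 0, len(vals) - 1)
            if strict and not (vals[idx_c] == keys[:, j]).all():
                bad = keys[~(vals[idx_c] == keys[:, j])][0]
                raise PositivityError(f"stratum {tuple(bad)} has a covariate value unseen at fit time")
            code += idx_c * mult
            mult *= len(vals)
        return code

    def decode(self, code: int) -> tuple:
        out = []
        for vals in self.col_values:
            out.append(float(vals[code % len(vals)]))
            code //= len(vals)
        return tuple(out)


class ParametricFit:
    """GLM fit with coefficients solving the weighted score equations."""

    def __init__(self, terms: Sequence, coef: np.ndarray, link: str):
        self.terms = list(terms)
        self.coef_ = coef
        self.link = link

    def predict(self, df: pd.DataFrame, offset: np.ndarray | None = None) -> np.ndarray:
        eta = _design(df, self.terms) @ self.coef_
        if offset is not None:
            eta = eta + offset
        return expit(eta) if self.link == "logit" else eta


class SaturatedFit:
    """Exact weighted stratum means over a discrete conditioning set."""

    def __init__(self, cols: Sequence[str], coder: "StratumCoder", mean_by_code: np.ndarray,
                 link: str = "logit"):
        self.cols = list(cols)
        self.coder = coder
        self.mean_by_code = mean_by_code  # NaN for strata unseen at fit time
        self.link = link

    @property
    def means(self) -> dict:
        return {
            self.coder.decode(c): m
            for c, m in enumerate(self.mean_by_code)
            if not np.isnan(m)
        }

    def _keys(self, df) -> np.ndarray:
        return np.column_stack([_col(df, c) for c in self.cols])

    def predict(self, df, offset: np.ndarray | None = None) -> np.ndarray:
        if offset is not None:
            raise ValueError("saturated fits do not accept an offset")
        out = self.mean_by_code[self.coder.encode(self._keys(df))]
        if np.isnan(out).any():
            i = int(np.flatnonzero(np.isnan(out))[0])
            stratum = dict(zip(self.cols, self._keys(df)[i]))
            raise PositivityError(f"stratum {stratum} unseen at fit time")
        return out


class ConstantFit:
    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, df: pd.DataFrame, offset: np.ndarray | None = None) -> np.ndarray:
        return np.full(len(df), self.value)


class LearnerFit:
    """Wrapper around a user-supplied fit/predict regressor."""

    def __init__(self, learner, cols: Sequence[str]):
        self.learner = learner
        self.cols = list(cols)

    def predict(self, df: pd.DataFrame, offset: np.ndarray | None = None) -> np.ndarray:
        if offset is not None:
            raise ValueError("learner fits do not accept an offset")
        pred = np.asarray(self.learner.predict(df[self.cols].to_numpy(dtype=float)), dtype=float)
        return np.clip(pred, 0.0, 1.0)


def _irls_logit(X: np.ndarray, y: np.ndarray, w: np.ndarray, offset: np.ndarray,
                tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Newton-Raphson with step halving for the weighted quasi-binomial score."""
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(np.average(y, weights=w), 1e-10, 1 - 1e-10)
    if not offset.any():
        beta[0] = logit(ybar)

    def loglik(b):
        mu = expit(X @ b + offset)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))

    ll = loglik(beta)
    scale = max(1.0, float(np.sum(w)))
    for _ in range(max_iter):
        mu = expit(X @ beta + offset)
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < tol * scale:
            return beta
        wt = w * np.clip(mu * (1 - mu), 1e-10, None)
        H = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, score, rcond=None)
        for _ in range(30):
            cand = beta + step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 1e3:
            break
    mu = expit(X @ beta + offset)
    score = X.T @ (w * (y - mu))
    if np.max(np.abs(score)) >= tol * scale:
        raise ConvergenceError(
            f"IRLS did not converge: max|score|={np.max(np.abs(score)):.3g}, "
            f"max|coef|={np.max(np.abs(beta)):.3g} (possible separation)"
        )
    return beta


def fit_weighted_regression(
    df: pd.DataFrame,
    y,
    spec: RegressionSpec,
    conditioning: Sequence[str],
    weights=None,
    offset=None,
):
    """Fit one nuisance regression; returns an object with ``.predict(df)``.

    ``conditioning`` is the conditioning set stated in the estimator
    definition; the spec decides which terms of it enter the model.
    Weights must be nonnegative and not all zero.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        raise PositivityError("zero effective sample for a nuisance regression")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be nonnegative and not all zero")
    off = None if offset is None else np.asarray(offset, dtype=float)

    if spec.flavor == "saturated":
        cols = spec.resolve_columns(conditioning)
        if off is not None:
            raise ValueError("saturated fits do not accept an offset")
        if not cols:
            return ConstantFit(np.average(y, weights=w))
        keys = np.column_stack([_col(df, c) for c in cols])
        coder = StratumCoder(keys)
        codes = coder.encode(keys)
        num = np.bincount(codes, weights=w * y, minlength=coder.n_codes)
        den = np.bincount(codes, weights=w, minlength=coder.n_codes)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_by_code = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return SaturatedFit(cols, coder, mean_by_code)

    if spec.flavor == "learner":
        if spec.learner is None:
            raise ValueError("flavor='learner' requires a learner object")
        cols = spec.resolve_columns(conditioning)
        from sklearn.base import clone

        try:
            est = clone(spec.learner)
        except Exception:
            import copy

            est = copy.deepcopy(spec.learner)
        X = df[cols].to_numpy(dtype=float)
        try:
            est.fit(X, y, sample_weight=w)
        except TypeError:
            est.fit(X, y)
        return LearnerFit(est, cols)

    terms = spec.resolve_terms(conditioning)
    X = _design(df, terms)
    if spec.link == "identity":
        sw = np.sqrt(w)
        rhs = y if off is None else y - off
        coef, *_ = np.linalg.lstsq(X * sw[:, None], rhs * sw, rcond=None)
        return ParametricFit(terms, coef, "identity")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("logit-link outcome must lie in [0, 1]")
    if off is None:
        off = np.zeros(n)
    pos = w > 0
    if np.ptp(y[pos]) == 0 and not off[pos].any():
        return ConstantFit(y[pos][0])
    coef = _irls_logit(X[pos], y[pos], w[pos], off[pos])
    return ParametricFit(terms, coef, "logit")


# ----------------------------------------------------------------------
# fluctuation


@dataclass
class FluctuationResult:
    epsilon: float
    converged: bool
    residual: float


def solve_fluctuation(y, offset, weights=None, link: str = "logit",
                      eps_max: float = EPS_MAX, tol: float = 1e-12) -> FluctuationResult:
    """Solve ``sum_i w_i (y_i - g^{-1}(offset_i + eps)) = 0`` for ``eps``.

    Equivalently the intercept of a weighted offset regression.  For the
    logit link the score is strictly decreasing, so a bracketed root search
    is exact; when all outcome mass sits at a bound the root diverges and
    ``eps`` is clamped at ``±eps_max`` with a warning.
    """
    y = np.asarray(y, dtype=float)
    off = np.asarray(offset, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("fluctuation weights must be positive")
    if link == "identity":
        eps = float(np.sum(w * (y - off)) / np.sum(w))
        return FluctuationResult(eps, True, 0.0)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("logit-link fluctuation requires y in [0, 1]")

    def score(eps: float) -> float:
        return float(np.sum(w * (y - expit(off + eps))))

    s_lo, s_hi = score(-eps_max), score(eps_max)
    if s_lo == 0.0:
        return FluctuationResult(-eps_max, True, 0.0)
    if s_hi == 0.0:
        return FluctuationResult(eps_max, True, 0.0)
    if s_lo * s_hi > 0:
        eps = eps_max if abs(s_hi) < abs(s_lo) else -eps_max
        warnings.warn(
            f"fluctuation has no root in [-{eps_max}, {eps_max}]; clamped (residual {score(eps):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
        return FluctuationResult(eps, False, score(eps))
    eps = float(brentq(score, -eps_max, eps_max, xtol=tol))
    return FluctuationResult(eps, True, score(eps))


# ----------------------------------------------------------------------
# nuisance estimation for the IA / IB estimators


@dataclass
class NuisanceFit:
    """Fitted nuisances evaluated on the table they were fit to.

    Probability arrays are filled with 1.0 on records where the quantity is
    not defined (those records are gated out by the matching indicator in
    every downstream expression).
    """

    mode: str
    a: float
    pi_a: np.ndarray
    pi_ra: np.ndarray
    pi_rl: list[np.ndarray]  # IA: single array; IB: one per k
    t_init: np.ndarray       # initial outcome prediction at A=a (NaN where undefined)
    fits: dict
    truncation: float
    diagnostics: dict
    t_star: list | None = None  # post-targeting sequential predictions

    @property
    def pi_rl_prod(self) -> np.ndarray:
        out = np.ones_like(self.pi_rl[0])
        for arr in self.pi_rl:
            out = out * arr
        return out


def _truncate(p: np.ndarray, trunc: float, diagnostics: dict, name: str) -> np.ndarray:
    """Truncate an estimated probability away from 0.

    Inverse weights are unstable only near zero, so truncation is one-sided:
    a prediction of exactly 1 (e.g. a degenerate missingness model on fully
    observed data) is left untouched.
    """
    diagnostics.setdefault("pred_range", {})[name] = (float(np.nanmin(p)), float(np.nanmax(p)))
    if trunc <= 0:
        return p
    clipped = np.clip(p, trunc, None)
    diagnostics.setdefault("truncated", {})[name] = int(np.sum(clipped != p))
    return clipped


def estimate_nuisances_ia(table, specs: NuisanceSpecs, a: float) -> NuisanceFit:
    """Fit the IA-mode nuisances (single block indicator for L_M).

    pi_RL is fit on all records from R_L ~ L_O; pi_RA among R_L = 1 from
    R_A ~ L; pi_A among R = 1 from 1{A = a} ~ L; the initial outcome
    regression among R = 1 from Y ~ (A, L), predicted at A = a.
    """
    roles = table.roles
    df = table.frame()
    n = table.n
    rl = table.r_l_joint
    r = table.complete_mask
    diag: dict = {}
    trunc = specs.truncation
    l_cols = list(roles.l_cols)
    exp_col = roles.exposure_col

    fit_rl = fit_weighted_regression(df, rl, specs.r_l, list(roles.l_o_cols))
    pi_rl = _truncate(fit_rl.predict(df), trunc, diag, "pi_rl")

    m = rl == 1
    fit_ra = fit_weighted_regression(df[m], table.r_a[m], specs.r_a, l_cols)
    pi_ra = np.ones(n)
    pi_ra[m] = _truncate(fit_ra.predict(df[m]), trunc, diag, "pi_ra")

    if not (r & (table.a == a)).any():
        raise PositivityError(f"no complete records with A = {a}")
    fit_a = fit_weighted_regression(df[r], (table.a[r] == a).astype(float), specs.exposure, l_cols)
    pi_a = np.ones(n)
    pi_a[r] = _truncate(fit_a.predict(df[r]), trunc, diag, "pi_a")

    fit_t1 = fit_weighted_regression(df[r], table.y[r], specs.outcome, [exp_col] + l_cols)
    df_a = df.copy()
    df_a[exp_col] = float(a)
    t_init = np.full(n, np.nan)
    t_init[m] = fit_t1.predict(df_a[m])

    return NuisanceFit(
        mode="ia", a=float(a), pi_a=pi_a, pi_ra=pi_ra, pi_rl=[pi_rl], t_init=t_init,
        fits={"pi_rl": fit_rl, "pi_ra": fit_ra, "pi_a": fit_a, "t1": fit_t1},
        truncation=trunc, diagnostics=diag,
    )


def estimate_nuisances_ib(table, specs: NuisanceSpecs, a: float, ordering: Sequence[str]) -> NuisanceFit:
    """Fit the IB-mode nuisances on a monotone-coarsened table.

    For k = 1..q, pi_RLk is fit among records with the first k-1 covariates
    observed from R_Lk ~ (Lbar_M,k-1, L_O); pi_RA among all-L_M-observed;
    pi_A and the initial outcome regression among fully complete records.
    """
    roles = table.roles
    order = list(ordering)
    if not table.is_monotone(order):
        raise ValueError("IB nuisances require a monotone-coarsened table")
    df = table.frame()
    n = table.n
    diag: dict = {}
    trunc = specs.truncation
    exp_col = roles.exposure_col
    idx = [roles.l_m_cols.index(c) for c in order]
    q = len(order)

    pi_rl_list: list[np.ndarray] = []
    fits: dict = {}
    prefix_obs = np.ones(n, dtype=bool)
    for k in range(q):
        cond = list(roles.l_o_cols) + order[:k]
        r_k = table.r_l[:, idx[k]]
        if not prefix_obs.any():
            raise PositivityError(f"empty conditioning stratum at k={k + 1} in the IB sequence")
        fit_k = fit_weighted_regression(df[prefix_obs], r_k[prefix_obs], specs.r_l, cond)
        p_k = np.ones(n)
        p_k[prefix_obs] = _truncate(fit_k.predict(df[prefix_obs]), trunc, diag, f"pi_rl_{k + 1}")
        pi_rl_list.append(p_k)
        fits[f"pi_rl_{k + 1}"] = fit_k
        prefix_obs = prefix_obs & (r_k == 1)

    l_cols = list(roles.l_o_cols) + order
    m = prefix_obs  # all L_M observed
    fit_ra = fit_weighted_regression(df[m], table.r_a[m], specs.r_a, l_cols)
    pi_ra = np.ones(n)
    pi_ra[m] = _truncate(fit_ra.predict(df[m]), trunc, diag, "pi_ra")
    fits["pi_ra"] = fit_ra

    r = m & (table.r_a == 1)
    if not (r & (table.a == a)).any():
        raise PositivityError(f"no complete records with A = {a}")
    fit_a = fit_weighted_regression(df[r], (table.a[r] == a).astype(float), specs.exposure, l_cols)
    pi_a = np.ones(n)
    pi_a[r] = _truncate(fit_a.predict(df[r]), trunc, diag, "pi_a")
    fits["pi_a"] = fit_a

    fit_t = fit_weighted_regression(df[r], table.y[r], specs.outcome, [exp_col] + l_cols)
    df_a = df.copy()
    df_a[exp_col] = float(a)
    t_init = np.full(n, np.nan)
    t_init[m] = fit_t.predict(df_a[m])
    fits["t_q"] = fit_t

    return NuisanceFit(
        mode="ib", a=float(a), pi_a=pi_a, pi_ra=pi_ra, pi_rl=pi_rl_list, t_init=t_init,
        fits=fits, truncation=trunc, diagnostics=diag,
    )
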