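"""Exact identification oracle on small discrete laws.

This module serves as the ground truth for the estimator suite.  It can

* enumerate the full-data law implied by an all-Bernoulli structural
  equation system (:class:`ScenarioDGP`) by exact marginalization over the
  latent common causes,
* compute the true counterfactual mean ``E(Y^a)`` by intervening on the
  exposure equation, and
* evaluate the three identifying functionals — the MAR functional, the IA
  functional (single block indicator for L_M) and the IB functional
  (per-covariate indicators under block-conditional MAR) — by exact
  summation over the law.

On any law satisfying the matching assumption set, the plug-in functional
equals the counterfactual mean; the test suite asserts this to 1e-10.
The module is a test oracle, not a production estimator: laws are capped at
10^6 states and all variables must be discrete.
"""

from __future__ import annotations

import itertools
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .nuisance import PositivityError

__all__ = [
    "DiscreteLaw",
    "ScenarioDGP",
    "default_dgp",
    "enumerate_law",
    "law_from_equations",
    "empirical_law",
    "true_potential_mean",
    "psi_mar_plugin",
    "psi_ia_plugin",
    "psi_ib_plugin",
    "law_nuisances_ia",
    "law_nuisances_ib",
]

MAX_STATES = 10**6

# Parent sets admissible for the missingness equations of each scenario.
# I: a single joint indicator driven by fully observed quantities (the
#    "-Y" variant lets it also depend on the outcome, still MAR);
# II: R_A may depend on the exposure, the partially observed covariates and
#    a latent cause shared with A; R_L on L_O and another shared latent;
# III: as II but with separate indicators, R_L2 additionally on L_M1.
_ALLOWED_R_PARENTS = {
    "I": {"r": {"l_o"}},
    "I-Y": {"r": {"l_o", "y"}},
    "II": {"r_a": {"a", "l_m1", "l_m2", "u4"}, "r_l": {"l_o", "u5"}},
    "III": {
        "r_a": {"a", "l_m1", "l_m2", "u4"},
        "r_l1": {"l_o", "u5"},
        "r_l2": {"l_m1", "l_o", "u5"},
    },
}


@dataclass
class ScenarioDGP:
    """All-Bernoulli structural equation system for one missingness scenario.

    ``equations`` maps each variable name, in topological order, to its
    logistic coefficients: ``{"const": b0, parent: b_parent, ...}``; the
    variable is Bernoulli(expit(b0 + sum b_p * parent)).  Latent common
    causes are the variables whose name starts with ``"u"``; they are never
    exported to observed tables.  Scenario ``I`` draws a single joint
    indicator ``r``; ``II`` draws ``r_a`` and a block ``r_l``; ``III`` draws
    ``r_a``, ``r_l1``, ``r_l2``.
    """

    scenario: str
    equations: "OrderedDict[str, dict[str, float]]"
    q: int = 2

    def __post_init__(self) -> None:
        if self.scenario not in _ALLOWED_R_PARENTS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        allowed = _ALLOWED_R_PARENTS[self.scenario]
        for var, parents in allowed.items():
            if var not in self.equations:
                raise ValueError(f"scenario {self.scenario} requires an equation for {var!r}")
            extra = set(self.equations[var]) - parents - {"const"}
            if extra:
                raise ValueError(
                    f"scenario {self.scenario}: {var!r} may not depend on {sorted(extra)}"
                )
        order = list(self.equations)
        for var, coefs in self.equations.items():
            for parent in coefs:
                if parent != "const" and order.index(parent) >= order.index(var):
                    raise ValueError(f"equation for {var!r} references non-ancestor {parent!r}")

    # -- canonical observed columns -----------------------------------
    @property
    def latent(self) -> list[str]:
        return [v for v in self.equations if v.startswith("u")]

    @property
    def r_cols(self) -> list[str]:
        return ["r_a", "r_l1", "r_l2"]

    def _prob(self, var: str, state: Mapping[str, np.ndarray]) -> np.ndarray:
        coefs = self.equations[var]
        lp = coefs.get("const", 0.0)
        for parent, b in coefs.items():
            if parent != "const":
                lp = lp + b * state[parent]
        return expit(lp)

    def _expand_indicators(self, df: pd.DataFrame) -> pd.DataFrame:
        """Add canonical r_a / r_l1 / r_l2 columns for any scenario."""
        out = df.copy()
        if self.scenario in ("I", "I-Y"):
            out["r_a"] = out["r"]
            out["r_l1"] = out["r"]
            out["r_l2"] = out["r"]
        elif self.scenario == "II":
            out["r_l1"] = out["r_l"]
            out["r_l2"] = out["r_l"]
        return out

    # -- exact enumeration --------------------------------------------
    def enumerate_states(
        self, intervene: Mapping[str, float] | None = None, marginalize_latent: bool = True
    ) -> pd.DataFrame:
        """Joint pmf over all variables, optionally intervening ``var := value``.

        Intervened variables are set deterministically (their structural
        equation is cut); latent causes are summed out when requested.
        """
        intervene = dict(intervene or {})
        df = pd.DataFrame({"prob": [1.0]})
        for var in self.equations:
            if len(df) * 2 > MAX_STATES:
                raise ValueError(f"law exceeds {MAX_STATES} states")
            if var in intervene:
                df[var] = float(intervene[var])
                continue
            p = self._prob(var, df)
            hi = df.copy()
            hi[var] = 1.0
            hi["prob"] = df["prob"] * p
            lo = df.copy()
            lo[var] = 0.0
            lo["prob"] = df["prob"] * (1.0 - p)
            df = pd.concat([hi, lo], ignore_index=True)
        df = self._expand_indicators(df)
        if marginalize_latent:
            keep = [c for c in df.columns if c not in self.latent and c != "prob"]
            df = df.groupby(keep, as_index=False)["prob"].sum()
        return df

    # -- sampling ------------------------------------------------------
    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``n`` records, including counterfactual outcomes y0 / y1.

        The outcome uses a shared exogenous uniform so that consistency
        holds exactly: ``y == y1`` where ``a == 1`` and ``y == y0`` where
        ``a == 0``.  Missingness indicators respond to the factual exposure.
        """
        state: dict[str, np.ndarray] = {}
        for var in self.equations:
            u = rng.random(n)
            if var == "y":
                base = dict(state)
                y_pot = {}
                for a_val in (0.0, 1.0):
                    base["a"] = np.full(n, a_val)
                    y_pot[a_val] = (u < self._prob("y", base)).astype(float)
                state["y0"] = y_pot[0.0]
                state["y1"] = y_pot[1.0]
                state["y"] = np.where(state["a"] == 1.0, y_pot[1.0], y_pot[0.0])
            else:
                state[var] = (u < self._prob(var, state)).astype(float)
        return self._expand_indicators(pd.DataFrame(state))

    def missingness_fraction(self) -> float:
        """Exact P(exposure or any L_M coordinate missing)."""
        law = self.enumerate_states()
        obs = (law[["r_a", "r_l1", "r_l2"]].to_numpy() == 1).all(axis=1)
        return float(law.loc[~obs, "prob"].sum())


def default_dgp(scenario: str, overrides: Mapping[str, Mapping[str, float]] | None = None) -> ScenarioDGP:
    """Default structural equations for Scenarios I-III.

    The full-data law is shared across scenarios: binary confounders
    ``l_o, l_m1, l_m2`` with latent common causes ``u1`` ({L_O, L_M}),
    ``u2`` ({L_M, Y}) and ``u3`` ({L_O, Y}); a binary exposure with latent
    causes ``u4, u5`` shared with the missingness process in Scenarios
    II-III; and a binary outcome.  The missingness intercepts are calibrated
    so that 20-30% of records have the exposure or some L_M coordinate
    missing.  ``overrides`` merges replacement coefficients per equation,
    so an externally specified parameterization can be dropped in.
    """
    eqs: OrderedDict[str, dict[str, float]] = OrderedDict(
        [
            ("u1", {"const": 0.0}),
            ("u2", {"const": 0.0}),
            ("u3", {"const": 0.0}),
            ("u4", {"const": 0.0}),
            ("u5", {"const": 0.0}),
            ("l_o", {"const": -0.2, "u1": 0.8, "u3": 0.8}),
            ("l_m1", {"const": -0.3, "u1": 0.7, "u2": 0.7}),
            ("l_m2", {"const": -0.1, "u1": 0.6, "u2": 0.6}),
            ("a", {"const": -0.6, "l_o": 0.6, "l_m1": 0.9, "l_m2": 0.7, "u4": 0.5, "u5": 0.5}),
            ("y", {"const": -3.8, "a": 0.7, "l_o": 0.6, "l_m1": 1.0, "l_m2": 0.8, "u2": 0.7, "u3": 0.6}),
        ]
    )
    if scenario == "I":
        eqs["r"] = {"const": 0.7, "l_o": 0.8}
    elif scenario == "I-Y":
        eqs["r"] = {"const": 0.5, "l_o": 0.8, "y": 0.6}
    elif scenario == "II":
        eqs["r_a"] = {"const": -0.1, "a": 1.0, "l_m1": 0.9, "l_m2": 0.6, "u4": 1.0}
        eqs["r_l"] = {"const": 2.1, "l_o": -0.7, "u5": 0.7}
    elif scenario == "III":
        eqs["r_a"] = {"const": -0.1, "a": 1.0, "l_m1": 0.9, "l_m2": 0.6, "u4": 1.0}
        eqs["r_l1"] = {"const": 2.6, "l_o": -0.7, "u5": 0.7}
        eqs["r_l2"] = {"const": 1.7, "l_m1": 1.2, "l_o": -0.4, "u5": 0.6}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    for var, coefs in (overrides or {}).items():
        eqs.setdefault(var, {})
        eqs[var] = {**eqs[var], **dict(coefs)}
    return ScenarioDGP(scenario=scenario, equations=eqs)


# ----------------------------------------------------------------------
# discrete laws


@dataclass
class DiscreteLaw:
    """Finite joint pmf over full-data states plus missingness indicators."""

    df: pd.DataFrame
    l_o_cols: tuple[str, ...] = ("l_o",)
    l_m_cols: tuple[str, ...] = ("l_m1", "l_m2")
    a_col: str = "a"
    y_col: str = "y"
    r_a_col: str = "r_a"
    r_l_cols: tuple[str, ...] = ("r_l1", "r_l2")
    prob_col: str = "prob"

    def __post_init__(self) -> None:
        self.l_o_cols = tuple(self.l_o_cols)
        self.l_m_cols = tuple(self.l_m_cols)
        self.r_l_cols = tuple(self.r_l_cols)
        p = self.df[self.prob_col].to_numpy()
        if (p < -1e-15).any():
            raise ValueError("negative probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {p.sum()!r}, not 1")
        if len(self.df) > MAX_STATES:
            raise ValueError(f"law exceeds {MAX_STATES} states")

    @property
    def l_cols(self) -> list[str]:
        return list(self.l_o_cols) + list(self.l_m_cols)

    def perturb(self, state_index: int, t: float) -> "DiscreteLaw":
        """Mixture law (1-t) P + t delta_o used for pathwise derivatives."""
        df = self.df.copy()
        p = df[self.prob_col].to_numpy() * (1.0 - t)
        p[state_index] += t
        df[self.prob_col] = p
        return DiscreteLaw(
            df, self.l_o_cols, self.l_m_cols, self.a_col, self.y_col,
            self.r_a_col, self.r_l_cols, self.prob_col,
        )


def law_from_equations(
    equations: Mapping[str, Mapping[str, float]],
    l_o_cols: Sequence[str] = ("l_o",),
    l_m_cols: Sequence[str] = ("l_m1",),
    r_l_cols: Sequence[str] = ("r_l1",),
) -> DiscreteLaw:
    """Enumerate an arbitrary all-Bernoulli equation system into a law.

    Unlike :class:`ScenarioDGP` this imposes no DAG-shape restrictions, so
    it can build witness laws that deliberately violate an assumption set
    (e.g. an exposure indicator that depends on the outcome).  Variables
    whose name starts with ``u`` are marginalized out.
    """
    df = pd.DataFrame({"prob": [1.0]})
    order = list(equations)
    for var, coefs in equations.items():
        if len(df) * 2 > MAX_STATES:
            raise ValueError(f"law exceeds {MAX_STATES} states")
        lp = coefs.get("const", 0.0)
        for parent, b in coefs.items():
            if parent == "const":
                continue
            if parent not in df.columns:
                raise ValueError(f"{var!r} references {parent!r} before its equation")
            lp = lp + b * df[parent]
        p = expit(lp)
        hi = df.copy()
        hi[var] = 1.0
        hi["prob"] = df["prob"] * p
        lo = df.copy()
        lo[var] = 0.0
        lo["prob"] = df["prob"] * (1.0 - p)
        df = pd.concat([hi, lo], ignore_index=True)
    keep = [c for c in df.columns if not c.startswith("u") and c != "prob"]
    df = df.groupby(keep, as_index=False)["prob"].sum()
    return DiscreteLaw(df, tuple(l_o_cols), tuple(l_m_cols), r_l_cols=tuple(r_l_cols))


def enumerate_law(dgp: ScenarioDGP) -> DiscreteLaw:
    """Exact observed+full-data law of a DGP with latent causes summed out."""
    df = dgp.enumerate_states(marginalize_latent=True)
    drop = [c for c in ("r", "r_l") if c in df.columns]
    return DiscreteLaw(df.drop(columns=drop))


def empirical_law(table) -> DiscreteLaw:
    """Empirical distribution of an observed table as a DiscreteLaw.

    Cells that are unobserved are filled with a 0.0 placeholder; only
    observed-data functionals (which never condition on masked cells) are
    meaningful on the result.
    """
    roles = table.roles
    df = pd.DataFrame({"y": table.y, "a": np.nan_to_num(table.a, nan=0.0)})
    for c in roles.l_o_cols:
        df[c] = table.l_o[c].to_numpy()
    for k, c in enumerate(roles.l_m_cols):
        df[c] = np.nan_to_num(table.l_m[c].to_numpy(), nan=0.0)
    df["r_a"] = table.r_a
    r_l_cols = []
    for k, c in enumerate(roles.l_m_cols):
        name = f"r_{c}"
        df[name] = table.r_l[:, k]
        r_l_cols.append(name)
    df["prob"] = 1.0 / table.n
    df = df.groupby(list(df.columns[:-1]), as_index=False)["prob"].sum()
    return DiscreteLaw(
        df,
        l_o_cols=roles.l_o_cols,
        l_m_cols=roles.l_m_cols,
        r_l_cols=tuple(r_l_cols),
    )


def true_potential_mean(dgp: ScenarioDGP, a: float, n_mc: int | None = None, seed: int | None = None):
    """True ``E(Y^a)`` under the DGP.

    Exact by enumeration when ``n_mc`` is None; otherwise Monte-Carlo,
    returning ``(mean, mc_standard_error)``.
    """
    if a not in (0.0, 1.0, 0, 1):
        raise ValueError(f"exposure level {a!r} outside the binary support")
    if n_mc is None:
        law = dgp.enumerate_states(intervene={"a": float(a)})
        return float((law["prob"] * law["y"]).sum())
    rng = np.random.default_rng(seed)
    draws = dgp.draw(int(n_mc), rng)
    y_a = draws["y1"] if a in (1, 1.0) else draws["y0"]
    mean = float(y_a.mean())
    return mean, float(y_a.std(ddof=1) / np.sqrt(len(y_a)))


# ----------------------------------------------------------------------
# plug-in functionals (exact summation)


def _group_sum(keys: np.ndarray, weights: np.ndarray) -> dict:
    out: dict = {}
    for key, w in zip(map(tuple, keys), weights):
        out[key] = out.get(key, 0.0) + w
    return out


def _law_arrays(law: DiscreteLaw):
    d = law.df
    p = d[law.prob_col].to_numpy(dtype=float)
    y = d[law.y_col].to_numpy(dtype=float)
    a = d[law.a_col].to_numpy(dtype=float)
    ra = d[law.r_a_col].to_numpy() == 1
    rl = d[list(law.r_l_cols)].to_numpy() == 1
    lo = d[list(law.l_o_cols)].to_numpy()
    lm = d[list(law.l_m_cols)].to_numpy()
    return d, p, y, a, ra, rl, lo, lm


def psi_mar_plugin(law: DiscreteLaw, a: float) -> float:
    """MAR identifying functional, by exact summation.

    ``Psi = E[ beta(L)/gamma(L) * R / P(R=1 | L_O, Y) ]`` with
    ``beta(L) = sum_y y p(L_M, a | L_O, y, R=1) p(y | L_O)`` and ``gamma``
    the same sum without the leading ``y``; ``R`` is the joint indicator.
    """
    d, p, y, aa, ra, rl, lo, lm = _law_arrays(law)
    r = ra & rl.all(axis=1)
    l_keys = np.column_stack([lo, lm])
    lo_y = np.column_stack([lo, y[:, None]])

    mass_lo = _group_sum(lo, p)
    mass_lo_y = _group_sum(lo_y, p)
    mass_r_lo_y = _group_sum(lo_y[r], p[r])
    # p(l_m, A=a, l_o, y, R=1)
    sel = r & (aa == float(a))
    mass_joint = _group_sum(np.column_stack([l_keys, y[:, None]])[sel], p[sel])

    y_support = sorted(set(y.tolist()))

    def beta_gamma(l_key: tuple, lo_key: tuple) -> tuple[float, float]:
        b = g = 0.0
        for yv in y_support:
            p_y_lo = mass_lo_y.get(lo_key + (yv,), 0.0) / mass_lo[lo_key]
            denom = mass_r_lo_y.get(lo_key + (yv,), 0.0)
            if p_y_lo > 0 and denom <= 0:
                raise PositivityError(f"P(R=1 | L_O={lo_key}, Y={yv}) = 0")
            f = (mass_joint.get(l_key + (yv,), 0.0) / denom if denom > 0 else 0.0) * p_y_lo
            b += yv * f
            g += f
        return b, g

    psi = 0.0
    n_lo = lo.shape[1]
    for i in np.flatnonzero(r & (p > 0)):
        l_key = tuple(l_keys[i])
        lo_key = l_key[:n_lo]
        y_key = lo_key + (y[i],)
        p_r1 = mass_r_lo_y[y_key] / mass_lo_y[y_key]
        b, g = beta_gamma(l_key, lo_key)
        if g <= 0:
            raise PositivityError(f"gamma(L)=0 at L={l_key}: no mass at A={a} among R=1")
        psi += p[i] / p_r1 * (b / g)
    return float(psi)


def psi_ia_plugin(law: DiscreteLaw, a: float) -> float:
    """IA identifying functional:
    ``sum_l E(Y | A=a, R_A=1, R_L=1, L=l) p(l_M | l_O, R_L=1) p(l_O)``.
    """
    d, p, y, aa, ra, rl, lo, lm = _law_arrays(law)
    rl_all = rl.all(axis=1)
    l_keys = np.column_stack([lo, lm])
    n_lo = lo.shape[1]

    mass_lo = _group_sum(lo, p)
    mass_rl_lo = _group_sum(lo[rl_all], p[rl_all])
    mass_rl_l = _group_sum(l_keys[rl_all], p[rl_all])
    sel = rl_all & ra & (aa == float(a))
    num_t1 = _group_sum(l_keys[sel], p[sel] * y[sel])
    den_t1 = _group_sum(l_keys[sel], p[sel])

    psi = 0.0
    for l_key, joint in mass_rl_l.items():
        lo_key = l_key[:n_lo]
        weight = mass_lo[lo_key] * joint / mass_rl_lo[lo_key]
        if weight <= 0:
            continue
        den = den_t1.get(l_key, 0.0)
        if den <= 0:
            raise PositivityError(f"no mass at (A={a}, R=1) in stratum L={l_key}")
        psi += weight * num_t1.get(l_key, 0.0) / den
    return float(psi)


def psi_ib_plugin(law: DiscreteLaw, a: float, ordering: Sequence[str] | None = None) -> float:
    """IB identifying functional with sequential covariate conditionals:
    ``sum_l E(Y | A=a, R_A=1, Rbar_Lq=1, L=l)
    prod_k p(l_Mk | l_O, lbar_M,k-1, Rbar_Lk=1) p(l_O)``.
    """
    order = list(ordering) if ordering is not None else list(law.l_m_cols)
    if sorted(order) != sorted(law.l_m_cols):
        raise ValueError(f"ordering must be a permutation of {law.l_m_cols}")
    d, p, y, aa, ra, rl, lo, lm = _law_arrays(law)
    q = len(order)
    # reorder l_m / r_l columns to the requested ordering
    perm = [list(law.l_m_cols).index(c) for c in order]
    lm_o = lm[:, perm]
    rl_o = rl[:, perm]
    n_lo = lo.shape[1]

    mass_lo = _group_sum(lo, p)
    num_k, den_k = [], []
    for k in range(q):
        mask = rl_o[:, : k + 1].all(axis=1)
        keys_full = np.column_stack([lo, lm_o[:, : k + 1]])
        keys_prefix = np.column_stack([lo, lm_o[:, :k]])
        num_k.append(_group_sum(keys_full[mask], p[mask]))
        den_k.append(_group_sum(keys_prefix[mask], p[mask]))
    rl_all = rl_o.all(axis=1)
    sel = rl_all & ra & (aa == float(a))
    keys_l = np.column_stack([lo, lm_o])
    num_t = _group_sum(keys_l[sel], p[sel] * y[sel])
    den_t = _group_sum(keys_l[sel], p[sel])

    lm_support = [sorted(set(lm_o[:, k].tolist())) for k in range(q)]
    psi = 0.0
    for lo_key in mass_lo:
        p_lo = mass_lo[lo_key]
        if p_lo <= 0:
            continue
        for lm_vals in itertools.product(*lm_support):
            w = p_lo
            for k in range(q):
                prefix = lo_key + lm_vals[:k]
                full = lo_key + lm_vals[: k + 1]
                den = den_k[k].get(prefix, 0.0)
                num = num_k[k].get(full, 0.0)
                if den <= 0:
                    raise PositivityError(
                        f"no mass with first {k + 1} indicators = 1 in stratum {prefix}"
                    )
                w *= num / den
                if w == 0.0:
                    break
            if w <= 0:
                continue
            l_key = lo_key + lm_vals
            den = den_t.get(l_key, 0.0)
            if den <= 0:
                raise PositivityError(f"no mass at (A={a}, R_A=1, all observed) in stratum {l_key}")
            psi += w * num_t.get(l_key, 0.0) / den
    return float(psi)


# ----------------------------------------------------------------------
# exact nuisance values at a law (for influence-function checks)


def law_nuisances_ia(law: DiscreteLaw, a: float) -> pd.DataFrame:
    """Per-state exact values of pi_A, pi_RA, pi_RL, T1, T0 under the law.

    Values that condition on events of zero mass are NaN; they only occur
    in states whose indicators gate them out of the influence function.
    """
    d, p, y, aa, ra, rl, lo, lm = _law_arrays(law)
    rl_all = rl.all(axis=1)
    r = rl_all & ra
    l_keys = np.column_stack([lo, lm])
    n_lo = lo.shape[1]

    def ratio(num: dict, den: dict, keys: np.ndarray) -> np.ndarray:
        out = np.full(len(keys), np.nan)
        for i, k in enumerate(map(tuple, keys)):
            dv = den.get(k, 0.0)
            if dv > 0:
                out[i] = num.get(k, 0.0) / dv
        return out

    sel = r & (aa == float(a))
    pi_a = ratio(_group_sum(l_keys[sel], p[sel]), _group_sum(l_keys[r], p[r]), l_keys)
    pi_ra = ratio(_group_sum(l_keys[r], p[r]), _group_sum(l_keys[rl_all], p[rl_all]), l_keys)
    pi_rl = ratio(_group_sum(lo[rl_all], p[rl_all]), _group_sum(lo, p), lo)
    t1 = ratio(_group_sum(l_keys[sel], (p * y)[sel]), _group_sum(l_keys[sel], p[sel]), l_keys)
    # T0(l_o) = E(T1(L) | L_O, R_L = 1)
    t1_mass = _group_sum(l_keys[rl_all], p[rl_all])
    num0: dict = {}
    den0: dict = {}
    for l_key, mass in t1_mass.items():
        lo_key = l_key[:n_lo]
        # T1 value for this stratum (shared by all states in the stratum)
        t1_val = None
        for i, k in enumerate(map(tuple, l_keys)):
            if k == l_key and not np.isnan(t1[i]):
                t1_val = t1[i]
                break
        if t1_val is None:
            raise PositivityError(f"T1 undefined on a stratum with R_L mass: {l_key}")
        num0[lo_key] = num0.get(lo_key, 0.0) + mass * t1_val
        den0[lo_key] = den0.get(lo_key, 0.0) + mass
    t0 = ratio(num0, den0, lo)
    return pd.DataFrame({"pi_a": pi_a, "pi_ra": pi_ra, "pi_rl": pi_rl, "t1": t1, "t0": t0})


def law_nuisances_ib(law: DiscreteLaw, a: float, ordering: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-state exact pi_A, pi_RA, pi_RLk and sequential regressions T~_k.

    Columns: ``pi_a``, ``pi_ra``, ``pi_rl_1..q``, ``t_0..t_q`` (t_q is the
    outcome regression at A=a; t_0 depends on L_O only).
    """
    order = list(ordering) if ordering is not None else list(law.l_m_cols)
    d, p, y, aa, ra, rl, lo, lm = _law_arrays(law)
    perm = [list(law.l_m_cols).index(c) for c in order]
    lm_o = lm[:, perm]
    rl_o = rl[:, perm]
    q = len(order)
    rl_all = rl_o.all(axis=1)
    r = rl_all & ra
    l_keys = np.column_stack([lo, lm_o])

    def ratio(num: dict, den: dict, keys: np.ndarray) -> np.ndarray:
        out = np.full(len(keys), np.nan)
        for i, k in enumerate(map(tuple, keys)):
            dv = den.get(k, 0.0)
            if dv > 0:
                out[i] = num.get(k, 0.0) / dv
        return out

    sel = r & (aa == float(a))
    out = pd.DataFrame(index=d.index)
    out["pi_a"] = ratio(_group_sum(l_keys[sel], p[sel]), _group_sum(l_keys[r], p[r]), l_keys)
    out["pi_ra"] = ratio(_group_sum(l_keys[r], p[r]), _group_sum(l_keys[rl_all], p[rl_all]), l_keys)
    for k in range(q):
        mask = rl_o[:, :k].all(axis=1) if k else np.ones(len(p), dtype=bool)
        mask_k = mask & (rl_o[:, k])
        keys_prefix = np.column_stack([lo, lm_o[:, :k]])
        out[f"pi_rl_{k + 1}"] = ratio(
            _group_sum(keys_prefix[mask_k], p[mask_k]),
            _group_sum(keys_prefix[mask], p[mask]),
            keys_prefix,
        )
    # sequential regressions, backwards
    t = ratio(_group_sum(l_keys[sel], (p * y)[sel]), _group_sum(l_keys[sel], p[sel]), l_keys)
    out[f"t_{q}"] = t
    for k in range(q, 0, -1):
        mask = rl_o[:, :k].all(axis=1)
        keys_prefix = np.column_stack([lo, lm_o[:, : k - 1]])
        num: dict = {}
        den: dict = {}
        for i in np.flatnonzero(mask & (p > 0)):
            key = tuple(keys_prefix[i])
            if np.isnan(t[i]):
                raise PositivityError(f"sequential regression input undefined at state {i}")
            num[key] = num.get(key, 0.0) + p[i] * t[i]
            den[key] = den.get(key, 0.0) + p[i]
        t = ratio(num, den, keys_prefix)
        out[f"t_{k - 1}"] = t
    return out
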