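"""Synthetic-data generation and the Monte-Carlo study harness.

``simulate_scenario`` draws an observed table (plus per-record
counterfactual outcomes for truth tracking) from a :class:`ScenarioDGP`:

* Scenario I — the exposure and all partially observed confounders share a
  single observation indicator driven by the fully observed covariate (an
  MAR mechanism; the ``I-Y`` variant lets it also depend on the outcome);
* Scenario II — separate indicators for the exposure and the L_M block,
  with the exposure indicator depending on the exposure itself and on L_M,
  and latent causes shared between the exposure and both indicators (the
  IA assumption set);
* Scenario III — per-covariate indicators, with the second covariate's
  indicator depending on the first covariate (the IB assumption set).

``run_study`` applies an estimator roster to replicated draws under one of
three specification regimes — all nuisance models correct, outcome model
misspecified, or exposure model misspecified — and reports bias, empirical
SE and 95% CI coverage, all x100, with Monte-Carlo standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import ObservedTable, VariableRoles
from .estimators import (
    CompleteCaseTMLE,
    EstimateResult,
    ice,
    ipw,
    mi_then_tmle,
    tmle_a,
    tmle_b,
    tmle_complete,
)
from .nuisance import ConvergenceError, NuisanceSpecs, PositivityError, RegressionSpec
from .oracle import ScenarioDGP, default_dgp, true_potential_mean

__all__ = [
    "SCENARIO_ROLES",
    "StudyConfig",
    "StudyMetrics",
    "simulate_scenario",
    "default_specs",
    "misspecify",
    "run_study",
]

SCENARIO_ROLES = VariableRoles(
    outcome_col="y",
    exposure_col="a",
    l_o_cols=("l_o",),
    l_m_cols=("l_m1", "l_m2"),
)

MODES = ("all-correct", "misspec-outcome", "misspec-exposure")


def simulate_scenario(dgp: ScenarioDGP, n: int, seed: int | None = None):
    """Draw one observed dataset; returns ``(table, y0, y1)``.

    Values are masked according to the scenario's missingness indicators;
    the counterfactual outcome arrays are returned unmasked for truth
    tracking and never appear in the table.  The same seed reproduces the
    output exactly.
    """
    rng = np.random.default_rng(seed)
    draws = dgp.draw(int(n), rng)
    df = pd.DataFrame({"y": draws["y"], "a": draws["a"], "l_o": draws["l_o"]})
    df.loc[draws["r_a"] == 0, "a"] = np.nan
    for k in (1, 2):
        df[f"l_m{k}"] = draws[f"l_m{k}"].where(draws[f"r_l{k}"] == 1, np.nan)
    table = ObservedTable.from_dataframe(df, SCENARIO_ROLES)
    return table, draws["y0"].to_numpy(), draws["y1"].to_numpy()


def default_specs(flavor: str = "saturated", truncation: float = 0.01) -> NuisanceSpecs:
    """Nuisance specs for the study scenarios.

    The scenario DGPs are all-binary with latent common causes, so the
    conditional means are saturated-model-correct but not main-effects-
    logistic-correct; ``flavor='saturated'`` is therefore the "correctly
    specified" regime and ``'parametric'`` gives main-effects models.
    """
    if flavor == "saturated":
        return NuisanceSpecs.saturated(truncation=truncation)
    return NuisanceSpecs(truncation=truncation)


def misspecify(specs: NuisanceSpecs, mode: str) -> NuisanceSpecs:
    """Distort one block of nuisance models, leaving the rest untouched.

    ``misspec-outcome`` drops the partially observed confounders from the
    sequential outcome regressions; ``misspec-exposure`` drops them from
    the exposure model.  (With binary covariates, omitting real confounders
    is the available material distortion.)  ``all-correct`` is the identity.
    """
    if mode == "all-correct":
        return specs
    lm = SCENARIO_ROLES.l_m_cols
    if mode == "misspec-outcome":
        bad = RegressionSpec(flavor="parametric", exclude=lm)
        return specs.replace(outcome=bad, outcome_seq=bad)
    if mode == "misspec-exposure":
        return specs.replace(exposure=RegressionSpec(flavor="parametric", exclude=lm))
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass
class StudyConfig:
    """Design of one Monte-Carlo study."""

    scenario: str = "II"
    n: int = 2500
    replicates: int = 1000
    modes: tuple[str, ...] = ("all-correct",)
    estimators: tuple[str, ...] = ("cc", "mi", "ice", "ipw", "tmle")
    a: float = 1.0
    seed: int | None = None
    truth: float | None = None  # computed by enumeration when None
    specs: NuisanceSpecs | None = None  # base (correct) specs
    mi_m: int = 10
    mi_iterations: int = 5
    ordering: tuple[str, ...] = ("l_m1", "l_m2")
    n_jobs: int = 1
    max_fail_frac: float = 0.05
    custom: dict = field(default_factory=dict)  # extra name -> callable(table) -> EstimateResult

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown specification modes {sorted(bad)}")


@dataclass
class StudyMetrics:
    """Bias / SE / coverage (x100) per estimator and specification mode."""

    table: pd.DataFrame  # columns: estimator, mode, bias100, se100, cp100, mc-SEs, n_fail
    truth: float
    replicates: int

    def row(self, estimator: str, mode: str = "all-correct") -> pd.Series:
        m = (self.table["estimator"] == estimator) & (self.table["mode"] == mode)
        if not m.any():
            raise KeyError(f"no row for ({estimator}, {mode})")
        return self.table[m].iloc[0]


def _estimator_fn(name: str, scenario: str, config: StudyConfig) -> Callable:
    """Resolve an estimator label to a closure table -> EstimateResult.

    The A-form estimators match Scenarios I-II (block missingness in L_M);
    the B-form match Scenario III.  TMLE-A is also applied in Scenario I
    under R = R_A = R_L, which satisfies the IA conditions there.
    """
    mode_b = scenario == "III"
    order = list(config.ordering)
    a = config.a

    def make(specs):
        if name == "cc":
            return lambda t: CompleteCaseTMLE(a=a, specs=specs)._estimate(t)
        if name == "mi":
            # imputation uses its own rng; seed varies per replicate via closure arg
            def run_mi(t, seed=None):
                return mi_then_tmle(t, specs, a, m=config.mi_m, seed=seed,
                                    fcs_iterations=config.mi_iterations)

            return run_mi
        if name == "ice":
            if mode_b:
                return lambda t: ice(t, specs, a, mode="ib", ordering=order)
            return lambda t: ice(t, specs, a, mode="ia")
        if name == "ipw":
            if mode_b:
                return lambda t: ipw(t, specs, a, mode="ib", ordering=order)
            return lambda t: ipw(t, specs, a, mode="ia")
        if name == "tmle":
            if mode_b:
                return lambda t: tmle_b(t, specs, a, ordering=order)
            return lambda t: tmle_a(t, specs, a)
        if name in config.custom:
            return config.custom[name]
        raise ValueError(f"unknown estimator {name!r}")

    return make


def _one_replicate(dgp, config, specs_by_mode, seed):
    rng_seed = int(seed)
    table, _, _ = simulate_scenario(dgp, config.n, seed=rng_seed)
    out = {}
    for mode, specs in specs_by_mode.items():
        for name in list(config.estimators) + list(config.custom):
            fn = _estimator_fn(name, config.scenario, config)(specs)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if name == "mi":
                        res = fn(table, seed=rng_seed + 1)
                    else:
                        res = fn(table)
                out[(name, mode)] = (res.psi, res.ci)
            except (PositivityError, ConvergenceError) as exc:
                out[(name, mode)] = ("failed", str(exc))
    return out


def run_study(config: StudyConfig, dgp: ScenarioDGP | None = None) -> StudyMetrics:
    """Run the Monte-Carlo study and aggregate the metrics.

    Per replicate: simulate, apply every estimator under every requested
    specification mode, record the estimate and its CI.  Metrics per
    (estimator, mode): bias = mean(psi_hat) - truth, SE = SD(psi_hat),
    CP = fraction of CIs containing the truth, all x100, each with a
    Monte-Carlo standard error.  Aborts if more than ``max_fail_frac`` of
    replicates fail for any estimator.
    """
    dgp = dgp if dgp is not None else default_dgp(config.scenario)
    truth = config.truth if config.truth is not None else true_potential_mean(dgp, config.a)
    base = config.specs if config.specs is not None else default_specs()
    specs_by_mode = {mode: misspecify(base, mode) for mode in config.modes}

    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.n_jobs)(
            delayed(_one_replicate)(dgp, config, specs_by_mode, s) for s in seeds
        )
    else:
        results = [_one_replicate(dgp, config, specs_by_mode, s) for s in seeds]

    rows = []
    keys = results[0].keys()
    for name, mode in keys:
        psis, covered, n_ci = [], 0, 0
        failures = 0
        for rep in results:
            psi, ci = rep[(name, mode)]
            if psi == "failed":
                failures += 1
                continue
            psis.append(psi)
            if ci is not None:
                n_ci += 1
                covered += int(ci[0] <= truth <= ci[1])
        if failures > config.max_fail_frac * config.replicates:
            raise RuntimeError(f"{failures}/{config.replicates} replicates failed for {name}/{mode}")
        psis = np.asarray(psis)
        k = len(psis)
        bias = psis.mean() - truth
        se = psis.std(ddof=1) if k > 1 else np.nan
        cp = covered / n_ci if n_ci else np.nan
        rows.append(
            {
                "estimator": name,
                "mode": mode,
                "bias100": 100 * bias,
                "se100": 100 * se,
                "cp100": 100 * cp,
                "mcse_bias100": 100 * se / np.sqrt(k),
                "mcse_se100": 100 * se / np.sqrt(2 * (k - 1)) if k > 1 else np.nan,
                "mcse_cp100": 100 * np.sqrt(max(cp * (1 - cp), 1e-12) / n_ci) if n_ci else np.nan,
                "n_fail": failures,
                "n_ok": k,
            }
        )
    return StudyMetrics(pd.DataFrame(rows), truth=float(truth), replicates=config.replicates)
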