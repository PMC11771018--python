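"""Synthetic longitudinal cohorts and the metric-validation experiments.

The generator draws from a landmark-form model: three fixed covariates
(two standard normal, one Bernoulli(1/2)) and one longitudinal covariate
with linear drift, updated at k equally spaced landmarks; the hazard is
piecewise constant between landmarks, with the linear predictor
(beta + beta_t * s_m)' (Z, X(s_m)) refreshed at each landmark. Event
times follow by inversion of the piecewise-exponential cumulative
hazard. Random right censoring is exponential with its rate calibrated,
on a large pre-run sample, so that the target fraction of subjects is cut
by the censoring process before their event or the administrative end of
follow-up at s_L + w; administrative censoring at s_L + w always applies.

The experiments reproduce the validation design for the summary metrics:
confidence-interval coverage against a Monte-Carlo oracle truth, type I
error of the model-comparison test between equivalently specified models
fitted on independent training draws, and power of the summary test
against families of multiplicity-adjusted landmark-specific tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, LandmarkGrid
from .metrics import (
    MetricCurve,
    adjust_pvalues,
    compare_landmarkwise,
    compare_models,
    metric_curve,
    summary_metric,
)
from .stacking import build_stack
from .supermodel import LandmarkSupermodel

__all__ = [
    "SimScenario",
    "simulate_cohort",
    "true_summary",
    "run_coverage_experiment",
    "run_type1_experiment",
    "run_power_experiment",
]

logger = logging.getLogger(__name__)

_CAL_SEED = 202_406  # fixed seed of the censoring-calibration pre-run
_CAL_N = 100_000


@dataclass(frozen=True)
class SimScenario:
    """One simulation scenario of the metric-validation study.

    ``n`` training/test sample size; ``k`` landmarks with longitudinal
    updates at s_m = m * lmi; ``censor_rate`` the target fraction of
    subjects cut by random censoring; ``window`` the prediction horizon w.
    Default coefficients give non-degenerate event fractions across all
    censoring settings.
    """

    n: int = 750
    k: int = 3
    lmi: float = 2.0
    censor_rate: float = 0.0
    window: float = 5.0
    beta: tuple = (0.5, -0.5, 0.3, 0.7)
    beta_t: tuple = (0.0, 0.0, 0.0, -0.05)
    h0: float = 0.05
    rho: float = 0.2
    sigma_e: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")

    @property
    def landmarks(self) -> tuple[float, ...]:
        return tuple(m * self.lmi for m in range(self.k))

    @property
    def horizon(self) -> float:
        """Administrative end of follow-up s_L + w."""
        return (self.k - 1) * self.lmi + self.window

    @property
    def grid(self) -> LandmarkGrid:
        return LandmarkGrid(self.landmarks, self.window)

    def _structure_key(self) -> tuple:
        return (self.k, self.lmi, self.censor_rate, self.window, self.beta,
                self.beta_t, self.h0, self.rho, self.sigma_e)


@dataclass
class RawCohort:
    """Vectorized cohort arrays (internal fast path)."""

    Z: np.ndarray  # (n, 3) fixed covariates
    X: np.ndarray  # (n, k) longitudinal covariate at each landmark
    T_true: np.ndarray
    T_obs: np.ndarray
    status: np.ndarray
    scenario: SimScenario = field(repr=False)

    def covariates_at(self, m: int) -> pd.DataFrame:
        return pd.DataFrame(
            {"z1": self.Z[:, 0], "z2": self.Z[:, 1], "z3": self.Z[:, 2], "x": self.X[:, m]}
        )


def _draw_event_times(scn: SimScenario, Z: np.ndarray, X: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    n = Z.shape[0]
    s = np.array(scn.landmarks)
    b = np.array(scn.beta)
    bt = np.array(scn.beta_t)
    # hazard level on each piece (s_m, s_{m+1}]
    lp = np.empty((n, scn.k))
    for m in range(scn.k):
        coef = b + bt * s[m]
        lp[:, m] = Z @ coef[:3] + coef[3] * X[:, m]
    haz = scn.h0 * np.exp(lp)
    widths = np.diff(s)  # k-1 finite pieces, last piece open-ended
    cum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(haz[:, :-1] * widths[None, :], axis=1)], axis=1
    ) if scn.k > 1 else np.zeros((n, 1))
    E = rng.exponential(size=n)
    piece = np.sum(E[:, None] >= cum, axis=1) - 1  # last boundary passed
    return s[piece] + (E - cum[np.arange(n), piece]) / haz[np.arange(n), piece]


def _simulate_raw(scn: SimScenario, rng: np.random.Generator | None = None,
                  uncensored: bool = False, n: int | None = None) -> RawCohort:
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    n = scn.n if n is None else int(n)
    Z = np.column_stack([
        rng.standard_normal(n),
        rng.standard_normal(n),
        (rng.random(n) < 0.5).astype(float),
    ])
    s = np.array(scn.landmarks)
    X0 = rng.standard_normal(n)
    X = X0[:, None] + scn.rho * s[None, :]
    if scn.k > 1:
        X[:, 1:] += rng.normal(scale=scn.sigma_e, size=(n, scn.k - 1))
    T = _draw_event_times(scn, Z, X, rng)
    if uncensored:
        return RawCohort(Z=Z, X=X, T_true=T, T_obs=T.copy(),
                         status=np.ones(n, dtype=int), scenario=scn)
    tau = scn.horizon
    if scn.censor_rate > 0:
        rate = _calibrated_rate(scn._structure_key(), scn.censor_rate)
        C = rng.exponential(scale=1.0 / rate, size=n)
    else:
        C = np.full(n, np.inf)
    T_obs = np.minimum(np.minimum(T, C), tau)
    status = (T <= np.minimum(C, tau)).astype(int)
    return RawCohort(Z=Z, X=X, T_true=T, T_obs=T_obs, status=status, scenario=scn)


@lru_cache(maxsize=64)
def _calibrated_rate(structure_key: tuple, target: float) -> float:
    """Exponential censoring rate hitting the target random-censoring fraction.

    Calibrated by root finding on a fixed large pre-run sample of event
    times: the censored fraction E[1 - exp(-q * min(T, tau))] is monotone
    in the rate q.
    """
    k, lmi, _, window, beta, beta_t, h0, rho, sigma_e = structure_key
    scn = SimScenario(n=_CAL_N, k=k, lmi=lmi, censor_rate=0.0, window=window,
                      beta=beta, beta_t=beta_t, h0=h0, rho=rho, sigma_e=sigma_e,
                      seed=_CAL_SEED)
    raw = _simulate_raw(scn, np.random.default_rng(_CAL_SEED), uncensored=True)
    U = np.minimum(raw.T_true, scn.horizon)

    def frac(q):
        return float(np.mean(-np.expm1(-q * U))) - target

    lo, hi = 1e-8, 1.0
    while frac(hi) < 0:
        hi *= 4.0
        if hi > 1e6:
            raise ValueError(f"censoring target {target} unattainable")
    return float(brentq(frac, lo, hi, xtol=1e-10))


def _raw_to_cohort(raw: RawCohort) -> Cohort:
    scn = raw.scenario
    n = len(raw.T_obs)
    ids = np.arange(n)
    outcomes = pd.DataFrame({"id": ids, "time": raw.T_obs, "status": raw.status})
    frames = []
    for m, s in enumerate(scn.landmarks):
        mask = s <= raw.T_obs
        frames.append(pd.DataFrame({
            "id": ids[mask], "obs_time": float(s),
            "z1": raw.Z[mask, 0], "z2": raw.Z[mask, 1], "z3": raw.Z[mask, 2],
            "x": raw.X[mask, m],
        }))
    meas = pd.concat(frames, ignore_index=True)
    return Cohort(outcomes, meas, n_causes=1)


def simulate_cohort(scenario: SimScenario, rng: np.random.Generator | None = None,
                    uncensored: bool = False) -> Cohort:
    """Generate one cohort from the scenario (deterministic under seed)."""
    return _raw_to_cohort(_simulate_raw(scenario, rng=rng, uncensored=uncensored))


# -- oracle truth -------------------------------------------------------------


def _risks_fast(model: LandmarkSupermodel, cov: pd.DataFrame, s: float,
                n_grid: int = 2048) -> np.ndarray:
    """Single-cause risks via interpolation of the monotone lp -> risk map."""
    lp = model.linear_predictor(cov, s)[:, 0]
    lo, hi = lp.min(), lp.max()
    grid = np.linspace(lo - 1e-9, hi + 1e-9, n_grid)
    F = model._risk_from_lp(grid[:, None], s, model.grid_.window)[:, 0]
    return np.interp(lp, grid, F)


def _uncensored_auc(score: np.ndarray, case: np.ndarray) -> float:
    from .metrics import _rank_sums

    n1, n0 = case.sum(), (~case).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: no cases or no controls")
    conc = _rank_sums(score[case], score[~case], np.ones(int(n0)))
    return float(conc.sum() / (n1 * n0))


def true_summary(scenario: SimScenario, model: LandmarkSupermodel, kind: str,
                 n_mc: int = 100_000, raw: RawCohort | None = None,
                 rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo population value of the fitted model's summary metric.

    Simulates an uncensored cohort from the scenario, computes the
    uncensored empirical AUC or Brier score of the model's predictions at
    each landmark, and averages. A pre-simulated ``raw`` cohort can be
    supplied to share the Monte-Carlo sample across calls.
    """
    if raw is None:
        rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
        raw = _simulate_raw(scenario, rng, uncensored=True, n=n_mc)
    vals = []
    w = scenario.window
    for m, s in enumerate(scenario.landmarks):
        at = raw.T_true > s
        cov = raw.covariates_at(m)[at]
        case = raw.T_true[at] <= s + w
        if kind == "auc":
            lp = model.linear_predictor(cov, s)[:, 0]  # rank-equivalent to risk
            vals.append(_uncensored_auc(lp, case))
        else:
            risk = _risks_fast(model, cov, s)
            vals.append(float(np.mean((case.astype(float) - risk) ** 2)))
    return float(np.mean(vals))


# -- shared experiment plumbing ----------------------------------------------


def _default_model(scn: SimScenario, covariates=None) -> LandmarkSupermodel:
    return LandmarkSupermodel(landmarks=scn.landmarks, window=scn.window,
                              beta_basis="linear", alpha_basis="quadratic", lam=0.0)


def _risk_matrix(model: LandmarkSupermodel, cohort: Cohort, grid: LandmarkGrid) -> np.ndarray:
    """(n_test, L) cause-1 risks; NaN for subjects not at risk at a landmark."""
    stack = build_stack(cohort, grid)
    ids = cohort.outcomes["id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    R = np.full((len(ids), len(grid.landmarks)), np.nan)
    for li, s in enumerate(grid.landmarks):
        rows = stack.rows_at(s)
        if len(rows) == 0:
            continue
        risks = model.predict_risk(rows[model.covariate_names_], s)[:, 0]
        idx = np.fromiter((pos[i] for i in rows["id"]), dtype=int, count=len(rows))
        R[idx, li] = risks
    return R


def _curves(risks: np.ndarray, cohort: Cohort, grid: LandmarkGrid) -> dict[str, MetricCurve]:
    t = cohort.outcomes["time"].to_numpy(dtype=float)
    d = cohort.outcomes["status"].to_numpy()
    return {
        kind: metric_curve(kind, risks, t, d, grid.landmarks, grid.window)
        for kind in ("auc", "bs")
    }


def _drop_covariate(cohort: Cohort, name: str) -> Cohort:
    return Cohort(cohort.outcomes, cohort.measurements.drop(columns=[name]),
                  n_causes=cohort.n_causes, validate=False)


# -- experiments --------------------------------------------------------------


def run_coverage_experiment(
    scenarios, reps: int = 500, level: float = 0.95, seed: int = 0,
    n_mc: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CI coverage of the summary metrics against the Monte-Carlo oracle.

    Per replicate: simulate independent train/test cohorts, fit the
    landmark supermodel on train, form the summary AUC and Brier CIs on
    test, and score whether each CI contains the oracle truth of the
    fitted model (uncensored Monte-Carlo cohort of size ``n_mc``, shared
    within a scenario). Returns ``(table, records)``: per-scenario
    coverage with binomial Monte-Carlo error, and the per-replicate
    records (estimate, se, truth) from which coverage at any level can be
    recomputed.
    """
    scenarios = list(scenarios)
    records = []
    for si, scn in enumerate(scenarios):
        ss = np.random.SeedSequence([seed, si])
        children = ss.spawn(reps + 1)
        truth_raw = _simulate_raw(scn, np.random.default_rng(children[0]),
                                  uncensored=True, n=n_mc)
        grid = scn.grid
        n_fail = 0
        for r in range(reps):
            rng = np.random.default_rng(children[r + 1])
            try:
                train = _raw_to_cohort(_simulate_raw(scn, rng))
                test_raw = _simulate_raw(scn, rng)
                test = _raw_to_cohort(test_raw)
                model = _default_model(scn).fit(train)
                risks = _risk_matrix(model, test, grid)
                curves = _curves(risks, test, grid)
                for kind in ("auc", "bs"):
                    sm = summary_metric(curves[kind], level=level)
                    truth = true_summary(scn, model, kind, raw=truth_raw)
                    records.append({
                        "scenario": si, "n": scn.n, "k": scn.k, "lmi": scn.lmi,
                        "censor_rate": scn.censor_rate, "rep": r, "metric": kind,
                        "estimate": sm.value, "se": sm.se, "truth": truth,
                        "covered": bool(sm.lo <= truth <= sm.hi),
                    })
            except (ValueError, RuntimeError) as exc:
                n_fail += 1
                logger.warning("scenario %d replicate %d failed: %s", si, r, exc)
        if n_fail:
            logger.warning("scenario %d: %d/%d replicates excluded", si, n_fail, reps)
    rec = pd.DataFrame(records)
    rows = []
    for (si, kind), g in rec.groupby(["scenario", "metric"]):
        c = g["covered"].mean()
        rows.append({
            "scenario": si, "n": g["n"].iloc[0], "k": g["k"].iloc[0],
            "lmi": g["lmi"].iloc[0], "censor_rate": g["censor_rate"].iloc[0],
            "metric": kind, "coverage": c,
            "mc_se": float(np.sqrt(c * (1 - c) / len(g))), "n_reps": len(g),
        })
    return pd.DataFrame(rows), rec


def run_type1_experiment(
    scenario: SimScenario, reps: int = 500, levels=(0.01, 0.05, 0.10), seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type I error of the model-comparison test between equivalent models.

    Two supermodels of identical specification are fitted to independent
    training draws and both evaluated on one shared test set; p-values of
    the summary-difference test are collected and rejection rates at each
    level returned, with per-replicate p-values alongside.
    """
    ss = np.random.SeedSequence([seed, 7])
    children = ss.spawn(reps)
    grid = scenario.grid
    records = []
    n_fail = 0
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        try:
            train1 = _raw_to_cohort(_simulate_raw(scenario, rng))
            train2 = _raw_to_cohort(_simulate_raw(scenario, rng))
            test = _raw_to_cohort(_simulate_raw(scenario, rng))
            m1 = _default_model(scenario).fit(train1)
            m2 = _default_model(scenario).fit(train2)
            r1 = _risk_matrix(m1, test, grid)
            r2 = _risk_matrix(m2, test, grid)
            c1, c2 = _curves(r1, test, grid), _curves(r2, test, grid)
            for kind in ("auc", "bs"):
                res = compare_models(c1[kind], c2[kind])
                records.append({"rep": r, "metric": kind, "p_value": res.p_value,
                                "delta": res.delta})
        except (ValueError, RuntimeError) as exc:
            n_fail += 1
            logger.warning("type-I replicate %d failed: %s", r, exc)
    rec = pd.DataFrame(records)
    rows = []
    for kind, g in rec.groupby("metric"):
        for a in levels:
            rate = float((g["p_value"] < a).mean())
            rows.append({"metric": kind, "level": a, "rejection_rate": rate,
                         "mc_se": float(np.sqrt(rate * (1 - rate) / len(g))),
                         "n_reps": len(g), "n_fail": n_fail})
    return pd.DataFrame(rows), rec


def run_power_experiment(
    scenarios, reps: int = 500, level: float = 0.05, seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Power of the summary test vs multiplicity-adjusted landmark tests.

    M1 is the full supermodel; M2 omits the longitudinal covariate. Both
    are fitted on the same training draw and compared on a shared test
    set. Per replicate the summary-difference p-value and the family of
    per-landmark p-values (Bonferroni- and Benjamini-Hochberg-adjusted;
    the family rejects if any adjusted p < level) are recorded.
    """
    scenarios = list(scenarios)
    records = []
    for si, scn in enumerate(scenarios):
        ss = np.random.SeedSequence([seed, 13, si])
        children = ss.spawn(reps)
        grid = scn.grid
        n_fail = 0
        for r in range(reps):
            rng = np.random.default_rng(children[r])
            try:
                train = _raw_to_cohort(_simulate_raw(scn, rng))
                test = _raw_to_cohort(_simulate_raw(scn, rng))
                m_full = _default_model(scn).fit(train)
                m_red = _default_model(scn).fit(_drop_covariate(train, "x"))
                r_full = _risk_matrix(m_full, test, grid)
                r_red = _risk_matrix(m_red, _drop_covariate(test, "x"), grid)
                c_full, c_red = _curves(r_full, test, grid), _curves(r_red, test, grid)
                for kind in ("auc", "bs"):
                    summ = compare_models(c_full[kind], c_red[kind])
                    lmw = compare_landmarkwise(c_full[kind], c_red[kind])
                    p_bonf = adjust_pvalues(lmw["p_value"], "bonferroni")
                    p_bh = adjust_pvalues(lmw["p_value"], "bh")
                    records.append({
                        "scenario": si, "n": scn.n, "k": scn.k,
                        "censor_rate": scn.censor_rate, "rep": r, "metric": kind,
                        "reject_summary": summ.p_value < level,
                        "reject_bonferroni": bool((p_bonf < level).any()),
                        "reject_bh": bool((p_bh < level).any()),
                    })
            except (ValueError, RuntimeError) as exc:
                n_fail += 1
                logger.warning("power scenario %d replicate %d failed: %s", si, r, exc)
        if n_fail:
            logger.warning("power scenario %d: %d/%d replicates excluded", si, n_fail, reps)
    rec = pd.DataFrame(records)
    rows = []
    for (si, kind), g in rec.groupby(["scenario", "metric"]):
        rows.append({
            "scenario": si, "n": g["n"].iloc[0], "k": g["k"].iloc[0],
            "censor_rate": g["censor_rate"].iloc[0], "metric": kind,
            "power_summary": float(g["reject_summary"].mean()),
            "power_bonferroni": float(g["reject_bonferroni"].mean()),
            "power_bh": float(g["reject_bh"].mean()),
            "n_reps": len(g),
        })
    return pd.DataFrame(rows), rec
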