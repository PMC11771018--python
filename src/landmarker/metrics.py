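"""Time-dependent IPCW metrics and their landmark summaries.

For a landmark ``s`` and window ``w``, the time-dependent AUC(s, s+w)
measures how well predicted risks rank cause-1 events in ``(s, s+w]``
above controls (subjects event-free at ``s+w`` plus, by default,
competing-cause events in the window); the time-dependent Brier score
BS(s, s+w) is the IPCW mean squared difference between the event
indicator and the predicted risk. Censoring is handled by inverse
probability of censoring weights 1/G(.|s) from a Kaplan-Meier estimator
of the censoring distribution, conditional on being at risk at ``s``.

The summary metrics average the per-landmark estimates over the landmark
set S. Because the same test subjects appear at several landmarks, the
per-landmark estimators are correlated; a first-order i.i.d.
decomposition (per-subject influence values, including the term from
estimating G) yields the cross-landmark covariance, a Wald confidence
interval for the summary, and a z-test for the difference between two
models evaluated on the same test subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StepSurvival",
    "censoring_km",
    "td_auc",
    "td_brier",
    "MetricCurve",
    "metric_curve",
    "SummaryMetric",
    "summary_metric",
    "ComparisonResult",
    "compare_models",
    "compare_landmarkwise",
    "adjust_pvalues",
]


@dataclass
class StepSurvival:
    """Right-continuous survival step function (product-limit form)."""

    times: np.ndarray  # jump times, ascending
    surv: np.ndarray  # value just after each jump time

    def eval(self, t) -> np.ndarray:
        vals = np.concatenate([[1.0], self.surv])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return vals[idx]

    def eval_left(self, t) -> np.ndarray:
        """Left limit G(t-): jumps strictly before t."""
        vals = np.concatenate([[1.0], self.surv])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        return vals[idx]


def censoring_km(times, status) -> StepSurvival:
    """Kaplan-Meier estimator of the censoring survival G(t) = P(C > t).

    Censorings (status 0) are the events of the censoring process; actual
    events (status >= 1) censor it. The risk set at time u contains all
    subjects with observed time >= u.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(status) == 0
    if len(t) == 0:
        raise ValueError("empty outcome sample")
    ct = np.unique(t[c])
    order = np.sort(t)
    n = len(t)
    at_risk = n - np.searchsorted(order, ct, side="left")
    d = np.array([np.sum((t == u) & c) for u in ct], dtype=float)
    surv = np.cumprod(1.0 - d / at_risk)
    return StepSurvival(times=ct, surv=surv)


# -- influence-function machinery --------------------------------------------


def _censoring_iid_term(T, is_cens, a, tau):
    """(1/m) * sum_j a_j * k_i(tau_j-) for every subsample subject i.

    ``k_i(t) = int_{(s, t)} dM_i^C(u) / S(u)`` is the censoring-martingale
    integral from the first-order Kaplan-Meier expansion, with S the
    at-risk proportion. All evaluation points use left limits (jumps
    strictly before tau_j), matching the G(.-) convention of the weights.
    """
    m = len(T)
    order = np.sort(T)
    # censoring process: distinct censoring times, multiplicities, risk sets
    ct = np.unique(T[is_cens])
    if len(ct) == 0:
        return np.zeros(m)
    atr = m - np.searchsorted(order, ct, side="left")  # #{T >= u}
    dc = np.array([np.sum((T == u) & is_cens) for u in ct], dtype=float)
    dH = m * dc / atr.astype(float) ** 2  # dLambda_C(u) / S(u)
    Hcum = np.concatenate([[0.0], np.cumsum(dH)])

    def hfun_left(t):
        return Hcum[np.searchsorted(ct, t, side="left")]

    def hfun(t):
        return Hcum[np.searchsorted(ct, t, side="right")]

    tau = np.asarray(tau, dtype=float)
    a = np.asarray(a, dtype=float)
    o = np.argsort(tau, kind="stable")
    tau_s, a_s = tau[o], a[o]
    pref_a = np.concatenate([[0.0], np.cumsum(a_s)])
    aH = a_s * hfun_left(tau_s)
    pref_aH = np.concatenate([[0.0], np.cumsum(aH)])
    total_a = pref_a[-1]

    idx = np.searchsorted(tau_s, T, side="right")  # #{tau_j <= T_i}
    a_gt = total_a - pref_a[idx]  # sum over tau_j > T_i
    term2 = pref_aH[idx] + hfun(T) * a_gt
    s_at_T = (m - np.searchsorted(order, T, side="left")) / m
    term1 = np.where(is_cens, a_gt / s_at_T, 0.0)
    return (term1 - term2) / m


def _classify(T, d, s, w, include_competing):
    """Case/control partition of the at-risk-at-s subsample."""
    case = (d == 1) & (T > s) & (T <= s + w)
    comp = (d >= 2) & (T > s) & (T <= s + w) if include_competing else np.zeros_like(case)
    surv = (T > s + w) | ((T == s + w) & (d == 0))
    return case, comp.astype(bool), surv


def _subsample(risks, times, status, s):
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    risks = np.asarray(risks, dtype=float)
    at_risk = times > s
    pi = risks[at_risk]
    if np.isnan(pi).any():
        raise ValueError(f"missing predicted risks for subjects at risk at s={s}")
    return at_risk, times[at_risk], status[at_risk], pi


def _weights(T, d, s, w, case, comp, surv, G: StepSurvival | None):
    """Conditional IPCW weights 1/G(.|s), all with left-limit evaluation."""
    if G is None:
        G = censoring_km(T, d)  # subsample KM == marginal ratio G(t)/G(s)
        gs = 1.0
    else:
        gs = float(G.eval(np.array([s]))[0])
        if gs <= 0:
            raise ValueError(f"censoring survival is zero at landmark s={s}")
    g_at_T = G.eval_left(T) / gs
    g_at_h = float(G.eval_left(np.array([s + w]))[0]) / gs
    need_T = case | comp
    if np.any(need_T & (g_at_T <= 0)):
        t_bad = T[need_T & (g_at_T <= 0)][0]
        raise ValueError(f"censoring survival is zero at evaluation point t={t_bad}")
    if surv.any() and g_at_h <= 0:
        raise ValueError(f"censoring survival is zero at evaluation point t={s + w}")
    wgt = np.zeros(len(T))
    wgt[need_T] = 1.0 / g_at_T[need_T]
    wgt[surv] = 1.0 / g_at_h
    return wgt


def td_brier(risks, times, status, s, window, G: StepSurvival | None = None,
             include_competing: bool = True) -> tuple[float, np.ndarray]:
    """IPCW Brier score BS(s, s+w) with full-sample influence values.

    ``risks`` are predicted cause-1 cumulative incidences over
    ``(s, s+w]`` for the full test sample (entries for subjects not at
    risk at ``s`` are ignored). Returns ``(estimate, phi)`` where ``phi``
    has one influence value per test subject (0 for those not at risk).
    """
    at_risk, T, d, pi = _subsample(risks, times, status, s)
    n, m = len(at_risk), int(at_risk.sum())
    if m == 0:
        raise ValueError(f"no subjects at risk at landmark s={s}")
    case, comp, surv = _classify(T, d, s, window, include_competing=True)
    wgt = _weights(T, d, s, window, case, comp, surv, G)
    D = case.astype(float)
    a = wgt * (D - pi) ** 2
    theta = float(a.mean())
    tau = np.where(case | comp, T, s + window)
    used = case | comp | surv
    gpart = _censoring_iid_term(T, d == 0, np.where(used, a, 0.0), tau)
    psi = a - theta + gpart
    phi = np.zeros(n)
    phi[at_risk] = (n / m) * psi
    return theta, phi


def _rank_sums(pi_query, pi_ref, w_ref):
    """For each query score, sum of ref weights strictly below + half ties."""
    o = np.argsort(pi_ref, kind="stable")
    pr, wr = pi_ref[o], w_ref[o]
    cw = np.concatenate([[0.0], np.cumsum(wr)])
    lo = np.searchsorted(pr, pi_query, side="left")
    hi = np.searchsorted(pr, pi_query, side="right")
    return cw[lo] + 0.5 * (cw[hi] - cw[lo])


def td_auc(risks, times, status, s, window, G: StepSurvival | None = None,
           include_competing: bool = True) -> tuple[float, np.ndarray]:
    """IPCW time-dependent AUC(s, s+w) with full-sample influence values.

    Cases are cause-1 events in ``(s, s+w]``; controls are subjects
    event-free at ``s+w`` plus (by default) competing-cause events in the
    window. Risk ties count one half. Returns ``(estimate, phi)`` aligned
    to the full test sample (0 for subjects not at risk at ``s``).
    """
    at_risk, T, d, pi = _subsample(risks, times, status, s)
    n, m = len(at_risk), int(at_risk.sum())
    if m == 0:
        raise ValueError(f"no subjects at risk at landmark s={s}")
    case, comp, surv = _classify(T, d, s, window, include_competing)
    ctrl = comp | surv
    if not case.any() or not ctrl.any():
        raise ValueError(
            f"AUC undefined at s={s}: {int(case.sum())} cases, {int(ctrl.sum())} controls"
        )
    wgt = _weights(T, d, s, window, case, comp, surv, G)
    Wc = np.where(case, wgt, 0.0)
    Wd = np.where(ctrl, wgt, 0.0)

    # rowcase_i = Wc_i * (1/m) sum_j Wd_j conc_ij ; rowctrl analogous
    conc_case = _rank_sums(pi, pi[ctrl], wgt[ctrl])  # controls below each score
    rowcase = Wc * conc_case / m
    # for controls: sum of case weights strictly above + half ties
    o_desc = -pi
    conc_ctrl = _rank_sums(o_desc, o_desc[case], wgt[case])
    rowctrl = Wd * conc_ctrl / m

    num = float(rowcase.sum() / m)
    wc_bar, wd_bar = Wc.mean(), Wd.mean()
    den = wc_bar * wd_bar
    auc = num / den

    tau = np.where(case | comp, T, s + window)
    g_num = _censoring_iid_term(T, d == 0, rowcase + rowctrl, tau)
    g_den = _censoring_iid_term(T, d == 0, Wc * wd_bar + Wd * wc_bar, tau)
    phi_num = rowcase + rowctrl - 2.0 * num + g_num
    phi_den = Wc * wd_bar + Wd * wc_bar - 2.0 * den + g_den
    psi = (phi_num - auc * phi_den) / den
    phi = np.zeros(n)
    phi[at_risk] = (n / m) * psi
    return auc, phi


# -- curves and summaries -----------------------------------------------------


@dataclass
class MetricCurve:
    """Landmark-indexed estimates of one metric with influence values."""

    kind: str  # "auc" or "bs"
    landmarks: np.ndarray
    window: float
    estimates: np.ndarray  # (L,)
    influence: np.ndarray  # (n_test, L), 0 for subjects not at risk
    n_test: int
    at_risk: np.ndarray  # (L,) subsample sizes

    def landmark_se(self) -> np.ndarray:
        """Per-landmark standard errors from the influence values."""
        return np.sqrt((self.influence**2).sum(axis=0)) / self.n_test


def metric_curve(kind: str, risks_by_landmark, times, status, landmarks, window,
                 G: StepSurvival | None = None, include_competing: bool = True) -> MetricCurve:
    """Evaluate AUC or Brier at every landmark of a grid.

    ``risks_by_landmark`` is an (n_test, L) array of predicted cause-1
    risks (NaN allowed for subjects not at risk at the given landmark).
    """
    fn = {"auc": td_auc, "bs": td_brier}[kind]
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    risks_by_landmark = np.asarray(risks_by_landmark, dtype=float)
    landmarks = np.asarray(landmarks, dtype=float)
    n = len(times)
    L = len(landmarks)
    est = np.empty(L)
    phi = np.zeros((n, L))
    m = np.empty(L, dtype=int)
    failures = []
    for li, s in enumerate(landmarks):
        try:
            est[li], phi[:, li] = fn(
                risks_by_landmark[:, li], times, status, s, window,
                G=G, include_competing=include_competing,
            )
        except ValueError as exc:
            failures.append((s, str(exc)))
            est[li] = np.nan
        m[li] = int((times > s).sum())
    if failures:
        msg = "; ".join(f"s={s}: {e}" for s, e in failures)
        raise ValueError(f"metric undefined at landmark(s): {msg}")
    return MetricCurve(
        kind=kind, landmarks=landmarks, window=window, estimates=est,
        influence=phi, n_test=n, at_risk=m,
    )


@dataclass
class SummaryMetric:
    value: float
    cov: np.ndarray  # (L, L) covariance of the landmark-wise estimates
    se: float
    level: float
    lo: float
    hi: float


def summary_metric(curve: MetricCurve, level: float = 0.95) -> SummaryMetric:
    """Average the landmark metrics into one score with a Wald CI.

    theta_bar = mean_s theta(s, s+w); the covariance of the landmark-wise
    estimates is the per-subject influence covariance divided by n; the
    standard error of the mean follows by summing the covariance. CI
    endpoints are truncated to [0, 1].
    """
    if np.isnan(curve.estimates).any():
        bad = curve.landmarks[np.isnan(curve.estimates)]
        raise ValueError(f"undefined landmark estimates at s={list(bad)}")
    n = curve.n_test
    L = len(curve.landmarks)
    theta = float(curve.estimates.mean())
    cov = curve.influence.T @ curve.influence / n**2
    se = float(np.sqrt(cov.sum()) / L)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, theta - z * se)
    hi = min(1.0, theta + z * se)
    return SummaryMetric(value=theta, cov=cov, se=se, level=level, lo=lo, hi=hi)


@dataclass
class ComparisonResult:
    delta: float
    se: float
    z: float
    p_value: float


def _check_comparable(curveA: MetricCurve, curveB: MetricCurve) -> None:
    if curveA.kind != curveB.kind:
        raise ValueError("curves measure different metrics")
    if curveA.n_test != curveB.n_test:
        raise ValueError("curves computed on different test samples")
    if len(curveA.landmarks) != len(curveB.landmarks) or not np.allclose(
        curveA.landmarks, curveB.landmarks
    ):
        raise ValueError("curves computed on different landmark sets")


def compare_models(curveA: MetricCurve, curveB: MetricCurve, level: float = 0.95) -> ComparisonResult:
    """Two-sided z-test of H0: the two models' summary metrics are equal.

    Both curves must come from the same test subjects and landmarks; the
    test statistic uses the per-subject influence values of the
    difference, which accounts for the correlation induced by the shared
    test sample.
    """
    _check_comparable(curveA, curveB)
    delta = float(curveA.estimates.mean() - curveB.estimates.mean())
    psi = (curveA.influence - curveB.influence).mean(axis=1)
    n = curveA.n_test
    se = float(np.sqrt((psi**2).sum()) / n)
    if se == 0.0:
        return ComparisonResult(delta=delta, se=0.0, z=0.0, p_value=1.0 if delta == 0 else 0.0)
    z = delta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(delta=delta, se=se, z=z, p_value=p)


def compare_landmarkwise(curveA: MetricCurve, curveB: MetricCurve) -> pd.DataFrame:
    """Per-landmark z-tests of the metric difference (no multiplicity adjustment)."""
    _check_comparable(curveA, curveB)
    n = curveA.n_test
    rows = []
    for li, s in enumerate(curveA.landmarks):
        delta = float(curveA.estimates[li] - curveB.estimates[li])
        psi = curveA.influence[:, li] - curveB.influence[:, li]
        se = float(np.sqrt((psi**2).sum()) / n)
        if se == 0.0:
            z, p = 0.0, 1.0 if delta == 0 else 0.0
        else:
            z = delta / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"landmark": s, "delta": delta, "se": se, "z": z, "p_value": p})
    return pd.DataFrame(rows)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "benjamini-hochberg": "fdr_bh"}[
        method.lower()
    ]
    return multipletests(p, method=key)[1]
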