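"""Penalized (cause-specific) Cox landmark supermodels.

One model is fitted per cause to the stacked landmark dataset by
maximizing the penalized log pseudo-partial likelihood, with risk sets
pooled across landmark rows as left-truncated counting-process intervals.
Together with Breslow baseline cumulative hazards, the fitted supermodel
produces dynamic w-year cumulative-incidence predictions
F_j(s+w | s, Z(s)) from any landmark s in the grid, holding the linear
predictor alpha_j(s) + beta_j(s)'Z(s) fixed over the window.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _coxsolver as solver
from .cohort import Cohort, LandmarkGrid
from .stacking import StackedDataset, TDSpec, build_stack, expand_design

__all__ = [
    "LandmarkSupermodel",
    "BaselineHazard",
    "fit_pencox",
    "fit_csc",
    "predict_risk",
    "cv_lambda",
    "neg_log_ipl",
]

logger = logging.getLogger(__name__)

neg_log_ipl = solver.neg_log_ipl


@dataclass
class BaselineHazard:
    """Breslow baseline cumulative hazard as a step function."""

    times: np.ndarray
    increments: np.ndarray

    def cum(self, t) -> np.ndarray:
        """H0(t), right-continuous (jumps at event times included at t)."""
        cs = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return cs[idx]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValueError("baseline hazard increments must be nonnegative")


class LandmarkSupermodel(BaseEstimator):
    """Penalized landmark supermodel with cause-specific hazards.

    Parameters
    ----------
    landmarks, window : grid used when fitting from a raw cohort; ignored
        when a pre-built :class:`StackedDataset` is supplied to :meth:`fit`.
    beta_basis, alpha_basis : preset names ('const'|'linear'|'quadratic',
        resp. 'none'|'linear'|'quadratic') or a :class:`TDSpec`.
    lam : penalty strength (lambda >= 0).
    l1_ratio : elastic-net mixing in [0, 1]; 1 = LASSO, 0 = ridge.
    penalty_factors : per-column nonnegative multipliers over the expanded
        design (alpha columns included); default 1 everywhere.
    tol, max_iter : solver convergence controls (max relative coefficient
        change and iteration cap).
    standardize : standardize design columns before penalization
        (coefficients are always reported on the original scale).

    Attributes (after fit)
    ----------------------
    coef_ : DataFrame (design columns x causes), original scale.
    baselines_ : dict cause -> BaselineHazard.
    column_map_ : list of per-column records (covariate, basis, kind).
    grid_, td_spec_, n_causes_, covariate_names_, fits_.
    """

    def __init__(
        self,
        landmarks=None,
        window: float | None = None,
        beta_basis="linear",
        alpha_basis="quadratic",
        lam: float = 0.0,
        l1_ratio: float = 0.0,
        penalty_factors=None,
        tol: float = 1e-7,
        max_iter: int = 10_000,
        standardize: bool = True,
    ):
        self.landmarks = landmarks
        self.window = window
        self.beta_basis = beta_basis
        self.alpha_basis = alpha_basis
        self.lam = lam
        self.l1_ratio = l1_ratio
        self.penalty_factors = penalty_factors
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    # -- fitting --------------------------------------------------------------

    def _resolve_spec(self, grid: LandmarkGrid) -> TDSpec:
        if isinstance(self.beta_basis, TDSpec):
            return self.beta_basis
        return TDSpec.from_names(self.beta_basis, self.alpha_basis, s0=grid.s0)

    def _stack(self, data) -> StackedDataset:
        if isinstance(data, StackedDataset):
            return data
        if isinstance(data, Cohort):
            if self.landmarks is None or self.window is None:
                raise ValueError(
                    "landmarks and window are required to fit from a Cohort"
                )
            grid = LandmarkGrid(tuple(self.landmarks), float(self.window))
            return build_stack(data, grid)
        raise TypeError(f"cannot fit a supermodel to {type(data).__name__}")

    def fit(self, data, causes: int | None = None) -> "LandmarkSupermodel":
        """Fit one penalized stacked Cox model per cause.

        ``data`` is a :class:`Cohort` (stacked internally using
        ``landmarks`` / ``window``) or a pre-built :class:`StackedDataset`.
        """
        stack = self._stack(data)
        if len(stack) == 0:
            raise ValueError("stacked dataset has no rows")
        grid = stack.grid
        spec = self._resolve_spec(grid)
        design, cmap = expand_design(stack, spec)
        X = design.to_numpy(dtype=float)
        entry = stack.data["entry"].to_numpy(dtype=float)
        exit_ = stack.data["exit"].to_numpy(dtype=float)
        status = stack.data["status"].to_numpy()
        J = int(causes) if causes is not None else int(stack.n_causes)
        if J < 1:
            raise ValueError("number of causes must be >= 1")
        pf = self.penalty_factors
        if pf is not None:
            pf = np.asarray(pf, dtype=float)
            if len(pf) != X.shape[1]:
                raise ValueError("penalty_factors length must match design columns")

        fits, coefs, baselines = {}, {}, {}
        for j in range(1, J + 1):
            if not np.any(status == j):
                raise ValueError(f"cause {j} has zero events in the stacked data")
            res = solver.fit_penalized(
                X, entry, exit_, status, cause=j,
                lam=self.lam, l1_ratio=self.l1_ratio, penalty_factors=pf,
                tol=self.tol, max_iter=self.max_iter, standardize=self.standardize,
            )
            lp = X @ res.beta
            times, incr = solver.breslow_increments(
                solver.CoxData(entry, exit_, status == j), lp
            )
            fits[j] = res
            coefs[j] = res.beta
            baselines[j] = BaselineHazard(times, incr)

        self.grid_ = grid
        self.td_spec_ = spec
        self.column_map_ = cmap
        self.design_columns_ = list(design.columns)
        self.covariate_names_ = list(stack.covariate_names)
        self.n_causes_ = J
        self.coef_ = pd.DataFrame(
            {f"cause_{j}": coefs[j] for j in range(1, J + 1)},
            index=self.design_columns_,
        )
        self.baselines_ = baselines
        self.fits_ = fits
        return self

    # -- prediction -----------------------------------------------------------

    def linear_predictor(self, covariates: pd.DataFrame, s: float) -> np.ndarray:
        """Per-cause linear predictors alpha_j(s) + beta_j(s)'Z(s), shape (n, J)."""
        self._check_fitted()
        missing = [c for c in self.covariate_names_ if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariates missing model columns: {missing}")
        n = len(covariates)
        lp = np.zeros((n, self.n_causes_))
        beta_fns = dict(self.td_spec_.beta_basis)
        alpha_fns = dict(self.td_spec_.alpha_basis)
        s_arr = np.array([float(s)])
        for ci, rec in enumerate(self.column_map_):
            if rec["kind"] == "beta":
                fval = float(beta_fns[rec["basis"]](s_arr)[0])
                zcol = covariates[rec["covariate"]].to_numpy(dtype=float) * fval
            else:
                fval = float(alpha_fns[rec["basis"]](s_arr)[0])
                zcol = np.full(n, fval)
            for j in range(1, self.n_causes_ + 1):
                lp[:, j - 1] += self.coef_.iloc[ci, j - 1] * zcol
        return lp

    def predict_risk(
        self,
        covariates: pd.DataFrame,
        s: float,
        window: float | None = None,
        max_chunk: int = 4096,
    ) -> np.ndarray:
        """Predicted cumulative incidence F_j(s+w | s, Z(s)), shape (n, J).

        The per-cause linear predictor is frozen at the landmark over the
        whole window. Within each baseline jump the total cause-specific
        hazard is treated as exponentially distributed, so for J causes
        the predicted incidences and the overall survival add exactly to
        one; for J=1 a single jump of size ``u`` yields ``1 - exp(-u)``.
        """
        self._check_fitted()
        w = float(window) if window is not None else self.grid_.window
        if not (self.grid_.landmarks[0] <= s <= self.grid_.landmarks[-1]):
            raise ValueError(
                f"landmark s={s} outside the fitted grid "
                f"[{self.grid_.landmarks[0]}, {self.grid_.landmarks[-1]}]"
            )
        lp = self.linear_predictor(covariates, s)
        return self._risk_from_lp(lp, s, w, max_chunk=max_chunk)

    def _window_steps(self, s: float, w: float) -> tuple[np.ndarray, np.ndarray]:
        """Union of baseline jump times in (s, s+w] and per-cause increments (J, K)."""
        all_times = np.unique(
            np.concatenate(
                [b.times[(b.times > s) & (b.times <= s + w)] for b in self.baselines_.values()]
            )
        )
        max_obs = max(
            (b.times.max() for b in self.baselines_.values() if len(b.times)),
            default=-np.inf,
        )
        if s + w > max_obs:
            logger.warning(
                "prediction horizon %.4g exceeds the largest observed event time "
                "%.4g; risk computed on available support", s + w, max_obs
            )
        J = self.n_causes_
        dH = np.zeros((J, len(all_times)))
        for j in range(1, J + 1):
            b = self.baselines_[j]
            pos = np.searchsorted(all_times, b.times)
            inside = (b.times > s) & (b.times <= s + w)
            dH[j - 1, pos[inside]] = b.increments[inside]
        return all_times, dH

    def _risk_from_lp(self, lp: np.ndarray, s: float, w: float, max_chunk: int = 4096) -> np.ndarray:
        _, dH = self._window_steps(s, w)
        J, K = dH.shape
        n = lp.shape[0]
        out = np.zeros((n, J))
        if K == 0:
            return out
        explp = np.exp(lp)  # (n, J)
        for lo in range(0, n, max_chunk):
            hi = min(lo + max_chunk, n)
            e = explp[lo:hi]  # (m, J)
            lam = e @ dH  # (m, K) total hazard increments
            cum = np.cumsum(lam, axis=1)
            s_pre = np.exp(-(cum - lam))  # survival up to each jump (left limit)
            jump = -np.expm1(-lam) * s_pre  # total event probability at each jump
            with np.errstate(invalid="ignore", divide="ignore"):
                for j in range(J):
                    frac = np.where(lam > 0, (e[:, j : j + 1] * dH[j]) / np.where(lam > 0, lam, 1.0), 0.0)
                    out[lo:hi, j] = (jump * frac).sum(axis=1)
        return out

    def predict_survival(self, covariates: pd.DataFrame, s: float, window: float | None = None) -> np.ndarray:
        """Overall event-free probability S(s+w | s), shape (n,)."""
        self._check_fitted()
        w = float(window) if window is not None else self.grid_.window
        lp = self.linear_predictor(covariates, s)
        _, dH = self._window_steps(s, w)
        total = np.exp(lp) @ dH.sum(axis=1)
        return np.exp(-total)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("supermodel is not fitted")

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        self._check_fitted()
        if isinstance(self.beta_basis, TDSpec):
            raise ValueError("models with custom basis callables cannot be serialized")
        obj = {
            "landmarks": list(self.grid_.landmarks),
            "window": self.grid_.window,
            "beta_basis": self.beta_basis,
            "alpha_basis": self.alpha_basis,
            "lam": self.lam,
            "l1_ratio": self.l1_ratio,
            "n_causes": self.n_causes_,
            "covariate_names": self.covariate_names_,
            "design_columns": self.design_columns_,
            "column_map": self.column_map_,
            "coef": {c: self.coef_[c].tolist() for c in self.coef_.columns},
            "baselines": {
                str(j): {"times": b.times.tolist(), "increments": b.increments.tolist()}
                for j, b in self.baselines_.items()
            },
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSupermodel":
        obj = json.loads(text)
        model = cls(
            landmarks=obj["landmarks"],
            window=obj["window"],
            beta_basis=obj["beta_basis"],
            alpha_basis=obj["alpha_basis"],
            lam=obj["lam"],
            l1_ratio=obj["l1_ratio"],
        )
        grid = LandmarkGrid(tuple(obj["landmarks"]), float(obj["window"]))
        model.grid_ = grid
        model.td_spec_ = TDSpec.from_names(obj["beta_basis"], obj["alpha_basis"], s0=grid.s0)
        model.column_map_ = obj["column_map"]
        model.design_columns_ = obj["design_columns"]
        model.covariate_names_ = obj["covariate_names"]
        model.n_causes_ = int(obj["n_causes"])
        model.coef_ = pd.DataFrame(
            {c: obj["coef"][c] for c in sorted(obj["coef"], key=lambda s: int(s.split("_")[1]))},
            index=obj["design_columns"],
        )
        model.baselines_ = {
            int(j): BaselineHazard(np.array(d["times"]), np.array(d["increments"]))
            for j, d in obj["baselines"].items()
        }
        model.fits_ = {}
        return model


# -- functional wrappers ------------------------------------------------------


def fit_pencox(stack: StackedDataset, spec: TDSpec | None = None, lam: float = 0.0,
               l1_ratio: float = 0.0, penalty_factors=None, cause: int = 1,
               **kwargs) -> LandmarkSupermodel:
    """Fit a single-cause penalized landmark supermodel to a stacked dataset."""
    model = LandmarkSupermodel(lam=lam, l1_ratio=l1_ratio, penalty_factors=penalty_factors, **kwargs)
    if spec is not None:
        model.beta_basis = spec
    if cause != 1:
        relabeled = stack.data.copy()
        relabeled["status"] = np.where(relabeled["status"].to_numpy() == cause, 1, 0)
        stack = StackedDataset(relabeled, stack.grid, stack.covariate_names, n_causes=1)
    return model.fit(stack, causes=1)


def fit_csc(stack: StackedDataset, spec: TDSpec | None = None, lam: float = 0.0,
            l1_ratio: float = 0.0, penalty_factors=None, **kwargs) -> LandmarkSupermodel:
    """Fit a cause-specific (J >= 2) penalized landmark supermodel."""
    if stack.n_causes < 2:
        raise ValueError("fit_csc requires J >= 2 competing causes; use fit_pencox for J=1")
    model = LandmarkSupermodel(lam=lam, l1_ratio=l1_ratio, penalty_factors=penalty_factors, **kwargs)
    if spec is not None:
        model.beta_basis = spec
    return model.fit(stack, causes=stack.n_causes)


def predict_risk(model: LandmarkSupermodel, covariates: pd.DataFrame, s: float,
                 window: float | None = None) -> np.ndarray:
    return model.predict_risk(covariates, s, window=window)


def cv_lambda(
    stack: StackedDataset,
    spec: TDSpec | None = None,
    l1_ratio: float = 0.0,
    lambdas=None,
    n_folds: int = 5,
    seed: int = 0,
    cause: int = 1,
    n_lambdas: int = 100,
    decades: float = 4.0,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated choice of the penalty strength lambda.

    Folds are formed by subject id (all landmark rows of a subject share a
    fold). The validation criterion is the held-out pseudo-partial-
    likelihood deviance, evaluated on the validation fold's own risk sets.
    Returns ``(lam_best, table)`` with the mean validation deviance per
    lambda; ties resolve to the larger lambda.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    grid = stack.grid
    if spec is None:
        spec = TDSpec.from_names(s0=grid.s0)
    design, _ = expand_design(stack, spec)
    X = design.to_numpy(dtype=float)
    entry = stack.data["entry"].to_numpy(dtype=float)
    exit_ = stack.data["exit"].to_numpy(dtype=float)
    status = stack.data["status"].to_numpy()
    ids = stack.data["id"].to_numpy()

    if lambdas is None:
        data_all = solver.CoxData(entry, exit_, status == cause)
        lmax = solver.lambda_max(data_all, (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0),
                                 l1_ratio, np.ones(X.shape[1]))
        lambdas = np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambdas)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    uids = pd.unique(ids)
    perm = rng.permutation(len(uids))
    fold_of = {uid: perm[i] % n_folds for i, uid in enumerate(uids)}
    folds = np.array([fold_of[i] for i in ids])

    dev = np.full((n_folds, len(lambdas)), np.nan)
    for f in range(n_folds):
        val = folds == f
        if not np.any(status[val] == cause):
            warnings.warn(f"fold {f} has zero cause-{cause} events; skipped")
            continue
        tr = ~val
        for li, lam in enumerate(lambdas):
            res = solver.fit_penalized(
                X[tr], entry[tr], exit_[tr], status[tr], cause=cause,
                lam=lam, l1_ratio=l1_ratio, tol=1e-6,
            )
            dev[f, li] = 2.0 * solver.neg_log_ipl(
                res.beta, X[val], entry[val], exit_[val], status[val], cause=cause
            )
    mean_dev = np.nanmean(dev, axis=0)
    # lambdas sorted descending: argmin picks the first (largest) on ties
    best = int(np.argmin(mean_dev))
    table = pd.DataFrame({"lam": lambdas, "mean_deviance": mean_dev})
    return float(lambdas[best]), table
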