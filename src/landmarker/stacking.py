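"""Landmark stacking and the time-interaction design matrix.

The landmark supermodel is fitted to one *stacked* dataset: for each
landmark ``s`` in the grid, every subject still event-free at ``s``
contributes a counting-process row with entry ``s``, exit
``min(T_i, s+w)`` (administrative censoring at the window end), the
status observed within the window, and covariates carried forward to
``s``. Landmark-time effects enter through basis expansions: covariate
effects beta(s) (default ``{1, s}`` — a main plus linear time-dependent
effect) and a landmark main effect alpha(s) (default ``{s-s0, (s-s0)^2}``,
vanishing at the first landmark so the baseline hazard absorbs the level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, LandmarkGrid

__all__ = ["TDSpec", "StackedDataset", "build_stack", "expand_design", "RESERVED_COLUMNS"]

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("id", "LM", "entry", "exit", "status")

BasisFn = tuple[str, Callable[[np.ndarray], np.ndarray]]


def _poly(name: str, degree: int, shift: float = 0.0) -> BasisFn:
    if degree == 0:
        return (name, lambda s: np.ones_like(np.asarray(s, dtype=float)))
    return (name, lambda s: (np.asarray(s, dtype=float) - shift) ** degree)


_BETA_PRESETS = {
    "const": [0],
    "constant": [0],
    "linear": [0, 1],
    "quadratic": [0, 1, 2],
}
_ALPHA_PRESETS = {
    "none": [],
    "linear": [1],
    "quadratic": [1, 2],
}


@dataclass(frozen=True)
class TDSpec:
    """Basis functions for landmark-time interactions.

    ``beta_basis`` multiplies every covariate (it must contain the
    constant function so main effects are identified); ``alpha_basis``
    enters additively and must vanish at the first landmark ``s0`` so
    that the baseline hazard absorbs the level at ``s0``.
    """

    beta_basis: tuple[BasisFn, ...] = field(default=None)  # type: ignore[assignment]
    alpha_basis: tuple[BasisFn, ...] = field(default=None)  # type: ignore[assignment]
    s0: float = 0.0

    def __post_init__(self) -> None:
        beta = self.beta_basis
        alpha = self.alpha_basis
        if beta is None:
            beta = self._from_preset("linear", kind="beta")
        if alpha is None:
            alpha = self._from_preset("quadratic", kind="alpha")
        object.__setattr__(self, "beta_basis", tuple(beta))
        object.__setattr__(self, "alpha_basis", tuple(alpha))
        if not any(
            np.allclose(fn(np.array([0.0, 1.0, 7.5])), 1.0)
            for _, fn in self.beta_basis
        ):
            raise ValueError("beta_basis must contain the constant function")
        for name, fn in self.alpha_basis:
            if abs(float(fn(np.array([self.s0]))[0])) > 1e-12:
                raise ValueError(
                    f"alpha basis function {name!r} does not vanish at s0={self.s0}"
                )

    def _from_preset(self, preset: str, kind: str) -> list[BasisFn]:
        degrees = (_BETA_PRESETS if kind == "beta" else _ALPHA_PRESETS)[preset]
        shift = self.s0 if kind == "alpha" else 0.0
        out = []
        for d in degrees:
            if d == 0:
                out.append(_poly("1", 0))
            else:
                base = "s" if shift == 0 else f"(s-{shift:g})"
                name = base if d == 1 else f"{base}^{d}"
                out.append(_poly(name, d, shift))
        return out

    @classmethod
    def from_names(cls, beta: str = "linear", alpha: str = "quadratic", s0: float = 0.0) -> "TDSpec":
        """Build a spec from preset names.

        beta: 'const' | 'linear' | 'quadratic'; alpha: 'none' | 'linear' |
        'quadratic' (alpha presets omit the constant and are shifted by s0).
        """
        if beta not in _BETA_PRESETS:
            raise ValueError(f"unknown beta basis preset {beta!r}")
        if alpha not in _ALPHA_PRESETS:
            raise ValueError(f"unknown alpha basis preset {alpha!r}")
        dummy = cls(beta_basis=(_poly("1", 0),), alpha_basis=(), s0=s0)
        return cls(
            beta_basis=tuple(dummy._from_preset(beta, "beta")),
            alpha_basis=tuple(dummy._from_preset(alpha, "alpha")),
            s0=s0,
        )


@dataclass
class StackedDataset:
    """The supermodel's extended dataset.

    ``data`` has the reserved columns ``id, LM, entry, exit, status``
    followed by covariate columns; one row per (subject, landmark) pair
    for subjects event-free at the landmark, with ``entry = s``,
    ``exit = min(T_i, s+w)`` and administrative censoring at ``s+w``.
    """

    data: pd.DataFrame
    grid: LandmarkGrid
    covariate_names: list[str]
    n_causes: int = 1

    def __len__(self) -> int:
        return len(self.data)

    def rows_at(self, s: float) -> pd.DataFrame:
        return self.data[self.data["LM"] == s]


def build_stack(cohort: Cohort, grid: LandmarkGrid) -> StackedDataset:
    """Stack a cohort over a landmark grid.

    For each landmark ``s`` and each subject with event time strictly
    greater than ``s``, emit one row ``(id, LM=s, entry=s,
    exit=min(T, s+w), status = eta if T <= s+w else 0)`` with covariates
    carried forward to ``s``. Subjects with ``T == s`` are not at risk at
    ``s``. An empty risk set at some landmark is logged and the landmark
    retained with zero rows.
    """
    if len(cohort) == 0:
        raise CohortError("cannot stack an empty cohort")
    out = cohort.outcomes
    meas = cohort.measurements
    ids = out[Cohort.ID].to_numpy()
    T = out[Cohort.TIME].to_numpy(dtype=float)
    eta = out[Cohort.STATUS].to_numpy()
    w = grid.window

    frames = []
    for s in grid.landmarks:
        at_risk = T > s
        if not at_risk.any():
            logger.warning("empty risk set at landmark s=%g; retained with zero rows", s)
            continue
        sub_ids = ids[at_risk]
        exit_t = np.minimum(T[at_risk], s + w)
        status = np.where(T[at_risk] <= s + w, eta[at_risk], 0)
        frame = pd.DataFrame(
            {
                "id": sub_ids,
                "LM": s,
                "entry": float(s),
                "exit": exit_t,
                "status": status.astype(int),
            }
        )
        # LOCF merge: latest measurement with obs_time <= s per subject
        eligible = meas[meas[Cohort.OBS_TIME] <= s]
        if eligible.empty:
            raise CohortError(
                f"no covariate measurement at or before landmark s={s} for any subject"
            )
        latest = eligible.groupby(Cohort.ID, sort=False).tail(1)
        cov = frame[["id"]].merge(
            latest.drop(columns=[Cohort.OBS_TIME]),
            left_on="id",
            right_on=Cohort.ID,
            how="left",
        )
        if Cohort.ID != "id":
            cov = cov.drop(columns=[Cohort.ID])
        missing = cov[cohort.covariate_names].isna().any(axis=1)
        if missing.any():
            sid = cov.loc[missing, "id"].iloc[0]
            raise CohortError(
                f"subject {sid!r}: no covariate measurement at or before s={s}"
            )
        frame = pd.concat(
            [frame.reset_index(drop=True), cov[cohort.covariate_names].reset_index(drop=True)],
            axis=1,
        )
        frames.append(frame)

    if not frames:
        data = pd.DataFrame(columns=list(RESERVED_COLUMNS) + cohort.covariate_names)
    else:
        data = pd.concat(frames, ignore_index=True)
    return StackedDataset(
        data=data,
        grid=grid,
        covariate_names=list(cohort.covariate_names),
        n_causes=cohort.n_causes,
    )


def expand_design(stack: StackedDataset, spec: TDSpec) -> tuple[pd.DataFrame, list[dict]]:
    """Expand the stacked covariates into the time-interaction design.

    Returns ``(design, column_map)``: per-row columns ``f_m(s) * Z_k`` for
    every beta-basis function and covariate, followed by the alpha-basis
    columns ``g_q(s)``. The column map records, per design column, the
    source covariate (or None for alpha columns) and the basis-function
    name, so fitted coefficients can be reported as main vs
    time-dependent effects.
    """
    if len(stack) == 0:
        raise CohortError("cannot expand an empty stacked dataset")
    s = stack.data["LM"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    cmap: list[dict] = []
    for bname, bfn in spec.beta_basis:
        fs = np.asarray(bfn(s), dtype=float)
        if not np.isfinite(fs).all():
            bad = s[~np.isfinite(fs)][0]
            raise ValueError(
                f"beta basis {bname!r} non-finite at landmark s={bad}"
            )
        for cov in stack.covariate_names:
            z = stack.data[cov].to_numpy(dtype=float)
            name = cov if bname == "1" else f"{cov}:{bname}"
            cols[name] = z if bname == "1" else z * fs
            cmap.append({"column": name, "covariate": cov, "basis": bname, "kind": "beta"})
    for gname, gfn in spec.alpha_basis:
        gs = np.asarray(gfn(s), dtype=float)
        if not np.isfinite(gs).all():
            bad = s[~np.isfinite(gs)][0]
            raise ValueError(
                f"alpha basis {gname!r} non-finite at landmark s={bad}"
            )
        name = f"LM:{gname}"
        cols[name] = gs
        cmap.append({"column": name, "covariate": None, "basis": gname, "kind": "alpha"})
    return pd.DataFrame(cols, index=stack.data.index), cmap
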