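"""Longitudinal cohort containers for landmark analysis.

A cohort couples one time-to-event outcome per subject with a sequence of
time-stamped covariate measurements. Outcomes use the status convention
``0`` = censored and ``1..J`` = competing causes of failure. Covariate
values are carried forward (LOCF) to each landmark time: the value used at
prediction-origin ``s`` is the most recent measurement taken at or before
``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "Cohort",
    "LandmarkGrid",
    "locf_covariates",
    "CohortError",
]


class CohortError(ValueError):
    """Raised when cohort data violate a structural invariant."""


@dataclass(frozen=True)
class Subject:
    """One subject: outcome plus time-stamped covariate measurements.

    Parameters
    ----------
    id : hashable
        Unique subject identifier.
    event_time : float
        Observed time-to-event or censoring time (nonnegative).
    status : int
        0 for censored, ``1..J`` for the cause of failure.
    measurements : sequence of (time, dict)
        Covariate records ordered by strictly increasing time; all
        measurement times must be <= ``event_time``.
    """

    id: object
    event_time: float
    status: int
    measurements: Sequence[tuple[float, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_time < 0:
            raise CohortError(f"subject {self.id!r}: negative event time")
        if self.status < 0:
            raise CohortError(f"subject {self.id!r}: negative status code")
        times = [t for t, _ in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CohortError(
                f"subject {self.id!r}: measurement times not strictly increasing"
            )
        if times and times[-1] > self.event_time:
            raise CohortError(
                f"subject {self.id!r}: measurement after event time"
            )


def locf_covariates(subject: Subject, s: float) -> dict:
    """Covariates of `subject` carried forward to time ``s``.

    Returns the covariate dict of the latest measurement taken at or
    before ``s`` (boundary inclusive). Raises :class:`CohortError` if the
    subject has no measurement at or before ``s``.
    """
    best = None
    for t, cov in subject.measurements:
        if t <= s:
            best = cov
        else:
            break
    if best is None:
        raise CohortError(
            f"subject {subject.id!r}: no covariate measurement at or before s={s}"
        )
    return best


@dataclass(frozen=True)
class LandmarkGrid:
    """Ordered landmark times and a prediction window.

    ``landmarks`` must be strictly increasing with the first landmark >= 0;
    ``window`` is the horizon w of the dynamic risk, i.e. the probability
    of the event in ``(s, s+w]`` is predicted from each landmark ``s``.
    Landmarks and window must share the time unit of the input data.
    """

    landmarks: tuple[float, ...]
    window: float

    def __post_init__(self) -> None:
        lms = tuple(float(s) for s in self.landmarks)
        object.__setattr__(self, "landmarks", lms)
        if len(lms) == 0:
            raise CohortError("landmark grid is empty")
        if lms[0] < 0:
            raise CohortError("first landmark must be nonnegative")
        if any(b <= a for a, b in zip(lms, lms[1:])):
            raise CohortError("landmarks must be strictly increasing")
        if not self.window > 0:
            raise CohortError("prediction window must be positive")

    @property
    def s0(self) -> float:
        return self.landmarks[0]

    @property
    def horizon(self) -> float:
        """Administrative end of follow-up used by the supermodel: s_L + w."""
        return self.landmarks[-1] + self.window


class Cohort:
    """A longitudinal cohort held as two aligned tables.

    Parameters
    ----------
    outcomes : DataFrame
        Columns ``id, time, status`` — one row per subject.
    measurements : DataFrame
        Columns ``id, obs_time, <covariate columns...>`` — one row per
        covariate record.
    n_causes : int, optional
        Number of competing causes J; inferred as ``max(status)`` (at
        least 1) when omitted.
    """

    ID, TIME, STATUS, OBS_TIME = "id", "time", "status", "obs_time"

    def __init__(
        self,
        outcomes: pd.DataFrame,
        measurements: pd.DataFrame,
        n_causes: int | None = None,
        validate: bool = True,
    ) -> None:
        self.outcomes = outcomes.reset_index(drop=True)
        self.measurements = measurements.sort_values(
            [self.ID, self.OBS_TIME], kind="stable"
        ).reset_index(drop=True)
        self.covariate_names = [
            c for c in measurements.columns if c not in (self.ID, self.OBS_TIME)
        ]
        status = self.outcomes[self.STATUS].to_numpy()
        inferred = int(status.max()) if len(status) else 0
        self.n_causes = int(n_causes) if n_causes is not None else max(inferred, 1)
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_subjects(cls, subjects: Sequence[Subject], n_causes: int | None = None) -> "Cohort":
        out_rows, meas_rows = [], []
        for sub in subjects:
            out_rows.append({cls.ID: sub.id, cls.TIME: sub.event_time, cls.STATUS: sub.status})
            for t, cov in sub.measurements:
                meas_rows.append({cls.ID: sub.id, cls.OBS_TIME: t, **cov})
        return cls(pd.DataFrame(out_rows), pd.DataFrame(meas_rows), n_causes=n_causes)

    @property
    def subjects(self) -> list[Subject]:
        groups = {k: g for k, g in self.measurements.groupby(self.ID, sort=False)}
        subs = []
        for row in self.outcomes.itertuples(index=False):
            sid = getattr(row, self.ID)
            g = groups.get(sid)
            meas = []
            if g is not None:
                for m in g.itertuples(index=False):
                    cov = {c: getattr(m, c) for c in self.covariate_names}
                    meas.append((getattr(m, self.OBS_TIME), cov))
            subs.append(
                Subject(
                    id=sid,
                    event_time=getattr(row, self.TIME),
                    status=int(getattr(row, self.STATUS)),
                    measurements=meas,
                )
            )
        return subs

    def __len__(self) -> int:
        return len(self.outcomes)

    # -- validation -----------------------------------------------------------

    def _validate(self) -> None:
        out, meas = self.outcomes, self.measurements
        for col in (self.ID, self.TIME, self.STATUS):
            if col not in out.columns:
                raise CohortError(f"outcomes table missing column {col!r}")
        if self.ID not in meas.columns or self.OBS_TIME not in meas.columns:
            raise CohortError("measurements table missing 'id' or 'obs_time'")
        if out[self.ID].duplicated().any():
            dup = out.loc[out[self.ID].duplicated(), self.ID].iloc[0]
            raise CohortError(f"duplicate subject id {dup!r} in outcomes")
        if (out[self.TIME].to_numpy() < 0).any():
            raise CohortError("negative event/censoring times in outcomes")
        status = out[self.STATUS].to_numpy()
        if ((status < 0) | (status > self.n_causes)).any():
            bad = status[(status < 0) | (status > self.n_causes)][0]
            raise CohortError(
                f"unknown status code {bad}: expected 0..{self.n_causes}"
            )
        # measurement ids must exist, times strictly increasing per subject,
        # and no record may postdate the subject's event/censoring time
        known = set(out[self.ID])
        unknown = set(meas[self.ID]) - known
        if unknown:
            raise CohortError(f"measurement rows for unknown subject id {next(iter(unknown))!r}")
        t = meas[self.OBS_TIME].to_numpy()
        same = meas[self.ID].to_numpy()
        if len(meas) > 1:
            nondecr = (np.diff(t) <= 0) & (same[1:] == same[:-1])
            if nondecr.any():
                sid = same[1:][nondecr][0]
                raise CohortError(
                    f"subject {sid!r}: measurement times not strictly increasing"
                )
        merged = meas[[self.ID, self.OBS_TIME]].merge(
            out[[self.ID, self.TIME]], on=self.ID, how="left"
        )
        late = merged[self.OBS_TIME].to_numpy() > merged[self.TIME].to_numpy()
        if late.any():
            sid = merged[self.ID].to_numpy()[late][0]
            raise CohortError(f"subject {sid!r}: measurement after event time")
        # every subject needs a baseline record at or before time 0 only if it
        # is ever used; the landmark stack enforces availability at each s.
        missing = known - set(meas[self.ID])
        if missing:
            raise CohortError(
                f"subject {next(iter(missing))!r} has no covariate measurements"
            )
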