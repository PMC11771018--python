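"""Delimited-text I/O and run configuration.

All tabular files are UTF-8 CSV with a header row and ``.`` decimal.
Outcomes: ``id, time, status`` (status 0 = censored, 1..J = causes).
Measurements: ``id, obs_time, <covariate columns>``. Stacked datasets
use the reserved columns ``id, LM, entry, exit, status``. Model files
are JSON; run configuration is YAML and round-trips unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortError, LandmarkGrid
from .metrics import ComparisonResult, MetricCurve, SummaryMetric
from .stacking import RESERVED_COLUMNS, StackedDataset

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_stack",
    "write_stack",
    "report_frame",
    "write_report",
    "RunConfig",
]

REPORT_COLUMNS = ["model", "metric", "landmark", "estimate", "se", "lo", "hi", "p_value"]


def read_cohort(outcomes_path, measurements_path, n_causes: int | None = None) -> Cohort:
    """Read and validate a cohort from two CSV files.

    Errors name the offending file and the violated invariant (duplicate
    id, non-increasing measurement times, measurement after event time,
    unknown status code).
    """
    out = pd.read_csv(outcomes_path)
    meas = pd.read_csv(measurements_path)
    try:
        return Cohort(out, meas, n_causes=n_causes)
    except CohortError as exc:
        raise CohortError(
            f"invalid cohort ({outcomes_path} / {measurements_path}): {exc}"
        ) from exc


def write_cohort(cohort: Cohort, outcomes_path, measurements_path) -> None:
    cohort.outcomes.to_csv(outcomes_path, index=False)
    cohort.measurements.to_csv(measurements_path, index=False)


def write_stack(stack: StackedDataset, path) -> None:
    stack.data.to_csv(path, index=False)


def read_stack(path, landmarks=None, window=None, n_causes: int = 1) -> StackedDataset:
    data = pd.read_csv(path)
    missing = [c for c in RESERVED_COLUMNS if c not in data.columns]
    if missing:
        raise CohortError(f"{path}: stacked file missing reserved columns {missing}")
    lms = tuple(sorted(data["LM"].unique())) if landmarks is None else tuple(landmarks)
    if window is None:
        window = float((data["exit"] - data["entry"]).max())
    covs = [c for c in data.columns if c not in RESERVED_COLUMNS]
    return StackedDataset(data=data, grid=LandmarkGrid(lms, float(window)),
                          covariate_names=covs, n_causes=n_causes)


def report_frame(
    metric_results: list[tuple[str, MetricCurve, SummaryMetric]],
    comparison_results: list[tuple[str, str, ComparisonResult]] | None = None,
) -> pd.DataFrame:
    """Tidy report: per-landmark rows plus one summary row per (model, metric).

    Comparison rows use ``model = "<A> vs <B>"`` with the difference, its
    standard error, and the two-sided p-value.
    """
    from scipy import stats

    rows = []
    for model, curve, summ in metric_results:
        z = stats.norm.ppf(0.5 + summ.level / 2.0)
        ses = curve.landmark_se()
        for li, s in enumerate(curve.landmarks):
            est = curve.estimates[li]
            rows.append({
                "model": model, "metric": curve.kind, "landmark": s,
                "estimate": est, "se": ses[li],
                "lo": max(0.0, est - z * ses[li]), "hi": min(1.0, est + z * ses[li]),
                "p_value": np.nan,
            })
        rows.append({
            "model": model, "metric": curve.kind, "landmark": "summary",
            "estimate": summ.value, "se": summ.se, "lo": summ.lo, "hi": summ.hi,
            "p_value": np.nan,
        })
    for name_a, name_b, comp in comparison_results or []:
        rows.append({
            "model": f"{name_a} vs {name_b}", "metric": "", "landmark": "summary",
            "estimate": comp.delta, "se": comp.se, "lo": np.nan, "hi": np.nan,
            "p_value": comp.p_value,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(metric_results, comparison_results, path) -> None:
    report_frame(metric_results, comparison_results).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    outcomes: str = ""
    measurements: str = ""
    landmarks: list = field(default_factory=list)
    window: float = 5.0
    beta_basis: str = "linear"
    alpha_basis: str = "quadratic"
    penalty: str = "ridge"
    lam: float | str = 0.0
    l1_ratio: float = 0.0
    metrics: list = field(default_factory=lambda: ["auc", "bs"])
    level: float = 0.95
    seed: int = 0
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
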