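"""Two-group statistics, regression, and report assembly.

Only the plumbing statistics used per figure are provided here: classical
Student t tests (pooled variance) and ordinary least squares for the
opening-volume-versus-behavior regression.  Reports bundle every stage
output with the exact configuration and seeds so a rerun reproduces all
numeric fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import __version__

__all__ = ["GroupComparison", "RegressionResult", "two_group_t", "regress", "assemble_report"]


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    percent_decrease: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    paired: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def two_group_t(values_a, values_b, paired: bool = False) -> GroupComparison:
    """Classical Student t test (pooled variance) with two-sided p.

    Percent decrease of A relative to B is 100·(1 − mean_A/mean_B).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if a.size < 2:
            raise ValueError("paired test requires at least 2 pairs")
        t, p = stats.ttest_rel(a, b)
        df = a.size - 1
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 values")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return GroupComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        percent_decrease=100.0 * (1.0 - mean_a / mean_b) if mean_b != 0 else float("nan"),
        t_statistic=float(t),
        degrees_of_freedom=int(df),
        p_value=float(p),
        paired=paired,
    )


def regress(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with the F test for slope ≠ 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must pair up")
    if x.size < 3:
        raise ValueError("at least 3 paired points are required")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
    )


def assemble_report(stage_outputs: dict, config: dict, out_path=None) -> dict:
    """Bundle stage outputs with the exact configuration and software version.

    The report is deterministic for fixed seeds (no timestamps), so reruns
    from the embedded config are byte-identical.
    """
    if not stage_outputs:
        raise ValueError("at least one stage output is required")
    if config is None:
        raise ValueError("the run configuration must be embedded in the report")

    def _clean(obj):
        if hasattr(obj, "to_dict"):
            return _clean(obj.to_dict())
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return [_clean(v) for v in obj.tolist()]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    report = {
        "software": {"name": "sonoquant", "version": __version__},
        "config": _clean(config),
        "results": _clean(stage_outputs),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
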