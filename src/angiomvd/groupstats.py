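"""Per-group MVD summaries and two-sample comparison.

The planned comparison between groups of per-VOI MVD values is a two-sample
t-test, two-sided. The default variant is the classic pooled-variance
Student's t (df = nₐ + n_b − 2); Welch's variant (Satterthwaite df) is
available and preferable when group variances differ. Reports carry an
explicit unit-of-analysis label because pooling VOIs across animals versus
per-animal averaging changes what n means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["GroupComparison", "summarize_group", "t_test_two_sample"]


@dataclass
class GroupComparison:
    group_a: list[float]
    group_b: list[float]
    label_a: str
    label_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    unit_of_analysis: str = "VOI"
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_a": len(self.group_a),
            "n_b": len(self.group_b),
            "summary_a": self.summary_a,
            "summary_b": self.summary_b,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "variant": self.variant,
            "sidedness": "two-sided",
            "unit_of_analysis": self.unit_of_analysis,
        }


def summarize_group(values) -> dict:
    """Sample mean, min, max and (n−1) standard deviation of a group.

    A single value has no dispersion; ``sd`` is then reported as NaN
    (not-applicable) rather than zero.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("summarize_group needs at least one value")
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
    }


def t_test_two_sample(
    a,
    b,
    variant: str = "pooled",
    label_a: str = "group_a",
    label_b: str = "group_b",
    unit_of_analysis: str = "VOI",
) -> GroupComparison:
    """Two-sided two-sample t-test between groups of scalars.

    ``variant="pooled"`` is the classic Student's t with pooled variance and
    df = nₐ + n_b − 2; it errors on zero pooled variance (use ``welch``).
    ``variant="welch"`` does not assume equal variances (Satterthwaite df).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    if variant == "pooled":
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        na, nb = len(a), len(b)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0:
            raise DegenerateInputError(
                "pooled variance is zero; the pooled t is undefined — "
                "consider variant='welch' or check the data"
            )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupComparison(
        group_a=a,
        group_b=b,
        label_a=label_a,
        label_b=label_b,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
        unit_of_analysis=unit_of_analysis,
        summary_a=summarize_group(a),
        summary_b=summarize_group(b),
    )
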