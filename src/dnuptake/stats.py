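"""Group statistics matching the study's reporting conventions.

Means ± s.d. per group, one-way ANOVA across groups, Tukey's HSD post hoc
(Tukey–Kramer for unbalanced designs, via the studentized range
distribution), and significance tiers: p <= 0.05 '*', p <= 0.01 '**',
p <= 0.001 '***', otherwise 'ns' (boundary values take the stronger tier,
matching the '<=' convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError

__all__ = [
    "GroupTable",
    "AnovaResult",
    "ComparisonResult",
    "significance_tier",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
    "summarize",
]


@dataclass
class GroupTable:
    """Replicate values per labelled group (>= 2 groups, >= 2 values each)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InvalidInputError("need at least 2 groups")
        clean = {}
        for name, values in self.groups.items():
            values = np.asarray(values, dtype=float)
            if values.ndim != 1 or values.size < 2:
                raise InvalidInputError(
                    f"group {name!r} needs >= 2 replicate values"
                )
            if not np.all(np.isfinite(values)):
                raise InvalidInputError(f"group {name!r} has non-finite values")
            clean[str(name)] = values
        self.groups = clean

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_col: str, value_col: str
    ) -> "GroupTable":
        return cls(
            {name: sub[value_col].to_numpy()
             for name, sub in df.groupby(group_col, sort=False)}
        )

    @property
    def names(self) -> list[str]:
        return list(self.groups)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class ComparisonResult:
    """ANOVA F and p plus the pairwise Tukey table with significance tiers."""

    f: float
    p: float
    pairwise: pd.DataFrame


def significance_tier(p: float) -> str:
    """Map a p value to the study's star tiers ('ns' for NaN)."""
    if not np.isfinite(p):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def one_way_anova(table: GroupTable) -> AnovaResult:
    """Between/within mean-square ratio and its F tail probability.

    Degenerate inputs are flagged with a warning: all-constant data give
    F = 0, p = 1; zero within-group variance with differing means gives
    F = inf, p = 0.
    """
    values = list(table.groups.values())
    sizes = np.array([v.size for v in values])
    k, n = len(values), int(sizes.sum())
    grand = np.concatenate(values).mean()
    means = np.array([v.mean() for v in values])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(values, means)))
    df_between, df_within = k - 1, n - k
    scale = max(ss_between, ss_within, 1.0)
    if ss_within / scale < 1e-14:
        if ss_between / scale < 1e-14:
            warnings.warn("all groups constant and equal; F undefined, "
                          "reporting F=0, p=1", stacklevel=2)
            return AnovaResult(0.0, 1.0, df_between, df_within)
        warnings.warn("zero within-group variance with differing means",
                      stacklevel=2)
        return AnovaResult(math.inf, 0.0, df_between, df_within)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(f, p, df_between, df_within)


def tukey_hsd(table: GroupTable) -> pd.DataFrame:
    """All-pairs Tukey HSD p values and significance tiers.

    Columns: ``group_a``, ``group_b``, ``p_value``, ``tier``; one row per
    unordered pair.
    """
    names = table.names
    values = [table.groups[name] for name in names]
    if all(np.ptp(v) == 0 for v in values) and np.ptp(
        np.concatenate(values)
    ) == 0:
        pairs = [
            {"group_a": a, "group_b": b, "p_value": 1.0, "tier": "ns"}
            for i, a in enumerate(names) for b in names[i + 1:]
        ]
        warnings.warn("all groups constant and equal; Tukey p set to 1",
                      stacklevel=2)
        return pd.DataFrame(pairs)
    result = sps.tukey_hsd(*values)
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            p = float(result.pvalue[i, j])
            rows.append(
                {"group_a": a, "group_b": names[j], "p_value": p,
                 "tier": significance_tier(p)}
            )
    return pd.DataFrame(rows)


def compare_groups(table: GroupTable) -> ComparisonResult:
    """One-way ANOVA followed by Tukey HSD post hoc."""
    anova = one_way_anova(table)
    return ComparisonResult(f=anova.f, p=anova.p, pairwise=tukey_hsd(table))


def summarize(table: GroupTable) -> pd.DataFrame:
    """Per-group n, mean, and sample s.d. (ddof=1)."""
    rows = [
        {"group": name, "n": v.size, "mean": float(v.mean()),
         "sd": float(v.std(ddof=1))}
        for name, v in table.groups.items()
    ]
    return pd.DataFrame(rows)
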