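"""Baseline-characteristics table: descriptive statistics and tests.

Continuous baseline variables are compared between arms with the
two-sided Wilcoxon rank-sum test; binary traits with the Pearson
chi-square test WITHOUT continuity correction (the dialect validated
against the published example values).  Display kinds follow clinical
convention: mean (SD), median [IQR], or n (%).
"""

from __future__ import annotations

import dataclasses
import decimal

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CohortDataset

__all__ = ["ContingencyTable2x2", "Table1Variable", "chi_square_p", "wilcoxon_p", "build_table1"]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows = arms, columns = trait present / absent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def chi_square_p(table: ContingencyTable2x2) -> float:
    """Pearson chi-square p-value (df = 1, no continuity correction)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def wilcoxon_p(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    ``auto`` uses exact enumeration when both groups have n ≤ 10 and
    there are no ties, otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([x, y])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class Table1Variable:
    """One row of the baseline table.

    ``kind`` picks both the display and the test: ``count_pct`` →
    chi-square on the 2×2; ``mean_sd`` / ``median_iqr`` → Wilcoxon.
    ``source`` is ``subjects`` (a covariate column) or ``baseline`` (the
    baseline concentration of a metabolite).
    """

    name: str
    kind: str  # mean_sd | median_iqr | count_pct
    source: str = "subjects"

    def __post_init__(self) -> None:
        if self.kind not in ("mean_sd", "median_iqr", "count_pct"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.source not in ("subjects", "baseline"):
            raise ValueError(f"unknown source {self.source!r}")


def _round_half_up(value: float, digits: int = 0) -> float:
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _fmt(values: np.ndarray, kind: str, n_arm: int) -> str:
    values = values[~np.isnan(values)]
    if kind == "mean_sd":
        return f"{np.mean(values):.1f} ({np.std(values, ddof=1):.1f})"
    if kind == "median_iqr":
        lo, med, hi = np.percentile(values, [25, 50, 75])
        return f"{med:.2f} [{lo:.2f}-{hi:.2f}]"
    k = int(np.nansum(values))
    pct = _round_half_up(100.0 * k / n_arm) if n_arm else 0.0
    return f"{k} ({pct:.0f})"


def _variable_values(dataset: CohortDataset, var: Table1Variable) -> np.ndarray | None:
    if var.source == "subjects":
        if var.name not in dataset.subjects.columns:
            return None
        return dataset.subjects[var.name].to_numpy(dtype=float)
    if var.name not in set(dataset.metabolite_ids):
        return None
    return dataset.pivot(var.name)["baseline"].to_numpy(dtype=float)


def build_table1(dataset: CohortDataset, spec: list[Table1Variable]) -> pd.DataFrame:
    """Arm-wise descriptive statistics with between-arm p-values.

    Returns a row per available variable (treated arm first); variables
    absent from the dataset are collected in ``result.attrs["skipped"]``.
    """
    arm = dataset.subjects["arm"].to_numpy()
    rows, skipped = [], []
    for var in spec:
        vals = _variable_values(dataset, var)
        if vals is None:
            skipped.append(var.name)
            continue
        vt, vp = vals[arm == 1], vals[arm == 0]
        if var.kind == "count_pct":
            a = int(np.nansum(vt))
            c = int(np.nansum(vp))
            table = ContingencyTable2x2(a, int((~np.isnan(vt)).sum()) - a,
                                        c, int((~np.isnan(vp)).sum()) - c)
            p, test = chi_square_p(table), "chi-square"
        else:
            p, test = wilcoxon_p(vt[~np.isnan(vt)], vp[~np.isnan(vp)]), "wilcoxon"
        rows.append(
            {
                "variable": var.name,
                "treated": _fmt(vt, var.kind, (arm == 1).sum()),
                "placebo": _fmt(vp, var.kind, (arm == 0).sum()),
                "p_value": round(p, 3),
                "test": test,
            }
        )
    out = pd.DataFrame(rows, columns=["variable", "treated", "placebo", "p_value", "test"])
    out.attrs["skipped"] = skipped
    return out
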