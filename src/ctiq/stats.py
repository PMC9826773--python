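"""Contrast arithmetic, replicate aggregation, percent differences and the
paired Wilcoxon signed-rank test.

The percent-difference convention throughout: ``percent_difference(a, b)``
is the signed change from reference ``a`` to comparator ``b``,
``100 * (b - a) / a``; in comparison tables the first-named condition
(e.g. V1, or mild) is the reference/denominator.

The Wilcoxon signed-rank test is implemented by direct enumeration of the
2^n sign patterns for small samples (n <= 15 after zero handling), which
stays exact in the presence of tied ranks; zero differences are handled by
the Pratt method (ranked, then dropped).  Larger samples fall back to the
normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "iodine_contrast",
    "percent_difference",
    "aggregate_mean_sd",
    "wilcoxon_paired",
    "ComparisonSpec",
    "ComparisonRow",
    "build_comparison_table",
]

EXACT_ENUMERATION_LIMIT = 15


def iodine_contrast(hu_iodine: float, hu_solid_water: float) -> float:
    """Iodine contrast: mean HU in the iodine insert minus solid water."""
    return float(hu_iodine) - float(hu_solid_water)


def percent_difference(a: float, b: float) -> float:
    """Signed percent change from reference ``a`` to comparator ``b``."""
    if a == 0:
        raise ZeroDivisionError("percent difference undefined for zero reference")
    return 100.0 * (b - a) / a


def aggregate_mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    A single value has SD 0 by convention (documented, not NaN) so that
    replicate tables with one replicate stay usable.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def _signed_rank_stat(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Pratt handling: rank |d| including zeros, drop zeros, return
    (W+ statistic, retained ranks)."""
    ranks = rankdata(np.abs(diffs))
    nonzero = diffs != 0
    w_plus = float(ranks[(diffs > 0)].sum())
    return w_plus, ranks[nonzero]


def wilcoxon_paired(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact by enumeration of sign patterns for small samples, normal
    approximation with tie correction otherwise.  All-zero differences
    return p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D samples with n >= 2")
    diffs = x - y
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    w_plus, ranks = _signed_rank_stat(diffs)
    n = ranks.size
    if n <= EXACT_ENUMERATION_LIMIT:
        total = 0
        at_least = 0
        at_most = 0
        for pattern in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(pattern, ranks))
            total += 1
            if w >= w_plus - 1e-9:
                at_least += 1
            if w <= w_plus + 1e-9:
                at_most += 1
        p = 2.0 * min(at_least, at_most) / total
        return min(p, 1.0)
    # Normal approximation with tie correction (Pratt zeros already dropped).
    mean_w = ranks.sum() / 2.0
    var_w = ranks @ ranks / 4.0  # sum r_i^2 / 4 absorbs tie correction
    z = (w_plus - mean_w) / np.sqrt(var_w)
    return float(2.0 * norm.sf(abs(z)))


@dataclass(frozen=True)
class ComparisonSpec:
    """One planned comparison over a measurement table.

    metric
        Which metric rows to use.
    pair_column / reference / comparator
        The column whose two values are compared, e.g.
        ``("version", "V1", "V2")`` or ``("level", "mild", "standard")``.
    fixed
        Equality filters applied first, e.g. ``{"level": "standard"}``.
    match_columns
        Key columns that pair observations between the two sides
        (e.g. ``("keV",)`` to pair per energy level).
    label
        Free-text description for the report.
    """

    metric: str
    pair_column: str
    reference: object
    comparator: object
    fixed: tuple = ()
    match_columns: tuple = ("keV",)
    label: str = ""


@dataclass
class ComparisonRow:
    metric: str
    label: str
    grouping: str
    contrast_pair: str
    n_pairs: int
    percent_diff_mean: float
    percent_diff_sd: float
    p_value: float | None


def build_comparison_table(
    records: pd.DataFrame, plan: list[ComparisonSpec]
) -> tuple[list[ComparisonRow], list[str]]:
    """Evaluate a comparison plan over a MeasurementRecord table.

    ``records`` needs columns ``metric``, ``value``, the pair column and
    every match/fixed column.  Replicates (or any residual columns not used
    for matching) are averaged within each matched key first.  Returns the
    comparison rows and a gap report naming comparisons whose sides were
    missing.
    """
    rows: list[ComparisonRow] = []
    gaps: list[str] = []
    for spec in plan:
        sub = records[records["metric"] == spec.metric]
        for col, val in spec.fixed:
            sub = sub[sub[col] == val]
        ref = sub[sub[spec.pair_column] == spec.reference]
        cmpr = sub[sub[spec.pair_column] == spec.comparator]
        if ref.empty or cmpr.empty:
            gaps.append(
                f"{spec.metric}: {spec.pair_column} {spec.reference} vs "
                f"{spec.comparator} with {dict(spec.fixed)} — side(s) missing"
            )
            continue
        keys = list(spec.match_columns)
        ref_m = ref.groupby(keys)["value"].mean()
        cmp_m = cmpr.groupby(keys)["value"].mean()
        joined = pd.concat([ref_m, cmp_m], axis=1, keys=["a", "b"]).dropna()
        if joined.empty:
            gaps.append(
                f"{spec.metric}: {spec.pair_column} {spec.reference} vs "
                f"{spec.comparator} with {dict(spec.fixed)} — no matched keys"
            )
            continue
        pd_vals = [percent_difference(a, b) for a, b in zip(joined["a"], joined["b"])]
        mean, sd = aggregate_mean_sd(pd_vals)
        p = (
            wilcoxon_paired(joined["a"].to_numpy(), joined["b"].to_numpy())
            if len(joined) >= 2
            else None
        )
        rows.append(
            ComparisonRow(
                metric=spec.metric,
                label=spec.label,
                grouping=", ".join(f"{c}={v}" for c, v in spec.fixed) or "all",
                contrast_pair=f"{spec.comparator} vs {spec.reference}",
                n_pairs=len(joined),
                percent_diff_mean=mean,
                percent_diff_sd=sd,
                p_value=p,
            )
        )
    return rows, gaps
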