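"""Feature reproducibility: two-way ANOVA ICC, reproducibility bins, and
rank-sum comparison between segmentation arms.

A measurement table holds one feature's values for n subjects (rows) by k
repeated measurements — raters, sessions, or rater-session combinations —
(columns), with no missing cells.  From its two-way ANOVA mean squares the
single-measurement intraclass correlation coefficients are

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))
    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)

(McGraw & Wong two-way model, single measurement): absolute agreement
penalizes systematic column offsets through MS_C, consistency does not, so
ICC(C,1) >= ICC(A,1) for every table.  ICC values are binned into the
reproducibility groups Poor (< 0.4), Fair [0.4, 0.6), Good [0.6, 0.75),
Excellent [0.75, 1]; the interior cut points are half-open so every value
lands in exactly one group.

A published variant of these formulas that replaces (k-1) MS_E by
(k+1) MS_E in the agreement denominator and uses MS_W and (k-1) MS_R in the
consistency form circulates in the applied literature; it is reproducible
here via ``printed_formula=True`` for auditability but is not a recognized
estimator (it breaks the identical-columns -> 1 sanity case) and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("Poor", "Fair", "Good", "Excellent")
_EDGES = (0.4, 0.6, 0.75)


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError(f"measurement table must be 2-D, got shape {t.shape}")
    n, k = t.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 measurements, got {n}x{k}")
    if not np.isfinite(t).all():
        raise ValueError("measurement table has missing or non-finite cells")
    return t


@dataclass(frozen=True)
class MeanSquares:
    """Two-way ANOVA mean squares of a complete n x k table."""

    ms_rows: float      # between-subject
    ms_cols: float      # between-rater/session
    ms_error: float     # interaction / residual
    ms_within: float    # within-subject (columns + error pooled)
    n: int
    k: int


@dataclass(frozen=True)
class ICCResult:
    model: str          # "A1" or "C1"
    value: float
    group: str
    degenerate: bool = False  # all cells identical; value defined as 1


def anova_mean_squares(table) -> MeanSquares:
    """Mean squares of the two-way (subjects x raters) ANOVA decomposition."""
    t = _as_table(table)
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    # interaction residuals computed directly (not by subtraction) so that
    # tables with identical columns give ss_error = 0 exactly
    resid = t - row_means[:, None] - col_means[None, :] + grand
    ss_error = (resid**2).sum()
    ss_within = ((t - row_means[:, None]) ** 2).sum()
    return MeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        ms_within=ss_within / (n * (k - 1)),
        n=n,
        k=k,
    )


def categorize_icc(value: float) -> str:
    """Reproducibility group of an ICC value (Poor/Fair/Good/Excellent)."""
    if value > 1.0 + 1e-12:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    for name, edge in zip(GROUPS, _EDGES):
        if value < edge:
            return name
    return GROUPS[-1]


def _icc(table, model: str, printed_formula: bool) -> ICCResult:
    t = _as_table(table)
    n, k = t.shape
    if np.ptp(t) == 0:
        # deterministic re-extraction: zero variance everywhere is the
        # perfect-reproducibility case, defined as ICC = 1
        return ICCResult(model, 1.0, categorize_icc(1.0), degenerate=True)
    if not printed_formula and (t == t[:, :1]).all():
        # identical repeated measurements with real between-subject variance:
        # MS_C = MS_E = 0, both estimators equal 1 exactly
        return ICCResult(model, 1.0, categorize_icc(1.0))
    ms = anova_mean_squares(t)
    if model == "A1":
        if printed_formula:
            den = ms.ms_rows + (k + 1) * ms.ms_error + (k / n) * (ms.ms_cols - ms.ms_error)
        else:
            den = ms.ms_rows + (k - 1) * ms.ms_error + (k / n) * (ms.ms_cols - ms.ms_error)
        num = ms.ms_rows - ms.ms_error
    elif model == "C1":
        if printed_formula:
            num = ms.ms_rows - ms.ms_within
            den = ms.ms_rows + (k - 1) * ms.ms_rows
        else:
            num = ms.ms_rows - ms.ms_error
            den = ms.ms_rows + (k - 1) * ms.ms_error
    else:
        raise ValueError(f"unknown ICC model {model!r}; use 'A1' or 'C1'")
    if den == 0:
        raise ZeroDivisionError("zero ICC denominator on a non-constant table")
    value = num / den
    return ICCResult(model, float(value), categorize_icc(min(value, 1.0)))


def icc_agreement(table, printed_formula: bool = False) -> ICCResult:
    """Single-measurement absolute-agreement ICC(A,1)."""
    return _icc(table, "A1", printed_formula)


def icc_consistency(table, printed_formula: bool = False) -> ICCResult:
    """Single-measurement consistency ICC(C,1)."""
    return _icc(table, "C1", printed_formula)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    Returns (W, p) where W is the rank sum of ``x`` in the pooled sample.
    For n_x + n_y <= 12 the p-value is exact by enumeration of all rank
    assignments (midranks make this valid under ties); otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, ny = x.size, y.size
    total = nx + ny
    w = float(ranks[:nx].sum())
    mu = nx * (total + 1) / 2.0

    if total <= 12:
        obs = abs(w - mu)
        hits = sum(
            abs(sum(ranks[list(idx)]) - mu) >= obs - 1e-9
            for idx in combinations(range(total), nx)
        )
        p = hits / comb(total, nx)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return w, float(min(p, 1.0))


@dataclass(frozen=True)
class StabilityReport:
    """Per-feature ICCs per arm plus Table-style reproducibility summaries."""

    model: str
    per_feature: pd.DataFrame     # index: feature, columns: arms, ICC values
    group_counts: pd.DataFrame    # index: Poor..Excellent, columns: arms
    group_percent: pd.DataFrame   # same shape, percentages
    summary: pd.DataFrame         # per arm: mean, sd (population) of ICC
    pairwise_wilcoxon: pd.DataFrame  # arms x arms, two-sided rank-sum p
    degenerate: pd.DataFrame      # bool, per feature x arm


def stability_report(
    arm_tables: dict[str, dict[str, np.ndarray]],
    model: str = "A1",
    printed_formula: bool = False,
) -> StabilityReport:
    """Reproducibility report across segmentation arms.

    ``arm_tables`` maps arm name -> {feature name -> n x k measurement
    table}; every arm must cover the same feature registry.  The report
    gives per-feature ICCs, per-arm group counts/percentages (the counts of
    each arm partition the registry), per-arm mean +/- population SD of the
    ICC, and pairwise two-sided rank-sum p-values between the arms'
    per-feature ICC distributions.
    """
    if not arm_tables:
        raise ValueError("need at least one arm")
    arms = list(arm_tables)
    registry = list(arm_tables[arms[0]])
    for arm in arms[1:]:
        missing = set(registry) ^ set(arm_tables[arm])
        if missing:
            raise ValueError(
                f"feature registry mismatch in arm {arm!r}: {sorted(missing)}"
            )

    values = pd.DataFrame(index=registry, columns=arms, dtype=float)
    degen = pd.DataFrame(False, index=registry, columns=arms)
    for arm in arms:
        for feat in registry:
            res = _icc(arm_tables[arm][feat], model, printed_formula)
            values.loc[feat, arm] = res.value
            degen.loc[feat, arm] = res.degenerate

    counts = pd.DataFrame(0, index=list(GROUPS), columns=arms)
    for arm in arms:
        for feat in registry:
            counts.loc[categorize_icc(min(values.loc[feat, arm], 1.0)), arm] += 1
    percent = counts / len(registry) * 100.0

    summary = pd.DataFrame(
        {"mean": values.mean(axis=0), "sd": values.std(axis=0, ddof=0)}
    )

    pw = pd.DataFrame(np.nan, index=arms, columns=arms)
    for a, b in combinations(arms, 2):
        _, p = wilcoxon_rank_sum(values[a].to_numpy(), values[b].to_numpy())
        pw.loc[a, b] = pw.loc[b, a] = p

    return StabilityReport(
        model=model,
        per_feature=values,
        group_counts=counts,
        group_percent=percent,
        summary=summary,
        pairwise_wilcoxon=pw,
        degenerate=degen,
    )
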