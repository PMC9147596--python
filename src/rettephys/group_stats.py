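"""Two-sample and paired comparisons and group summaries.

Mirrors the reporting style of per-cell electrophysiology studies: values are
summarised as mean +/- SEM over cells, with the animal of origin carried for
transparency (no mixed-effects modelling).  The unpaired comparison selects
between the pooled-variance and Welch t statistics, either explicitly or
automatically via an F test of variance equality at the 0.05 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import InsufficientDataError


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    method: str  # "pooled_t", "welch_t" or "paired_t"
    degenerate: bool = False


@dataclass
class GroupReport:
    summary: GroupSummary
    n_animals: int
    cells_per_animal: dict = field(default_factory=dict)


def variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p of the F test for equality of two variances."""
    fa = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    p = stats.f.cdf(fa, dfa, dfb)
    return float(2 * min(p, 1 - p))


def unpaired_t(group_a, group_b, equal_var: bool | str = "auto") -> TestResult:
    """Unpaired t test, pooled or Welch.

    ``equal_var`` may be True, False, or ``"auto"`` (Welch when the F test of
    variances rejects equality at 0.05).  Groups with zero variance are
    handled as degenerate: statistic 0 / p 1 when means coincide, otherwise
    an infinite statistic with p 0, both flagged.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        same = math.isclose(a.mean(), b.mean())
        return TestResult(statistic=0.0 if same else math.inf,
                          df=a.size + b.size - 2,
                          p_two_sided=1.0 if same else 0.0,
                          method="pooled_t", degenerate=True)
    if equal_var == "auto":
        equal = variance_f_test(a, b) >= 0.05
    else:
        equal = bool(equal_var)
    res = stats.ttest_ind(a, b, equal_var=equal)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p_two_sided=float(res.pvalue),
                      method="pooled_t" if equal else "welch_t")


def paired_t(pre, post) -> TestResult:
    """Paired t test (t on the within-pair differences)."""
    a = np.asarray(list(pre), dtype=float)
    b = np.asarray(list(post), dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired test needs equal lengths, got {a.size} and {b.size}")
    if a.size < 2:
        raise InsufficientDataError("paired test needs n >= 2 pairs")
    d = b - a
    if np.var(d, ddof=1) == 0:
        same = math.isclose(float(d.mean()), 0.0, abs_tol=1e-300)
        return TestResult(statistic=0.0 if same else math.copysign(math.inf, d.mean()),
                          df=a.size - 1,
                          p_two_sided=1.0 if same else 0.0,
                          method="paired_t", degenerate=True)
    res = stats.ttest_rel(a, b)
    return TestResult(statistic=float(-res.statistic), df=float(a.size - 1),
                      p_two_sided=float(res.pvalue), method="paired_t")


def group_report(per_cell_values, cell_to_animal) -> GroupReport:
    """Mean +/- SEM over cells with nested animal counts.

    ``per_cell_values`` maps cell id to value; every cell must appear in
    ``cell_to_animal`` (unmapped cells raise ``KeyError``).
    """
    items = dict(per_cell_values)
    if not items:
        raise InsufficientDataError("no cells to summarise")
    animals: dict = {}
    for cell in items:
        if cell not in cell_to_animal:
            raise KeyError(f"cell '{cell}' has no animal mapping")
        animals.setdefault(cell_to_animal[cell], []).append(cell)
    values = np.array(list(items.values()), dtype=float)
    n = values.size
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return GroupReport(
        summary=GroupSummary(n=n, mean=float(values.mean()), sem=sem),
        n_animals=len(animals),
        cells_per_animal={a: len(c) for a, c in animals.items()},
    )
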