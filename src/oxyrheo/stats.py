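"""Repeated-measures statistics for patient cohorts.

The cohort design is fully paired: each patient contributes one value
(e.g. a flow behavior index) per condition (oxygen tension).  Condition
effects are tested nonparametrically with Friedman's rank test, followed
by pairwise post-hoc comparisons with a Bonferroni correction.  Linearity
between continuous per-patient metrics (e.g. fractional velocity change
vs hemoglobin fractions) is assessed with the Pearson correlation and its
t-transform p-value.

The Friedman statistic uses the tie-corrected form.  For small designs
the p-value is computed exactly by enumerating the within-block rank
permutation distribution (a dynamic program over rank-sum vectors, so the
cost is polynomial rather than (k!)^n); otherwise the chi-squared
asymptotic is used.  The post-hoc default is the exact paired
sign-permutation test, which is distribution-free and exact at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "PairedCohortTable",
    "FriedmanResult",
    "PairwiseComparison",
    "pearson_with_p",
    "friedman_test",
    "pairwise_bonferroni",
]

_EXACT_LIMIT = 1_000_000  # max (k!)^n for automatic exact enumeration


@dataclass(frozen=True)
class PairedCohortTable:
    """Complete patients x conditions block design (no missing cells)."""

    values: np.ndarray  # shape (n_patients, n_conditions)
    condition_labels: Tuple
    patient_ids: Tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (patients x conditions) array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 patients and 2 conditions")
        if not np.all(np.isfinite(v)):
            raise ValueError("table is incomplete or non-finite; Friedman requires complete blocks")
        if len(self.condition_labels) != v.shape[1]:
            raise ValueError("condition label count does not match table width")
        if len(self.patient_ids) != v.shape[0]:
            raise ValueError("patient id count does not match table height")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_arrays(cls, values, condition_labels=None, patient_ids=None) -> "PairedCohortTable":
        v = np.asarray(values, dtype=float)
        if condition_labels is None:
            condition_labels = tuple(range(v.shape[1]))
        if patient_ids is None:
            patient_ids = tuple(range(v.shape[0]))
        return cls(values=v, condition_labels=tuple(condition_labels), patient_ids=tuple(patient_ids))

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        patient_col: str = "patient",
        condition_col: str = "condition",
        value_col: str = "value",
    ) -> "PairedCohortTable":
        """Pivot a long-format (patient, condition, value) frame into a complete table."""
        for col in (patient_col, condition_col, value_col):
            if col not in df.columns:
                raise ValueError(f"long-format table missing column {col!r}")
        wide = df.pivot_table(index=patient_col, columns=condition_col, values=value_col)
        if wide.isna().any().any():
            missing = int(wide.isna().sum().sum())
            raise ValueError(f"incomplete design: {missing} missing (patient, condition) cells")
        return cls(
            values=wide.to_numpy(dtype=float),
            condition_labels=tuple(wide.columns),
            patient_ids=tuple(wide.index),
        )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t-transform (n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if xa.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    res = _st.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float
    df: int
    method: Literal["asymptotic", "exact"]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "df": self.df,
            "method": self.method,
        }


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return _st.rankdata(values, axis=1, method="average")


def _friedman_statistic_from_ranks(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-squared from within-block ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    stat = 12.0 * float(np.sum(col_sums**2)) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    # tie correction: sum over blocks of sum(t^3 - t) for tie groups of size t
    tie_sum = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * k * (k * k - 1))
    if denom <= 0:
        # every block fully tied: no information
        return 0.0
    return stat / denom


def _exact_pvalue(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p by dynamic programming over column rank-sum vectors.

    Within each block the k observed ranks (including any tie pattern) are
    equally likely to appear in any of the k! orders; the statistic is a
    monotone function of the column-sum-of-squares, so the null distribution
    follows from the distribution of the rank-sum vector.
    """
    n, k = ranks.shape
    # distribution over rank-sum vectors, keyed by tuple of sums
    dist: Dict[Tuple[float, ...], float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        w = 1.0 / math.factorial(k)
        # weight each distinct ordering by its multiplicity under uniform k! orders
        counts: Dict[Tuple[float, ...], int] = {}
        for p in itertools.permutations(row.tolist()):
            counts[p] = counts.get(p, 0) + 1
        new: Dict[Tuple[float, ...], float] = {}
        for sums, prob in dist.items():
            for p, c in counts.items():
                key = tuple(s + v for s, v in zip(sums, p))
                new[key] = new.get(key, 0.0) + prob * c * w
        dist = new
    # tie correction is permutation invariant; compare statistics directly
    tie_sum = 0.0
    for row in ranks:
        _, cts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(cts**3 - cts))
    denom = 1.0 - tie_sum / (n * k * (k * k - 1))
    p = 0.0
    for sums, prob in dist.items():
        stat = 12.0 * sum(s * s for s in sums) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
        if denom > 0:
            stat /= denom
        else:
            stat = 0.0
        if stat >= observed - 1e-12:
            p += prob
    return min(p, 1.0)


def friedman_test(
    table: PairedCohortTable, method: Literal["auto", "asymptotic", "exact"] = "auto"
) -> FriedmanResult:
    """Friedman's rank test for a condition effect in a complete block design.

    Returns the tie-corrected chi-squared statistic with k-1 degrees of
    freedom.  ``method="auto"`` enumerates the exact within-block permutation
    distribution whenever (k!)^n <= 1e6 and falls back to the chi-squared
    asymptotic otherwise.
    """
    ranks = _row_ranks(table.values)
    n, k = ranks.shape
    stat = _friedman_statistic_from_ranks(ranks)
    if method == "auto":
        method = "exact" if math.factorial(k) ** n <= _EXACT_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_pvalue(ranks, stat)
        return FriedmanResult(statistic=stat, pvalue=p, df=k - 1, method="exact")
    p = float(_st.chi2.sf(stat, k - 1))
    if stat == 0.0:
        p = 1.0
    return FriedmanResult(statistic=stat, pvalue=p, df=k - 1, method="asymptotic")


@dataclass(frozen=True)
class PairwiseComparison:
    condition_a: object
    condition_b: object
    p_raw: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": [self.condition_a, self.condition_b],
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


def _sign_permutation_p(diffs: np.ndarray) -> float:
    """Exact two-sided paired sign-permutation test on within-patient differences.

    Under the null of exchangeable signs, each difference flips sign with
    probability 1/2; the statistic is |sum of differences|.
    """
    n = diffs.size
    if n > 24:
        raise ValueError("exact sign-permutation limited to n <= 24 patients")
    observed = abs(float(np.sum(diffs)))
    signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    sums = np.abs(signs @ diffs)
    return float(np.mean(sums >= observed - 1e-12))


def pairwise_bonferroni(
    table: PairedCohortTable,
    alpha: float = 0.05,
    method: Literal["sign_permutation", "wilcoxon"] = "sign_permutation",
) -> List[PairwiseComparison]:
    """All pairwise condition comparisons with Bonferroni-adjusted p-values.

    Raw p-values come from the exact paired sign-permutation test by default
    (Wilcoxon signed-rank available as an alternative); each is multiplied by
    the number of pairs and capped at 1.  Significance is at the given alpha.
    """
    k = table.n_conditions
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    out: List[PairwiseComparison] = []
    for i, j in pairs:
        d = table.values[:, i] - table.values[:, j]
        if method == "sign_permutation":
            p_raw = _sign_permutation_p(d)
        elif method == "wilcoxon":
            if np.all(d == 0):
                p_raw = 1.0
            else:
                p_raw = float(_st.wilcoxon(d, zero_method="wilcox", mode="exact").pvalue)
        else:
            raise ValueError(f"unknown post-hoc method {method!r}")
        p_adj = min(1.0, p_raw * m)
        out.append(
            PairwiseComparison(
                condition_a=table.condition_labels[i],
                condition_b=table.condition_labels[j],
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out
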