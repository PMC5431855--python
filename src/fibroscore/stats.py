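"""Paired nonparametric testing for donor-matched readouts.

The analysis chain is unconditionally nonparametric: a Shapiro-Wilk screen
documents non-normality, Friedman's ANOVA summarises an omnibus effect over
k >= 3 groups, and pairwise Wilcoxon signed-rank tests carry the actual
comparisons that feed the scoring model.

The signed-rank test is implemented here rather than delegated, because the
study regime — n = 10 donors, ties possible through detection-limit
substitution — lives squarely in the exact small-sample branch.  The exact
two-sided p-value comes from the tie-aware null distribution of W (sum of
ranks of positive differences), computed by dynamic programming over the
doubled mid-ranks (doubling makes half-integer mid-ranks exact integers).
A brute-force enumeration of all 2^n sign assignments,
:func:`exact_signed_rank_null`, serves as an independent oracle and is kept
deliberately naive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    DegenerateInputError,
    DomainError,
    EmptySelectionError,
    MissingDataError,
    PairingError,
    SizeError,
)

__all__ = [
    "PairedSample",
    "PairwiseTestResult",
    "ConditionDependencyResult",
    "shapiro_wilk_screen",
    "friedman_test",
    "wilcoxon_signed_rank",
    "exact_signed_rank_null",
    "condition_dependency_tests",
    "paired_sample_from_table",
    "EXACT_THRESHOLD",
]

#: Largest n_used for which the exact null of W is used (DP is cheap there;
#: n = 10 donors always lands in this branch).
EXACT_THRESHOLD = 25

#: Hard guard for the brute-force oracle: 2^n sign vectors are materialised.
_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class PairedSample:
    """Two donor-aligned measurement vectors for one group pair.

    ``x[i]`` and ``y[i]`` belong to ``donor_ids[i]``; the labels say which
    two groups (materials or conditions) are being compared.
    """

    labels: tuple[str, str]
    x: np.ndarray
    y: np.ndarray
    donor_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "donor_ids", tuple(self.donor_ids))
        if not (len(self.x) == len(self.y) == len(self.donor_ids)):
            raise PairingError(
                f"length mismatch: |x|={len(self.x)}, |y|={len(self.y)}, "
                f"|donor_ids|={len(self.donor_ids)}"
            )
        if len(set(self.donor_ids)) != len(self.donor_ids):
            raise PairingError("donor_ids contain duplicates")

    def swapped(self) -> "PairedSample":
        return PairedSample(
            labels=(self.labels[1], self.labels[0]),
            x=self.y,
            y=self.x,
            donor_ids=self.donor_ids,
        )


@dataclass
class PairwiseTestResult:
    """Outcome of one paired signed-rank comparison."""

    labels: tuple[str, str]
    n_used: int
    statistic: float
    p_value: float
    mean_diff: float
    method: str  # "exact" | "approximate"
    significant: bool | None = None


@dataclass
class ConditionDependencyResult:
    """Friedman omnibus plus all pairwise condition comparisons for one
    (material, readout) slice."""

    material: str
    readout: str
    friedman_statistic: float | None
    friedman_p: float | None
    pairwise: list[PairwiseTestResult] = field(default_factory=list)


def shapiro_wilk_screen(values) -> tuple[float, float]:
    """Shapiro-Wilk normality screen.

    Documents the non-normality of donor-dependent readouts; the pipeline
    never switches test family on its outcome.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise DegenerateInputError(f"need >= 3 values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("values must be finite")
    if np.ptp(v) == 0:
        raise DegenerateInputError("zero variance: all values identical")
    res = scipy.stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def friedman_test(block_data) -> tuple[float, float]:
    """Friedman's chi-square ANOVA on within-donor ranks.

    ``block_data``: 2-D array-like or DataFrame, one row per donor, one
    column per group; blocks must be complete.  Mid-ranks for ties; p from
    the chi-square approximation with k-1 degrees of freedom.
    """
    if isinstance(block_data, pd.DataFrame):
        data = block_data.to_numpy(dtype=float)
        donors = list(block_data.index)
    else:
        data = np.asarray(block_data, dtype=float)
        donors = list(range(data.shape[0])) if data.ndim == 2 else []
    if data.ndim != 2:
        raise DomainError("block_data must be 2-D (donors x groups)")
    n, k = data.shape
    if k < 3:
        raise DomainError(
            f"Friedman needs k >= 3 groups, got {k}; use the pairwise "
            "signed-rank test for two groups"
        )
    if n < 2:
        raise DomainError(f"need >= 2 donors, got {n}")
    bad = [str(donors[i]) for i in range(n) if not np.all(np.isfinite(data[i]))]
    if bad:
        raise MissingDataError(f"incomplete blocks for donors: {bad}")
    # all-tied blocks: every rank equal, statistic 0 by convention (scipy's
    # tie correction would divide by zero here)
    if all(np.ptp(row) == 0 for row in data):
        return 0.0, 1.0
    stat, p = scipy.stats.friedmanchisquare(*[data[:, j] for j in range(k)])
    return float(stat), float(p)


def _exact_pmf_doubled(ranks2: tuple[int, ...]) -> np.ndarray:
    """PMF of 2*W over support 0..sum(ranks2) by sign-flip convolution."""
    total = sum(ranks2)
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    upto = 0
    for r in ranks2:
        upto += r
        pmf[r : upto + 1] += pmf[: upto + 1 - r]
        pmf[: upto + 1] /= 2.0
    return pmf


@lru_cache(maxsize=4096)
def _exact_pmf_cached(ranks2: tuple[int, ...]) -> np.ndarray:
    return _exact_pmf_doubled(ranks2)


def exact_signed_rank_null(abs_ranks) -> tuple[np.ndarray, np.ndarray]:
    """Exact null PMF of W by brute-force enumeration of sign assignments.

    Enumerates all 2^n assignments of signs to the given (possibly tied)
    absolute ranks and tabulates W = sum of positively-signed ranks.
    Returns ``(support, pmf)``.  This is the verification oracle for the
    convolution used by :func:`wilcoxon_signed_rank`; it stays a literal
    enumeration on purpose.
    """
    ranks = np.asarray(abs_ranks, dtype=float)
    n = len(ranks)
    if n < 1:
        raise SizeError("need at least one rank")
    if n > _ENUMERATION_LIMIT:
        raise SizeError(f"enumeration limited to n <= {_ENUMERATION_LIMIT}, got {n}")
    codes = np.arange(2**n, dtype=np.int64)
    signs = (codes[:, None] >> np.arange(n)) & 1  # (2^n, n) in {0,1}
    w2 = signs @ np.rint(2 * ranks).astype(np.int64)
    counts = np.bincount(w2)
    support2 = np.nonzero(counts)[0]
    return support2 / 2.0, counts[support2] / float(2**n)


def _two_sided_exact_p(pmf2: np.ndarray, w2: int) -> float:
    cdf = np.cumsum(pmf2)
    p_le = cdf[w2]
    p_ge = 1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    sample: PairedSample, exact_threshold: int = EXACT_THRESHOLD
) -> PairwiseTestResult:
    """Two-sided Wilcoxon signed-rank test on donor-paired differences.

    Differences d_i = x_i - y_i; zero differences are dropped (classic
    reduction), |d| ranked with mid-ranks, W = sum of ranks of positive d.
    Exact tie-aware p for ``n_used <= exact_threshold``, else a
    tie-corrected normal approximation without continuity correction.
    ``mean_diff`` is mean(x) - mean(y) over all pairs, zeros included —
    it is the direction carrier for the downstream Eq.-style scoring.
    All differences zero is not an error: W = 0, p = 1, n_used = 0.
    """
    if len(sample.x) < 2:
        raise PairingError(f"need >= 2 pairs, got {len(sample.x)}")
    d = sample.x - sample.y
    mean_diff = float(np.mean(sample.x) - np.mean(sample.y))
    nonzero = d != 0
    n_used = int(np.count_nonzero(nonzero))
    if n_used == 0:
        return PairwiseTestResult(
            labels=sample.labels,
            n_used=0,
            statistic=0.0,
            p_value=1.0,
            mean_diff=mean_diff,
            method="exact",
        )
    dz = d[nonzero]
    ranks = scipy.stats.rankdata(np.abs(dz))
    w = float(np.sum(ranks[dz > 0]))

    if n_used <= exact_threshold:
        ranks2 = tuple(sorted(np.rint(2 * ranks).astype(int)))
        pmf2 = _exact_pmf_cached(ranks2)
        p = _two_sided_exact_p(pmf2, int(round(2 * w)))
        method = "exact"
    else:
        mu = n_used * (n_used + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n_used * (n_used + 1) * (2 * n_used + 1) / 24.0 - tie_term
        z = (w - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))
        method = "approximate"
    return PairwiseTestResult(
        labels=sample.labels,
        n_used=n_used,
        statistic=w,
        p_value=p,
        mean_diff=mean_diff,
        method=method,
    )


def paired_sample_from_table(
    table: pd.DataFrame,
    group_column: str,
    group_1: str,
    group_2: str,
    **fixed,
) -> PairedSample:
    """Extract a donor-aligned pair of vectors from a long-format table.

    ``fixed`` pins the other design columns (e.g. ``condition=...,
    readout=...``); donors missing from either group raise a pairing error.
    """
    sel = table
    for col, val in fixed.items():
        sel = sel[sel[col] == val]
    piv = sel.pivot_table(
        index="donor_id", columns=group_column, values="value", aggfunc="first"
    )
    for g in (group_1, group_2):
        if g not in piv.columns:
            raise EmptySelectionError(
                f"no rows for {group_column}={g!r} under {fixed!r}"
            )
    pair = piv[[group_1, group_2]].dropna()
    missing = piv.index[piv[[group_1, group_2]].isna().any(axis=1)]
    if len(missing):
        raise PairingError(
            f"donors missing a value for {group_1!r}/{group_2!r}: "
            f"{sorted(map(str, missing))}"
        )
    return PairedSample(
        labels=(group_1, group_2),
        x=pair[group_1].to_numpy(),
        y=pair[group_2].to_numpy(),
        donor_ids=tuple(map(str, pair.index)),
    )


def condition_dependency_tests(
    table: pd.DataFrame,
    material: str,
    readout: str,
    alpha: float = 0.05,
    exact_threshold: int = EXACT_THRESHOLD,
) -> ConditionDependencyResult:
    """All condition-vs-condition paired tests for one material and readout.

    Friedman's ANOVA across the conditions is reported alongside (None when
    only two conditions are present); every unordered condition pair gets a
    Wilcoxon signed-rank test, donor-paired, flagged significant at
    p <= alpha.  The Friedman result does not gate the pairwise tests.
    """
    sel = table[(table["material"] == material) & (table["readout"] == readout)]
    if sel.empty:
        raise EmptySelectionError(
            f"no rows for material={material!r}, readout={readout!r}"
        )
    conditions = [c for c in sel["condition"].unique()]
    if len(conditions) < 2:
        raise EmptySelectionError(
            f"need >= 2 conditions for material={material!r}, readout={readout!r}"
        )
    piv = sel.pivot_table(
        index="donor_id", columns="condition", values="value", aggfunc="first"
    )[conditions]
    if piv.isna().any().any():
        bad = piv.index[piv.isna().any(axis=1)]
        raise PairingError(
            f"donors missing conditions for ({material!r}, {readout!r}): "
            f"{sorted(map(str, bad))}"
        )
    if len(conditions) >= 3:
        fr_stat, fr_p = friedman_test(piv)
    else:
        fr_stat = fr_p = None
    donors = tuple(map(str, piv.index))
    cols = {c: piv[c].to_numpy() for c in conditions}
    results = []
    for c1, c2 in combinations(conditions, 2):
        sample = PairedSample(labels=(c1, c2), x=cols[c1], y=cols[c2], donor_ids=donors)
        res = wilcoxon_signed_rank(sample, exact_threshold=exact_threshold)
        res.significant = res.p_value <= alpha
        results.append(res)
    return ConditionDependencyResult(
        material=material,
        readout=readout,
        friedman_statistic=fr_stat,
        friedman_p=fr_p,
        pairwise=results,
    )
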