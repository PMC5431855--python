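"""Ternary significance-profile scoring and material ranking.

The comparative model condenses donor-paired readouts into one assessment
criterion per material and condition.  For every unordered material pair
(M1, M2) within a (condition, readout) cell, a Wilcoxon signed-rank test is
run on the donor-paired values and mapped to a ternary score for M1:

    +1  if p <= alpha and mean(M1) > mean(M2)
    -1  if p <= alpha and mean(M1) < mean(M2)
     0  otherwise (no significant difference)

Direction comes from the arithmetic means while significance comes from the
rank test — that asymmetry is deliberate and kept literal; a rank-based
direction is available behind ``direction="signed_rank"``.

A material's *significance profile* for one readout is the sum of its K-1
pairwise scores; stacking profiles over all R readouts gives the K x R
score matrix (the numeric heat map), and row sums give the per-condition
material ranking (the "sum score").  Pairwise antisymmetry makes every
readout column sum to zero exactly, a conservation law the matrix builder
verifies before returning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import EmptySelectionError, InternalConsistencyError, PairingError
from .stats import (
    EXACT_THRESHOLD,
    PairedSample,
    PairwiseTestResult,
    friedman_test,
    wilcoxon_signed_rank,
)

__all__ = [
    "PairwiseScore",
    "ScoreMatrix",
    "MaterialRanking",
    "pairwise_material_score",
    "significance_profile",
    "build_score_matrix",
    "material_ranking",
]

logger = logging.getLogger(__name__)


@dataclass
class PairwiseScore:
    """One ternary pairwise comparison, scored for ``material_1``."""

    material_1: str
    material_2: str
    readout: str | None
    condition: str | None
    score: int
    p_value: float
    mean_diff: float

    def reversed(self) -> "PairwiseScore":
        return PairwiseScore(
            material_1=self.material_2,
            material_2=self.material_1,
            readout=self.readout,
            condition=self.condition,
            score=-self.score,
            p_value=self.p_value,
            mean_diff=-self.mean_diff,
        )


@dataclass
class ScoreMatrix:
    """K x R integer grid of significance-profile values for one condition."""

    condition: str
    materials: tuple[str, ...]
    readouts: tuple[str, ...]
    entries: np.ndarray  # shape (K, R), int

    def __post_init__(self) -> None:
        self.materials = tuple(self.materials)
        self.readouts = tuple(self.readouts)
        self.entries = np.asarray(self.entries, dtype=int)

    def validate(self) -> None:
        K, R = len(self.materials), len(self.readouts)
        if self.entries.shape != (K, R):
            raise InternalConsistencyError(
                f"entries shape {self.entries.shape} != ({K}, {R})"
            )
        if np.any(np.abs(self.entries) > K - 1):
            raise InternalConsistencyError(
                f"profile value outside [-(K-1), K-1] = [{-(K-1)}, {K-1}]"
            )
        col_sums = self.entries.sum(axis=0)
        if np.any(col_sums != 0):
            bad = {
                self.readouts[j]: int(col_sums[j])
                for j in np.nonzero(col_sums)[0]
            }
            raise InternalConsistencyError(
                f"readout columns do not sum to zero: {bad}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.materials), columns=list(self.readouts)
        )

    def row(self, material: str) -> np.ndarray:
        return self.entries[self.materials.index(material)]


@dataclass
class MaterialRanking:
    """Per-condition sum scores and the induced descending rank order.

    ``ties`` lists every group of materials sharing a total (singletons
    included), in rank order; exact ties are reported, never broken.
    """

    condition: str
    total_scores: dict[str, int]
    rank_order: tuple[str, ...]
    ties: tuple[frozenset, ...]

    def rank_of(self, material: str) -> int:
        """Competition rank (1-based; tied materials share the best rank)."""
        total = self.total_scores[material]
        return 1 + sum(1 for t in self.total_scores.values() if t > total)


def _score_from_test(res: PairwiseTestResult, alpha: float, direction: str) -> int:
    if res.p_value > alpha:
        return 0
    if direction == "mean":
        signed = res.mean_diff
    elif direction == "signed_rank":
        # sign of W relative to its null centre n(n+1)/4
        signed = res.statistic - res.n_used * (res.n_used + 1) / 4.0
    else:
        raise ValueError(f"direction must be 'mean' or 'signed_rank', got {direction!r}")
    if signed > 0:
        return 1
    if signed < 0:
        return -1
    # significant but directionless (possible with censored substitutes):
    # score 0, conservatively, and leave a trace in the log
    logger.warning(
        "significant test with zero direction for pair %s (p=%.4g); scored 0",
        res.labels,
        res.p_value,
    )
    return 0


def pairwise_material_score(
    sample: PairedSample,
    alpha: float = 0.05,
    *,
    readout: str | None = None,
    condition: str | None = None,
    direction: str = "mean",
    exact_threshold: int = EXACT_THRESHOLD,
) -> PairwiseScore:
    """Score material ``sample.labels[0]`` against ``sample.labels[1]``.

    Runs the donor-paired signed-rank test and applies the ternary map;
    p-value and mean difference are recorded for audit.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    res = wilcoxon_signed_rank(sample, exact_threshold=exact_threshold)
    return PairwiseScore(
        material_1=sample.labels[0],
        material_2=sample.labels[1],
        readout=readout,
        condition=condition,
        score=_score_from_test(res, alpha, direction),
        p_value=res.p_value,
        mean_diff=res.mean_diff,
    )


def _pairwise_scores_for_cell(
    table: pd.DataFrame,
    condition: str,
    readout: str,
    materials: tuple[str, ...],
    alpha: float,
    direction: str,
    multiple_testing: str,
    friedman_gate: bool,
    exact_threshold: int,
    audit: list | None,
) -> dict[str, int]:
    """All C(K,2) pairwise scores for one (condition, readout) cell,
    aggregated to per-material profile values."""
    cell = table[(table["condition"] == condition) & (table["readout"] == readout)]
    piv = cell.pivot_table(
        index="donor_id", columns="material", values="value", aggfunc="first"
    )
    missing = [m for m in materials if m not in piv.columns]
    if missing:
        raise EmptySelectionError(
            f"no rows for materials {missing} under condition={condition!r}, "
            f"readout={readout!r}"
        )
    if piv[list(materials)].isna().any().any():
        bad = piv.index[piv[list(materials)].isna().any(axis=1)]
        raise PairingError(
            f"donors missing values in ({condition!r}, {readout!r}): "
            f"{sorted(map(str, bad))}"
        )

    gate_open = True
    if friedman_gate and len(materials) >= 3:
        _, fr_p = friedman_test(piv[list(materials)])
        gate_open = fr_p <= alpha

    donors = tuple(map(str, piv.index))
    cols = {m: piv[m].to_numpy() for m in materials}
    tests: list[PairwiseTestResult] = []
    pairs = list(combinations(materials, 2))
    for m1, m2 in pairs:
        sample = PairedSample(labels=(m1, m2), x=cols[m1], y=cols[m2], donor_ids=donors)
        tests.append(wilcoxon_signed_rank(sample, exact_threshold=exact_threshold))

    p_values = np.array([t.p_value for t in tests])
    if multiple_testing == "benjamini_hochberg":
        _, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    elif multiple_testing == "none":
        p_adj = p_values
    else:
        raise ValueError(f"unknown multiple_testing policy {multiple_testing!r}")

    profile = {m: 0 for m in materials}
    for (m1, m2), test, p in zip(pairs, tests, p_adj):
        effective = test if p == test.p_value else PairwiseTestResult(
            labels=test.labels,
            n_used=test.n_used,
            statistic=test.statistic,
            p_value=float(p),
            mean_diff=test.mean_diff,
            method=test.method,
        )
        s = _score_from_test(effective, alpha, direction) if gate_open else 0
        profile[m1] += s
        profile[m2] -= s
        if audit is not None:
            audit.append(
                {
                    "condition": condition,
                    "readout": readout,
                    "label_1": m1,
                    "label_2": m2,
                    "n_used": test.n_used,
                    "statistic": test.statistic,
                    "p_value": float(p),
                    "mean_diff": test.mean_diff,
                    "method": test.method,
                    "significant": bool(p <= alpha) and gate_open,
                    "score": s,
                }
            )
    return profile


def significance_profile(
    table: pd.DataFrame,
    condition: str,
    readout: str,
    alpha: float = 0.05,
    *,
    direction: str = "mean",
    multiple_testing: str = "none",
    friedman_gate: bool = False,
    exact_threshold: int = EXACT_THRESHOLD,
    audit: list | None = None,
) -> dict[str, int]:
    """Per-material profile values for one (condition, readout) cell.

    Each material's value is the sum of its K-1 ternary pairwise scores
    against every other material; the values sum to zero over materials.
    """
    sel = table[(table["condition"] == condition) & (table["readout"] == readout)]
    materials = tuple(sel["material"].unique())
    if len(materials) < 2:
        raise EmptySelectionError(
            f"need >= 2 materials for condition={condition!r}, readout={readout!r}"
        )
    return _pairwise_scores_for_cell(
        table,
        condition,
        readout,
        materials,
        alpha,
        direction,
        multiple_testing,
        friedman_gate,
        exact_threshold,
        audit,
    )


def build_score_matrix(
    table: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
    *,
    materials: tuple[str, ...] | None = None,
    readouts: tuple[str, ...] | None = None,
    direction: str = "mean",
    multiple_testing: str = "none",
    friedman_gate: bool = False,
    exact_threshold: int = EXACT_THRESHOLD,
    audit: list | None = None,
) -> ScoreMatrix:
    """Assemble the K x R score matrix for one condition and validate its
    conservation invariants (zero column sums, entries within +/-(K-1))."""
    sel = table[table["condition"] == condition]
    if sel.empty:
        raise EmptySelectionError(f"no rows for condition={condition!r}")
    if materials is None:
        materials = tuple(sel["material"].unique())
    if readouts is None:
        readouts = tuple(sel["readout"].unique())
    entries = np.zeros((len(materials), len(readouts)), dtype=int)
    for j, readout in enumerate(readouts):
        profile = _pairwise_scores_for_cell(
            table,
            condition,
            readout,
            materials,
            alpha,
            direction,
            multiple_testing,
            friedman_gate,
            exact_threshold,
            audit,
        )
        for i, m in enumerate(materials):
            entries[i, j] = profile[m]
    matrix = ScoreMatrix(
        condition=condition, materials=materials, readouts=readouts, entries=entries
    )
    matrix.validate()
    return matrix


def material_ranking(matrix: ScoreMatrix) -> MaterialRanking:
    """Sum each material's row and order descending; ties stay grouped."""
    matrix.validate()
    totals = {m: int(matrix.entries[i].sum()) for i, m in enumerate(matrix.materials)}
    order = tuple(
        sorted(matrix.materials, key=lambda m: (-totals[m], matrix.materials.index(m)))
    )
    tie_groups: list[frozenset] = []
    seen: set[int] = set()
    for m in order:
        if totals[m] in seen:
            continue
        seen.add(totals[m])
        tie_groups.append(frozenset(k for k in matrix.materials if totals[k] == totals[m]))
    return MaterialRanking(
        condition=matrix.condition,
        total_scores=totals,
        rank_order=order,
        ties=tuple(tie_groups),
    )
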