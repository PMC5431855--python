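"""Concordance between a computed material ranking and a literature
reference ordering of fibrotic potential.

The reference (from animal and clinical implantation studies) orders
PE < titanium < PTFE < silicone by increasing fibrotic potential; glass,
a cell-culture control with no in vivo reference, is left unranked and
excluded from the concordance metrics.  Agreement is measured by Kendall's
tau-b (primary — short rankings with possible tied sum scores), Spearman's
rho, and the plain concordant-pair fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.stats

from .errors import ConfigError, InsufficientOverlapError
from .scoring import MaterialRanking, build_score_matrix, material_ranking
from .simulate import LITERATURE_ORDER, SimulationConfig, generate_dataset, literature_scenario

__all__ = [
    "ReferenceRanking",
    "ConcordanceResult",
    "FIBROTIC_REFERENCE",
    "compare_to_reference",
    "ranking_recovery_experiment",
]


@dataclass(frozen=True)
class ReferenceRanking:
    """An ordered reference, lowest to highest fibrotic potential, plus the
    materials deliberately excluded from it."""

    ordered_materials: tuple[str, ...]
    unranked: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_materials", tuple(self.ordered_materials))
        object.__setattr__(self, "unranked", frozenset(self.unranked))
        if len(set(self.ordered_materials)) != len(self.ordered_materials):
            raise ConfigError("ordered_materials contain duplicates")
        if self.unranked & set(self.ordered_materials):
            raise ConfigError("unranked materials overlap the ordered list")

    def position(self, material: str) -> int:
        return self.ordered_materials.index(material)


#: Literature consensus: increasing fibrotic potential PE < titanium <
#: PTFE < silicone; glass has no in vivo reference.
FIBROTIC_REFERENCE = ReferenceRanking(LITERATURE_ORDER, unranked=frozenset({"glass"}))


@dataclass
class ConcordanceResult:
    """Agreement metrics between computed sum scores and a reference order,
    restricted to the materials present in both."""

    kendall_tau: float
    spearman_rho: float
    concordant_pair_fraction: float
    n_pairs_compared: int
    overlap: tuple[str, ...] = ()


def compare_to_reference(
    ranking: MaterialRanking, reference: ReferenceRanking = FIBROTIC_REFERENCE
) -> ConcordanceResult:
    """Kendall tau-b / Spearman rho between sum scores and reference
    positions over the overlapping materials.

    The concordant-pair fraction counts material pairs whose sum scores
    order the same way as the reference, over all non-tied pairs.  Both
    rank correlations use their usual tie conventions (tau-b tie
    correction, mid-ranks for rho); ties can only come from the computed
    totals — the reference is a strict order.
    """
    overlap = tuple(
        m for m in reference.ordered_materials if m in ranking.total_scores
    )
    if len(overlap) < 2:
        raise InsufficientOverlapError(
            f"only {len(overlap)} material(s) shared with the reference"
        )
    scores = np.array([ranking.total_scores[m] for m in overlap], dtype=float)
    positions = np.arange(len(overlap), dtype=float)
    if np.ptp(scores) == 0:
        # all totals tied: correlation with the reference is undefined
        tau = rho = float("nan")
    else:
        tau = float(scipy.stats.kendalltau(positions, scores).statistic)
        rho = float(scipy.stats.spearmanr(positions, scores).statistic)
    concordant = discordant = 0
    for i, j in combinations(range(len(overlap)), 2):
        diff = scores[j] - scores[i]  # reference says j more fibrotic than i
        if diff > 0:
            concordant += 1
        elif diff < 0:
            discordant += 1
    denom = concordant + discordant
    fraction = concordant / denom if denom else float("nan")
    return ConcordanceResult(
        kendall_tau=tau,
        spearman_rho=rho,
        concordant_pair_fraction=fraction,
        n_pairs_compared=len(overlap) * (len(overlap) - 1) // 2,
        overlap=overlap,
    )


def ranking_recovery_experiment(
    base: SimulationConfig,
    effect_steps,
    n_replicates: int,
    alpha: float = 0.05,
    reference: ReferenceRanking = FIBROTIC_REFERENCE,
    conditions=None,
) -> dict[float, float]:
    """Fraction of simulated screens whose ranking exactly recovers the
    reference order, per planted effect step.

    For each step, ``n_replicates`` datasets are drawn from
    :func:`literature_scenario` applied to ``base`` (fresh sub-seed per
    replicate, derived deterministically from ``base.seed``); each scored
    condition contributes one recovery trial, recovered iff Kendall's tau
    against the reference is exactly 1 (strict order, no ties).
    """
    if n_replicates < 1:
        raise ConfigError(f"n_replicates must be >= 1, got {n_replicates}")
    steps = [float(s) for s in effect_steps]
    if any(s < 0 for s in steps):
        raise ConfigError("effect_steps must be nonnegative")
    if conditions is None:
        conditions = base.conditions
    ss = np.random.SeedSequence(base.seed)
    sub_seeds = [int(s) for s in ss.generate_state(len(steps) * n_replicates) % (2**31)]
    rates: dict[float, float] = {}
    k = 0
    for step in steps:
        recovered = trials = 0
        for _ in range(n_replicates):
            cfg = literature_scenario(base, step)
            cfg.seed = sub_seeds[k]
            k += 1
            table = generate_dataset(cfg)
            for condition in conditions:
                matrix = build_score_matrix(table, condition, alpha=alpha)
                result = compare_to_reference(material_ranking(matrix), reference)
                trials += 1
                if result.kendall_tau == 1.0:
                    recovered += 1
        rates[step] = recovered / trials
    return rates
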