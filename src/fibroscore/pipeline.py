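"""End-to-end orchestration: data in, per-condition score matrices,
rankings, concordance, and a full audit trail out.

``run_pipeline`` is deterministic given (data, config): it contains no
randomness of its own, and writing the same result bundle twice produces
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigError, MissingDataError
from .io import (
    write_concordance_csv,
    write_pairwise_csv,
    write_ranking_csv,
    write_score_matrix_tsv,
)
from .scoring import MaterialRanking, ScoreMatrix, build_score_matrix, material_ranking
from .simulate import SimulationConfig
from .stats import EXACT_THRESHOLD, ConditionDependencyResult, condition_dependency_tests
from .validation import FIBROTIC_REFERENCE, ConcordanceResult, ReferenceRanking, compare_to_reference

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "write_result_bundle",
    "experiment_design_summary",
]

#: Condition labels treated as measurement references, not scored scenarios.
DEFAULT_EXCLUDED_CONDITIONS = frozenset({"blank", "blank medium", "blank RPMI"})


@dataclass
class PipelineConfig:
    """Analysis settings; defaults reproduce the flat two-sided p <= 0.05
    rule with no multiplicity correction and no Friedman gate."""

    alpha: float = 0.05
    friedman_gate: bool = False
    multiple_testing: str = "none"  # "none" | "benjamini_hochberg"
    direction: str = "mean"  # "mean" | "signed_rank"
    exact_threshold: int = EXACT_THRESHOLD
    reference_ranking: ReferenceRanking = FIBROTIC_REFERENCE
    include_conditions: tuple[str, ...] | None = None
    excluded_conditions: frozenset = DEFAULT_EXCLUDED_CONDITIONS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.exact_threshold < 1:
            raise ConfigError(
                f"exact_threshold must be >= 1, got {self.exact_threshold}"
            )


@dataclass
class PipelineResult:
    """Everything one run produces, keyed by condition where applicable."""

    conditions: tuple[str, ...]
    score_matrices: dict[str, ScoreMatrix]
    rankings: dict[str, MaterialRanking]
    concordance: dict[str, ConcordanceResult]
    condition_dependency: list[ConditionDependencyResult]
    material_test_audit: list[dict]
    condition_test_audit: list[dict]


def _check_completeness(data: pd.DataFrame, conditions) -> None:
    """Every (material, condition, readout) cell must carry the same donor
    set with >= 2 donors; name the offending cells otherwise."""
    sel = data[data["condition"].isin(conditions)]
    donors = set(sel["donor_id"].unique())
    counts = sel.groupby(["material", "condition", "readout"], sort=False)["donor_id"].agg(set)
    bad = []
    for key, cell_donors in counts.items():
        if cell_donors != donors or len(cell_donors) < 2:
            missing = sorted(donors - cell_donors)
            bad.append(f"{key}: missing donors {missing}")
    expected = (
        sel["material"].nunique() * len(conditions) * sel["readout"].nunique()
    )
    if len(counts) != expected:
        bad.append(
            f"only {len(counts)} of {expected} (material, condition, readout) cells present"
        )
    if bad:
        raise MissingDataError("incomplete design: " + "; ".join(bad[:20]))


def run_pipeline(data: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full comparative analysis of one readout table.

    Per scored condition: K x R score matrix, material ranking and
    concordance against the reference; additionally all condition-dependency
    tests (Friedman + pairwise, per material x readout) and a per-test
    audit trail recording every p-value and scoring branch taken.
    """
    if config.include_conditions is not None:
        conditions = tuple(config.include_conditions)
    else:
        conditions = tuple(
            c for c in data["condition"].unique() if c not in config.excluded_conditions
        )
    if not conditions:
        raise ConfigError("no conditions left to score")
    _check_completeness(data, conditions)
    scored = data[data["condition"].isin(conditions)]
    materials = tuple(scored["material"].unique())
    readouts = tuple(scored["readout"].unique())

    material_audit: list[dict] = []
    matrices: dict[str, ScoreMatrix] = {}
    rankings: dict[str, MaterialRanking] = {}
    concordance: dict[str, ConcordanceResult] = {}
    for condition in conditions:
        matrix = build_score_matrix(
            scored,
            condition,
            alpha=config.alpha,
            materials=materials,
            readouts=readouts,
            direction=config.direction,
            multiple_testing=config.multiple_testing,
            friedman_gate=config.friedman_gate,
            exact_threshold=config.exact_threshold,
            audit=material_audit,
        )
        matrices[condition] = matrix
        rankings[condition] = material_ranking(matrix)
        concordance[condition] = compare_to_reference(
            rankings[condition], config.reference_ranking
        )

    condition_audit: list[dict] = []
    dependency: list[ConditionDependencyResult] = []
    if len(conditions) >= 2:
        for material in materials:
            for readout in readouts:
                res = condition_dependency_tests(
                    scored,
                    material,
                    readout,
                    alpha=config.alpha,
                    exact_threshold=config.exact_threshold,
                )
                dependency.append(res)
                for t in res.pairwise:
                    condition_audit.append(
                        {
                            "material": material,
                            "readout": readout,
                            "label_1": t.labels[0],
                            "label_2": t.labels[1],
                            "n_used": t.n_used,
                            "statistic": t.statistic,
                            "p_value": t.p_value,
                            "mean_diff": t.mean_diff,
                            "method": t.method,
                            "significant": t.significant,
                        }
                    )

    return PipelineResult(
        conditions=conditions,
        score_matrices=matrices,
        rankings=rankings,
        concordance=concordance,
        condition_dependency=dependency,
        material_test_audit=material_audit,
        condition_test_audit=condition_audit,
    )


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in label)


def write_result_bundle(result: PipelineResult, outdir) -> list[Path]:
    """Write all exports; returns the paths written (fixed order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for condition in result.conditions:
        p = outdir / f"score_matrix_{_slug(condition)}.tsv"
        write_score_matrix_tsv(result.score_matrices[condition], p)
        written.append(p)
    p = outdir / "rankings.csv"
    write_ranking_csv([result.rankings[c] for c in result.conditions], p)
    written.append(p)
    p = outdir / "concordance.csv"
    write_concordance_csv(result.concordance, p)
    written.append(p)
    p = outdir / "material_pairwise_tests.csv"
    write_pairwise_csv(result.material_test_audit, p)
    written.append(p)
    if result.condition_test_audit:
        p = outdir / "condition_pairwise_tests.csv"
        pd.DataFrame(result.condition_test_audit).to_csv(p, index=False)
        written.append(p)
    summary = {
        "conditions": list(result.conditions),
        "n_material_tests": len(result.material_test_audit),
        "n_condition_tests": len(result.condition_test_audit),
        "rankings": {
            c: {
                "totals": result.rankings[c].total_scores,
                "order": list(result.rankings[c].rank_order),
            }
            for c in result.conditions
        },
        "kendall_tau": {
            c: result.concordance[c].kendall_tau for c in result.conditions
        },
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, allow_nan=True), encoding="utf-8")
    written.append(p)
    return written


def experiment_design_summary(obj) -> dict[str, int]:
    """Design counts: K materials, C conditions, donors, R readouts and the
    K*C material-condition combinations actually tested."""
    if isinstance(obj, SimulationConfig):
        K, C = len(obj.materials), len(obj.conditions)
        n, R = obj.n_donors, len(obj.readouts)
    elif isinstance(obj, pd.DataFrame):
        K = obj["material"].nunique()
        C = obj["condition"].nunique()
        n = obj["donor_id"].nunique()
        R = obj["readout"].nunique()
    else:
        raise TypeError(f"expected SimulationConfig or DataFrame, got {type(obj)}")
    return {
        "n_materials": K,
        "n_conditions": C,
        "n_donors": n,
        "n_readouts": R,
        "n_combinations": K * C,
    }
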