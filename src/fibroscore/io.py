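"""File formats: readout tables (CSV), exports (CSV/TSV), configs (YAML).

The readout-table schema is fixed:

    donor_id,material,condition,readout,value,below_lod

UTF-8, "." decimal separator, ``below_lod`` written as ``true``/``false``.
Reading is strict — unknown or missing columns, malformed booleans,
non-finite or negative values, and duplicate design keys are all reported
with line numbers before any statistics run.  Write/read round-trips are
value-exact (floats serialized with shortest-round-trip repr).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .simulate import TABLE_COLUMNS, SimulationConfig

__all__ = [
    "read_readout_table",
    "write_readout_table",
    "validate_readout_table",
    "write_score_matrix_tsv",
    "write_ranking_csv",
    "write_pairwise_csv",
    "write_concordance_csv",
    "load_simulation_config",
    "save_simulation_config",
]

_KEY_COLUMNS = ["donor_id", "material", "condition", "readout"]


def validate_readout_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Check schema, dtypes and invariants; return the validated frame."""
    if list(df.columns) != TABLE_COLUMNS:
        raise SchemaError(
            f"{source}: header must be exactly {TABLE_COLUMNS}, got {list(df.columns)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() | ~np.isfinite(values) | (values < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ParseError(
            f"{source}: non-finite or negative 'value' at line(s) {lines}"
        )
    df = df.assign(value=values.astype(float))
    if df["below_lod"].dtype != bool:
        tokens = df["below_lod"].astype(str).str.strip().str.lower()
        bad = df.index[~tokens.isin(["true", "false"])]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:10]]
            raise ParseError(
                f"{source}: 'below_lod' must be true/false, bad line(s) {lines}"
            )
        df = df.assign(below_lod=(tokens == "true"))
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ParseError(
            f"{source}: duplicate (donor, material, condition, readout) "
            f"key at line(s) {lines}"
        )
    return df


def read_readout_table(path) -> pd.DataFrame:
    """Read and validate a readout-table CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    return validate_readout_table(df, source=str(path))


def write_readout_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    out = df[TABLE_COLUMNS].copy()
    out["below_lod"] = np.where(out["below_lod"].astype(bool), "true", "false")
    out.to_csv(path, index=False)


def write_score_matrix_tsv(matrix, path) -> None:
    """First column the material label, one integer column per readout."""
    frame = matrix.to_frame()
    frame.index.name = "material"
    frame.to_csv(path, sep="\t")


def write_ranking_csv(rankings, path) -> None:
    """``condition,material,total_score,rank`` — one row per material, in
    rank order; tied materials share the best (competition) rank."""
    rows = []
    for ranking in rankings:
        for m in ranking.rank_order:
            rows.append(
                {
                    "condition": ranking.condition,
                    "material": m,
                    "total_score": ranking.total_scores[m],
                    "rank": ranking.rank_of(m),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pairwise_csv(audit_rows, path) -> None:
    columns = [
        "condition",
        "readout",
        "label_1",
        "label_2",
        "n_used",
        "statistic",
        "p_value",
        "mean_diff",
        "method",
        "significant",
        "score",
    ]
    df = pd.DataFrame(audit_rows)
    df = df[[c for c in columns if c in df.columns]]
    df.to_csv(path, index=False)


def write_concordance_csv(results: dict, path) -> None:
    """``results``: condition -> ConcordanceResult."""
    rows = [
        {
            "condition": condition,
            "kendall_tau": r.kendall_tau,
            "spearman_rho": r.spearman_rho,
            "concordant_pair_fraction": r.concordant_pair_fraction,
            "n_pairs_compared": r.n_pairs_compared,
        }
        for condition, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_simulation_config(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["materials"] = list(config.materials)
    data["conditions"] = list(config.conditions)
    data["readouts"] = list(config.readouts)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def load_simulation_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SimulationConfig(**data)
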