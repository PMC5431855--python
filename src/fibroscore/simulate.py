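"""Synthetic donor-paired readout data for the biomaterial scoring pipeline.

The generator emulates the structure of a multi-donor macrophage/biomaterial
screen: ``n_donors`` human donors, each measured on every
(material, condition, readout) cell exactly once.  Measurements are
lognormal — effects are additive on the log scale and the linear-scale
values are right-skewed and strictly positive, the standard model for
cytokine concentrations:

    value = exp(baseline + condition_effect + material_effect
                + donor_effect + noise)

The donor effect is drawn once per (donor, readout) and shared across all
materials and conditions; it is the component that makes donor-paired
testing informative.  Values that fall below a per-readout detection limit
(LOD) are flagged and replaced according to a substitution policy
(``half_lod`` by default, the conventional censored-value imputation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "default_config",
    "generate_dataset",
    "literature_scenario",
    "null_scenario",
    "restrict_conditions",
    "MATERIALS",
    "CONDITIONS",
    "READOUTS",
    "LITERATURE_ORDER",
]

#: The five test materials of the reference screen.
MATERIALS = ("glass", "titanium", "PTFE", "silicone", "PE")

#: The five scored test conditions (surface/stimulus scenarios).
CONDITIONS = (
    "without treatment",
    "LPS",
    "native plasma",
    "heat-inactivated plasma",
    "IL-4",
)

#: The seven quantitative readout factors: ATP-based viability plus six
#: cytokines measured in the culture supernatant.
READOUTS = ("CellTiter", "IL-1b", "IL-6", "TNF-a", "IL-8", "IL-10", "TGF-b1")

#: Literature consensus ordering, lowest to highest fibrotic potential.
LITERATURE_ORDER = ("PE", "titanium", "PTFE", "silicone")

_LOD_POLICIES = ("half_lod", "zero", "lod")

TABLE_COLUMNS = ["donor_id", "material", "condition", "readout", "value", "below_lod"]


def _per_readout(value, readouts, name: str) -> dict[str, float]:
    """Broadcast a scalar to all readouts, or validate a per-readout map."""
    if isinstance(value, Mapping):
        out = {r: float(value.get(r, 0.0)) for r in readouts}
        unknown = set(value) - set(readouts)
        if unknown:
            raise ConfigError(f"{name}: unknown readout labels {sorted(unknown)}")
        return out
    return {r: float(value) for r in readouts}


@dataclass
class SimulationConfig:
    """Full generative specification for one synthetic screen.

    Effects are nested mappings: ``condition_log_effect[readout][condition]``
    and ``material_log_effect[readout][condition][material]``, both additive
    on the log scale; absent keys mean a zero effect.  ``donor_sd``,
    ``noise_sd``, ``baseline_log_mean`` and ``lod`` are per-readout maps
    (a scalar is broadcast to all readouts on construction).
    """

    n_donors: int = 10
    materials: tuple[str, ...] = MATERIALS
    conditions: tuple[str, ...] = CONDITIONS
    readouts: tuple[str, ...] = READOUTS
    baseline_log_mean: dict = field(default_factory=dict)
    material_log_effect: dict = field(default_factory=dict)
    condition_log_effect: dict = field(default_factory=dict)
    donor_sd: dict = field(default_factory=lambda: 0.8)
    noise_sd: dict = field(default_factory=lambda: 0.5)
    lod: dict = field(default_factory=dict)
    lod_policy: str = "half_lod"
    seed: int = 0

    def __post_init__(self) -> None:
        self.materials = tuple(self.materials)
        self.conditions = tuple(self.conditions)
        self.readouts = tuple(self.readouts)
        if self.n_donors < 2:
            raise ConfigError(f"n_donors must be >= 2, got {self.n_donors}")
        for name, labels in (
            ("materials", self.materials),
            ("conditions", self.conditions),
            ("readouts", self.readouts),
        ):
            if not labels:
                raise ConfigError(f"{name} must be non-empty")
            if len(set(labels)) != len(labels):
                raise ConfigError(f"{name} contains duplicate labels")
        self.baseline_log_mean = _per_readout(
            self.baseline_log_mean, self.readouts, "baseline_log_mean"
        )
        self.donor_sd = _per_readout(self.donor_sd, self.readouts, "donor_sd")
        self.noise_sd = _per_readout(self.noise_sd, self.readouts, "noise_sd")
        self.lod = _per_readout(self.lod, self.readouts, "lod")
        for name, mapping in (("donor_sd", self.donor_sd), ("noise_sd", self.noise_sd), ("lod", self.lod)):
            for r, v in mapping.items():
                if v < 0:
                    raise ConfigError(f"{name}[{r}] must be >= 0, got {v}")
        if self.lod_policy not in _LOD_POLICIES:
            raise ConfigError(
                f"lod_policy must be one of {_LOD_POLICIES}, got {self.lod_policy!r}"
            )
        self._check_effect_keys("condition_log_effect", self.condition_log_effect, depth=2)
        self._check_effect_keys("material_log_effect", self.material_log_effect, depth=3)

    def _check_effect_keys(self, name: str, effects: Mapping, depth: int) -> None:
        for readout, sub in effects.items():
            if readout not in self.readouts:
                raise ConfigError(f"{name}: unknown readout {readout!r}")
            for condition, subsub in sub.items():
                if condition not in self.conditions:
                    raise ConfigError(f"{name}: unknown condition {condition!r}")
                if depth == 3:
                    for material in subsub:
                        if material not in self.materials:
                            raise ConfigError(f"{name}: unknown material {material!r}")

    # -- effect lookups -------------------------------------------------
    def condition_effect(self, readout: str, condition: str) -> float:
        return float(self.condition_log_effect.get(readout, {}).get(condition, 0.0))

    def material_effect(self, readout: str, condition: str, material: str) -> float:
        return float(
            self.material_log_effect.get(readout, {}).get(condition, {}).get(material, 0.0)
        )

    @property
    def donor_ids(self) -> list[str]:
        width = len(str(self.n_donors))
        return [f"D{i + 1:0{width}d}" for i in range(self.n_donors)]

    def n_rows(self) -> int:
        return (
            self.n_donors * len(self.materials) * len(self.conditions) * len(self.readouts)
        )


def default_config(seed: int = 0, n_donors: int = 10) -> SimulationConfig:
    """The reference study design: 10 donors x 5 materials x 5 conditions
    x 7 readouts, with condition effects emulating the qualitative pattern
    of a macrophage screen (LPS boosts pro-inflammatory cytokines and
    depresses ATP; IL-4 raises viability and depresses IL-6/IL-8) and a
    detection limit that censors IL-1b for most donor cells.

    Material effects default to zero; plant them with
    :func:`literature_scenario` or leave them null for calibration runs.
    Baselines are log pg/ml for cytokines and log relative luminescence
    units for CellTiter.  All magnitudes are documented modelling
    assumptions, not estimates from data.
    """
    baseline = {
        "CellTiter": np.log(5e4),
        "IL-1b": np.log(3.0),
        "IL-6": np.log(250.0),
        "TNF-a": np.log(90.0),
        "IL-8": np.log(700.0),
        "IL-10": np.log(30.0),
        "TGF-b1": np.log(1100.0),
    }
    cond_eff: dict[str, dict[str, float]] = {
        "CellTiter": {"LPS": -0.6, "IL-4": 0.6},
        "IL-1b": {"LPS": 2.5},
        "IL-6": {"LPS": 2.5, "IL-4": -1.0, "heat-inactivated plasma": -0.4},
        "TNF-a": {"LPS": 2.5, "heat-inactivated plasma": 0.5},
        "IL-8": {"LPS": 2.0, "IL-4": -1.0},
        "IL-10": {"LPS": 1.0, "IL-4": 0.5},
        "TGF-b1": {},  # basal medium component, condition-insensitive
    }
    # CBA-like detection limits (pg/ml); CellTiter luminescence has none.
    lod = {
        "CellTiter": 0.0,
        "IL-1b": 7.2,
        "IL-6": 2.5,
        "TNF-a": 3.7,
        "IL-8": 3.6,
        "IL-10": 3.3,
        "TGF-b1": 60.0,
    }
    return SimulationConfig(
        n_donors=n_donors,
        baseline_log_mean=baseline,
        condition_log_effect=cond_eff,
        donor_sd=0.8,
        noise_sd=0.5,
        lod=lod,
        seed=seed,
    )


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one complete readout table.

    Returns a long-format DataFrame with columns
    ``donor_id, material, condition, readout, value, below_lod`` and exactly
    ``n_donors * K * C * R`` rows.  Deterministic given ``config.seed``: the
    donor random effects are drawn first (one per donor x readout), then the
    residual noise in fixed row order.
    """
    rng = np.random.default_rng(config.seed)
    donors = config.donor_ids
    R = len(config.readouts)

    donor_effects = rng.normal(size=(config.n_donors, R))
    donor_sd = np.array([config.donor_sd[r] for r in config.readouts])
    donor_effects = donor_effects * donor_sd  # (donor, readout)

    index = pd.MultiIndex.from_product(
        [donors, config.materials, config.conditions, config.readouts],
        names=["donor_id", "material", "condition", "readout"],
    )
    df = index.to_frame(index=False)

    base = df["readout"].map(config.baseline_log_mean).to_numpy(float)
    noise_sd = df["readout"].map(config.noise_sd).to_numpy(float)
    cond = np.array(
        [config.condition_effect(r, c) for r, c in zip(df["readout"], df["condition"])]
    )
    mat = np.array(
        [
            config.material_effect(r, c, m)
            for r, c, m in zip(df["readout"], df["condition"], df["material"])
        ]
    )
    donor_idx = df["donor_id"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    readout_idx = df["readout"].map(
        {r: j for j, r in enumerate(config.readouts)}
    ).to_numpy()
    donor = donor_effects[donor_idx, readout_idx]
    noise = rng.normal(size=len(df)) * noise_sd

    value = np.exp(base + cond + mat + donor + noise)
    lod = df["readout"].map(config.lod).to_numpy(float)
    below = value < lod
    substitute = {"half_lod": lod / 2.0, "zero": np.zeros_like(lod), "lod": lod}[
        config.lod_policy
    ]
    value = np.where(below, substitute, value)

    df["value"] = value
    df["below_lod"] = below
    return df


def literature_scenario(base: SimulationConfig, effect_step: float) -> SimulationConfig:
    """Plant the literature fibrotic ordering PE < titanium < PTFE < silicone.

    Material log-effects become an arithmetic progression with spacing
    ``effect_step`` in that order, identical across all readouts and
    conditions; glass (if present) keeps effect 0.  The returned config is a
    deep copy; ``base`` is untouched.
    """
    if effect_step < 0:
        raise ConfigError(f"effect_step must be >= 0, got {effect_step}")
    missing = [m for m in LITERATURE_ORDER if m not in base.materials]
    if missing:
        raise ConfigError(f"materials missing from config: {missing}")
    steps = {m: i * float(effect_step) for i, m in enumerate(LITERATURE_ORDER)}
    effects = {
        r: {c: dict(steps) for c in base.conditions} for r in base.readouts
    }
    out = copy.deepcopy(base)
    out.material_log_effect = effects
    out.__post_init__()
    return out


def restrict_conditions(base: SimulationConfig, conditions) -> SimulationConfig:
    """A copy of ``base`` limited to the given conditions, with effect maps
    filtered accordingly.  Useful for single-condition calibration runs."""
    conditions = tuple(conditions)
    missing = [c for c in conditions if c not in base.conditions]
    if missing:
        raise ConfigError(f"conditions not in config: {missing}")
    out = copy.deepcopy(base)
    out.conditions = conditions
    out.condition_log_effect = {
        r: {c: v for c, v in sub.items() if c in conditions}
        for r, sub in out.condition_log_effect.items()
    }
    out.material_log_effect = {
        r: {c: v for c, v in sub.items() if c in conditions}
        for r, sub in out.material_log_effect.items()
    }
    out.__post_init__()
    return out


def null_scenario(base: SimulationConfig) -> SimulationConfig:
    """Zero out all material and condition effects; everything else unchanged.

    Under the null every material (and condition) draws from the same
    distribution within a readout, which is what Type-I-error calibration
    of the downstream scoring needs.
    """
    out = copy.deepcopy(base)
    out.material_log_effect = {}
    out.condition_log_effect = {}
    out.__post_init__()
    return out
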