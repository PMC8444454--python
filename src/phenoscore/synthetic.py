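"""Synthetic cohorts and DEG contrast tables with known ground truth.

The generator emulates the structure of a maternal-environment mouse
study: three offspring groups — fully wildtype controls (WT), genetically
wildtype littermates of transgenics that shared the adverse maternal
environment (NTg), and transgenic offspring (Tg) — crossed with two
sexes, each animal measured on a battery of behavioural tests whose
outcome measures map to behavioural traits.

Group effects are *planted* on the raw measure scales, as mean shifts in
reference-population standard-deviation units oriented so that the shift
increases the trait deficit; NTg effects default to half the Tg effect,
mirroring an environment that impacts transgenic offspring more than
their littermates.  Latency measures are truncated at zero and
right-censored at the session maximum when a time-out fires.  All
randomness flows from one integer seed, and the planted truth is
returned alongside the records for parameter-recovery tests.

The DEG simulator produces the three pairwise contrast tables (TgWT,
TgNTg, NTgWT) with planted memberships: genes significant in TgWT and
TgNTg (gene effects), in TgWT and NTgWT (environment effects), and in
TgWT alone.  Planted genes receive p-values far below any calling
threshold by construction; the differential-expression model itself is
not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .deg import CONTRASTS, ContrastTable, bh_adjust
from .traitmap import TRAITS, TraitEntry, TraitMap

__all__ = [
    "ConfigError",
    "MeasureDef",
    "TestDef",
    "CohortConfig",
    "SimulatedCohort",
    "DEGSimConfig",
    "SimulatedDEG",
    "default_battery",
    "compact_battery",
    "battery_trait_map",
    "generate_cohort",
    "generate_deg_tables",
    "plant_deficit",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MeasureDef:
    """One outcome measure: its trait mapping and reference-population scale."""

    name: str
    trait: str
    direction: int  # +1: larger raw value = more deficit; -1: less
    mean: float
    sd: float
    latency_type: bool = False
    negative_allowed: bool = False
    session_max: float | None = None  # censoring point for latency measures

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ConfigError(f"unknown trait {self.trait!r} for measure {self.name!r}")
        if self.direction not in (+1, -1):
            raise ConfigError(f"direction must be +1/-1 for measure {self.name!r}")
        if self.sd <= 0:
            raise ConfigError(f"sd must be positive for measure {self.name!r}")


@dataclass(frozen=True)
class TestDef:
    name: str
    measures: tuple[MeasureDef, ...]

    __test__ = False  # behavioural test definition, not a pytest item


def default_battery() -> tuple[TestDef, ...]:
    """A nine-trait behavioural battery with realistic reference scales.

    Means and standard deviations are the generator's own choices of
    plausible magnitudes for each apparatus (seconds, counts, percent);
    they set the scale on which effects in sd units are planted.
    """
    M = MeasureDef
    return (
        TestDef("light_dark_box", (
            M("time_in_light", "anxiety", -1, 120.0, 40.0),
            M("crosses_to_light", "anxiety", -1, 20.0, 6.0),
            M("latency_to_light", "anxiety", +1, 30.0, 15.0,
              latency_type=True, session_max=300.0),
        )),
        TestDef("exploratory_reluctance", (
            M("latency_to_approach", "anxiety", +1, 25.0, 12.0,
              latency_type=True, session_max=180.0),
        )),
        TestDef("social_interaction", (
            M("time_following", "sociability", +1, 40.0, 15.0),
            M("time_sniffing", "sociability", +1, 60.0, 20.0),
        )),
        TestDef("social_propinquity", (
            M("time_sharing_tube", "sociability", +1, 200.0, 60.0),
            M("time_tube_vacant_pct", "anxiety", +1, 30.0, 12.0),
        )),
        TestDef("odour_discrimination", (
            M("novel_visit_difference", "sociability", +1, 2.0, 3.0,
              negative_allowed=True),
        )),
        TestDef("classical_conditioning", (
            M("acquisition_slope", "cognition", -1, 1.5, 0.8, negative_allowed=True),
            M("consolidation_cs_responses", "cognition", -1, 25.0, 8.0),
            M("habituation_magazine_entries", "motivation", -1, 30.0, 10.0),
        )),
        TestDef("lick_cluster_analysis", (
            M("mean_lick_cluster_size", "depression", -1, 35.0, 10.0),
            M("concentration_response_slope", "depression", -1, 2.0, 1.0,
              negative_allowed=True),
        )),
        TestDef("reward_consumption", (
            M("amount_consumed", "motivation", -1, 1.2, 0.4),
        )),
        TestDef("fcm_assay", (
            M("baseline_fcm", "stress", +1, 60.0, 20.0),
            M("stressed_fcm", "stress", +1, 110.0, 30.0),
            M("fcm_percent_change", "stress", +1, 80.0, 40.0, negative_allowed=True),
        )),
        TestDef("five_choice", (
            M("accuracy", "attention", -1, 75.0, 10.0),
            M("response_time", "attention", +1, 1.2, 0.3),
            M("n_timeouts", "attention", +1, 8.0, 3.0),
            M("anticipatory_responses", "impulsivity", +1, 12.0, 5.0),
            M("total_trials", "motivation", -1, 90.0, 15.0),
        )),
        TestDef("open_field", (
            M("distance_moved", "activity", -1, 40.0, 10.0),
            M("velocity", "activity", -1, 5.0, 1.2),
        )),
        TestDef("locomotor_activity", (
            M("beam_breaks", "activity", -1, 1500.0, 400.0),
        )),
    )


def compact_battery() -> tuple[TestDef, ...]:
    """Anxiety-only two-test battery for Monte-Carlo studies.

    Scoring and statistics of one trait depend only on that trait's
    measures, so calibration and power studies of the anxiety GROUP term
    use this battery; results are identical to running the full battery
    and discarding the other traits.
    """
    M = MeasureDef
    return (
        TestDef("light_dark_box", (
            M("time_in_light", "anxiety", -1, 120.0, 40.0),
            M("crosses_to_light", "anxiety", -1, 20.0, 6.0),
            M("latency_to_light", "anxiety", +1, 30.0, 15.0,
              latency_type=True, session_max=300.0),
        )),
        TestDef("exploratory_reluctance", (
            M("latency_to_approach", "anxiety", +1, 25.0, 12.0,
              latency_type=True, session_max=180.0),
        )),
    )


def battery_trait_map(tests: Sequence[TestDef]) -> TraitMap:
    """Derive the TraitMap implied by a battery definition."""
    entries = {
        (t.name, m.name): TraitEntry(m.trait, m.direction, m.latency_type)
        for t in tests
        for m in t.measures
    }
    return TraitMap(entries)


@dataclass
class CohortConfig:
    """Study design and planted ground truth for one simulated cohort.

    ``planted_effects`` maps ``(group, sex, trait)`` to an effect size in
    reference-population sd units; the shift is applied to every measure
    of that trait in the deficit-increasing direction.  The first group
    is the reference and carries no effect by construction.
    """

    n_per_cell: int = 20
    groups: tuple[str, ...] = ("WT", "NTg", "Tg")
    sexes: tuple[str, ...] = ("F", "M")
    tests: tuple[TestDef, ...] = field(default_factory=default_battery)
    planted_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    timeout_prob: float = 0.08
    ntg_fraction: float = 0.5
    cohort_label: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ConfigError(f"n_per_cell must be >= 2, got {self.n_per_cell}")
        if not (0.0 <= self.timeout_prob <= 1.0):
            raise ConfigError("timeout_prob must be in [0, 1]")
        if len(self.groups) < 2:
            raise ConfigError("need >= 2 groups (first is the reference)")
        traits = {m.trait for t in self.tests for m in t.measures}
        for (group, sex, trait), effect in self.planted_effects.items():
            if group not in self.groups:
                raise ConfigError(f"planted effect for unknown group {group!r}")
            if sex not in self.sexes:
                raise ConfigError(f"planted effect for unknown sex {sex!r}")
            if trait not in traits:
                raise ConfigError(
                    f"planted effect for trait {trait!r} with no measures in battery"
                )
            if group == self.reference_group and effect != 0:
                raise ConfigError("reference-group effect must be 0 by construction")

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    # -------------------------------------------------------------- I/O

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CohortConfig":
        doc = dict(doc)
        if "tests" in doc:
            tests = tuple(
                TestDef(
                    t["name"],
                    tuple(MeasureDef(**m) for m in t["measures"]),
                )
                for t in doc["tests"]
            )
            doc["tests"] = tests
        if "planted_effects" in doc:
            doc["planted_effects"] = {
                (e["group"], e["sex"], e["trait"]): float(e["effect"])
                for e in doc["planted_effects"]
            }
        for key in ("groups", "sexes"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def plant_deficit(
    config: CohortConfig,
    trait: str,
    tg_effect: float,
    *,
    sexes: Sequence[str] | None = None,
    tg_group: str = "Tg",
    ntg_group: str = "NTg",
) -> CohortConfig:
    """Return a config with a Tg deficit planted (NTg at ``ntg_fraction``).

    Mirrors an adverse maternal environment with a greater impact on
    transgenic offspring than on their genetically wildtype littermates.
    """
    effects = dict(config.planted_effects)
    for sex in sexes or config.sexes:
        effects[(tg_group, sex, trait)] = tg_effect
        effects[(ntg_group, sex, trait)] = tg_effect * config.ntg_fraction
    return replace(config, planted_effects=effects)


@dataclass
class SimulatedCohort:
    records: pd.DataFrame
    trait_map: TraitMap
    ground_truth: dict
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw one cohort of measure records from the configured design.

    Reference-population values are Gaussian on each measure's scale;
    planted effects shift the group mean by ``effect * sd`` in the
    deficit direction.  Latency values are truncated at 0 and, with
    probability ``timeout_prob``, censored at the session maximum with
    the time-out flag set.  Other non-negative measures are truncated at
    0; measures flagged ``negative_allowed`` are left unrestricted.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for sex in config.sexes:
        for group in config.groups:
            for i in range(config.n_per_cell):
                animal = f"{group}_{sex}_{i + 1:03d}"
                for test in config.tests:
                    for m in test.measures:
                        effect = config.planted_effects.get((group, sex, m.trait), 0.0)
                        mu = m.mean + effect * m.sd * m.direction
                        value = rng.normal(mu, m.sd)
                        is_timeout = False
                        if m.latency_type:
                            value = max(value, 0.0)
                            if rng.uniform() < config.timeout_prob:
                                value = (
                                    m.session_max
                                    if m.session_max is not None
                                    else m.mean + 3.0 * m.sd
                                )
                                is_timeout = True
                        elif not m.negative_allowed:
                            value = max(value, 0.0)
                        rows.append(
                            {
                                "animal_id": animal,
                                "sex": sex,
                                "group": group,
                                "cohort": config.cohort_label,
                                "test": test.name,
                                "measure": m.name,
                                "value": value,
                                "is_timeout": is_timeout,
                            }
                        )
    records = pd.DataFrame(rows)
    truth = {
        "planted_effects": {
            f"{g}|{s}|{t}": e for (g, s, t), e in sorted(config.planted_effects.items())
        },
        "n_per_cell": config.n_per_cell,
        "groups": list(config.groups),
        "sexes": list(config.sexes),
        "seed": config.seed,
    }
    return SimulatedCohort(
        records=records,
        trait_map=battery_trait_map(config.tests),
        ground_truth=truth,
        config=config,
    )


@dataclass
class DEGSimConfig:
    """Planted structure for the three pairwise DEG contrast tables."""

    n_genes: int = 1000
    n_gene_effect: int = 5
    n_env_effect: int = 3
    n_tgwt_only: int = 2
    effect_log2fc: float = 1.5
    planted_pval: float = 1e-8
    region: str = "Hip"
    sex: str = "M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        for name in ("n_gene_effect", "n_env_effect", "n_tgwt_only"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_gene_effect + self.n_env_effect + self.n_tgwt_only > self.n_genes:
            raise ConfigError("planted counts exceed n_genes")


@dataclass
class SimulatedDEG:
    tables: dict[str, ContrastTable]  # keyed by contrast label
    ground_truth: dict
    config: DEGSimConfig


def generate_deg_tables(config: DEGSimConfig) -> SimulatedDEG:
    """Simulate the TgWT, TgNTg and NTgWT contrast tables.

    Planted genes get raw p-values at ``planted_pval`` scale in every
    contrast they belong to, hence adjusted p-values far below any
    calling threshold; null genes draw uniform p-values.  Fold-change
    signs are random per gene but consistent across contrasts.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])
    n_planted = config.n_gene_effect + config.n_env_effect + config.n_tgwt_only
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    ge = genes[planted_idx[: config.n_gene_effect]]
    env = genes[planted_idx[config.n_gene_effect : config.n_gene_effect + config.n_env_effect]]
    only = genes[planted_idx[config.n_gene_effect + config.n_env_effect :]]
    signs = dict(zip(genes[planted_idx], rng.choice([-1.0, 1.0], size=n_planted)))

    membership = {
        "TgWT": set(ge) | set(env) | set(only),
        "TgNTg": set(ge),
        "NTgWT": set(env),
    }
    tables: dict[str, ContrastTable] = {}
    for contrast in CONTRASTS:
        pval = rng.uniform(0.0, 1.0, size=config.n_genes)
        log2fc = rng.normal(0.0, 0.2, size=config.n_genes)
        for j, g in enumerate(genes):
            if g in membership[contrast]:
                pval[j] = config.planted_pval * rng.uniform(0.5, 1.0)
                log2fc[j] = signs[g] * config.effect_log2fc * rng.uniform(0.8, 1.2)
        data = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": log2fc,
                "pval": pval,
                "adj_pval": bh_adjust(pval),
            }
        )
        tables[contrast] = ContrastTable(
            contrast=contrast, data=data, region=config.region, sex=config.sex
        )
    truth = {
        "gene_effect": sorted(ge.tolist()),
        "env_effect": sorted(env.tolist()),
        "tgwt_only": sorted(only.tolist()),
        "signs": {g: int(s) for g, s in sorted(signs.items())},
        "seed": config.seed,
    }
    return SimulatedDEG(tables=tables, ground_truth=truth, config=config)
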