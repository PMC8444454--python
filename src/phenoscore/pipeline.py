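"""End-to-end orchestration: simulate/load -> score -> prevalence -> stats -> DEG.

Every run is driven by a :class:`RunConfig`; fixed inputs and seed give
byte-identical output bundles, and each bundle carries a manifest with
the configuration hash, package version and per-file record counts so
that exclusions (missing values, time-outs) are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deg import attribute_effects, summarize_counts
from .group_stats import StatsError, one_way_anova, pairwise_posthoc, two_way_anova
from .io import read_deg_table, read_measures, write_json, write_measures
from .prevalence import build_heatmap, compute_prevalence
from .scoring import ScoreSet, score_cohort
from .synthetic import CohortConfig, generate_cohort
from .traitmap import TraitMap

log = logging.getLogger("phenoscore")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All options of one pipeline run, with recorded defaults.

    Either ``measures_path`` + ``trait_map_path`` point at existing data,
    or ``simulate`` holds an inline cohort configuration.  DEG paths are
    optional; when present, attribution runs on them.
    """

    out_dir: str = "phenoscore_out"
    measures_path: str | None = None
    trait_map_path: str | None = None
    simulate: CohortConfig | None = None
    deg_tgwt_path: str | None = None
    deg_tgntg_path: str | None = None
    deg_ntgwt_path: str | None = None
    deg_region: str = ""
    deg_sex: str = ""
    stratum: str = "sex_cohort"  # or "sex"
    timeout_policy: str = "deficit"
    prevalence_mode: str = "relative"  # or "ratio"
    reference_group: str = "WT"
    ss_type: str = "auto"
    posthoc_method: str = "tukey"
    alpha: float = 0.05
    seed: int = 0

    def stratum_cols(self) -> tuple[str, ...]:
        if self.stratum == "sex_cohort":
            return ("sex", "cohort")
        if self.stratum == "sex":
            return ("sex",)
        raise PipelineError(f"unknown stratum {self.stratum!r}")

    def to_jsonable(self) -> dict:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir", None)  # bundle location is not part of the run identity
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["planted_effects"] = {
                f"{g}|{s}|{t}": e
                for (g, s, t), e in sorted(self.simulate.planted_effects.items())
            }
            doc["simulate"] = sim
        return doc

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "simulate" in doc and doc["simulate"] is not None:
            doc["simulate"] = CohortConfig.from_dict(doc["simulate"])
        return cls(**doc)


@dataclass
class PipelineResult:
    score_set: ScoreSet
    prevalence: pd.DataFrame
    heatmap: pd.DataFrame
    stats: pd.DataFrame
    attribution: dict | None
    manifest: dict


def trait_statistics(
    unified_scores: pd.DataFrame,
    *,
    ss_type: str = "auto",
    posthoc_method: str = "tukey",
) -> pd.DataFrame:
    """Whole-cohort two-way and sex-split one-way ANOVA per trait.

    Both analyses are computed unconditionally for every trait, with
    pairwise post-hoc contrasts on the sex-split scores; interpretation
    (e.g. whether to gate on the interaction term) is left to the reader.
    Returns a tidy frame: trait, analysis, term, statistic, df1, df2, p,
    p_adj, method.
    """
    rows: list[dict] = []
    for trait, sub in unified_scores.groupby("trait", sort=True):
        try:
            res = two_way_anova(
                sub["score"], sub["group"], sub["sex"], ss_type=ss_type
            )
            for term in res.terms.values():
                rows.append(
                    {
                        "trait": trait, "analysis": "two_way", "term": term.term,
                        "statistic": term.F, "df1": term.df, "df2": res.residual_df,
                        "p": term.p, "p_adj": float("nan"), "method": res.ss_type,
                    }
                )
        except StatsError as exc:
            log.warning("two-way ANOVA skipped for trait %s: %s", trait, exc)
        for sex, bysex in sub.groupby("sex", sort=True):
            try:
                res1 = one_way_anova(bysex["score"], bysex["group"])
            except StatsError as exc:
                log.warning("one-way ANOVA skipped (%s, %s): %s", trait, sex, exc)
                continue
            term = res1["GROUP"]
            rows.append(
                {
                    "trait": trait, "analysis": f"one_way[{sex}]", "term": "GROUP",
                    "statistic": term.F, "df1": term.df, "df2": res1.residual_df,
                    "p": term.p, "p_adj": float("nan"), "method": "classical",
                }
            )
            post = pairwise_posthoc(
                bysex["score"], bysex["group"], method=posthoc_method
            )
            for _, pr in post.iterrows():
                rows.append(
                    {
                        "trait": trait, "analysis": f"posthoc[{sex}]", "term": pr["pair"],
                        "statistic": pr["t"], "df1": 1, "df2": pr["df"],
                        "p": pr["p_raw"], "p_adj": pr["p_adj"], "method": pr["method"],
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages and write the output bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "config": config.to_jsonable(),
        "files": {},
    }

    def _record(name: str, n: int) -> None:
        manifest["files"][name] = {"rows": n}

    # ---- stage: acquire measures -------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            cohort = generate_cohort(sim_cfg)
            records, trait_map = cohort.records, cohort.trait_map
            write_measures(records, out / "measure_records.csv")
            write_json(cohort.ground_truth, out / "ground_truth.json")
            _record("measure_records.csv", len(records))
        elif config.measures_path and config.trait_map_path:
            records = read_measures(config.measures_path)
            trait_map = TraitMap.from_yaml(config.trait_map_path)
        else:
            raise PipelineError(
                "config needs either `simulate` or both `measures_path` and "
                "`trait_map_path`"
            )
    except Exception as exc:
        raise PipelineError(f"stage 'measures' failed: {exc}") from exc

    # ---- stage: scoring ----------------------------------------------
    try:
        score_set = score_cohort(
            records,
            trait_map,
            stratum_cols=config.stratum_cols(),
            timeout_policy=config.timeout_policy,
        )
        long = score_set.to_long()
        long.to_csv(out / "scores.csv", index=False)
        score_set.unified_scores.to_csv(out / "unified_scores.csv", index=False)
        _record("scores.csv", len(long))
        _record("unified_scores.csv", len(score_set.unified_scores))
        n_timeout = int(records["is_timeout"].sum())
        n_missing = int(records["value"].isna().sum())
        log.info("scoring: %d records, %d timeouts, %d missing", len(records),
                 n_timeout, n_missing)
        manifest["exclusions"] = {"timeouts": n_timeout, "missing_values": n_missing}
    except Exception as exc:
        raise PipelineError(f"stage 'scoring' failed: {exc}") from exc

    # ---- stage: prevalence -------------------------------------------
    try:
        prev = compute_prevalence(
            score_set.unified_scores,
            reference_group=config.reference_group,
            mode=config.prevalence_mode,
        )
        heat = build_heatmap(prev, reference_group=config.reference_group)
        prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)
        heat.to_csv(out / "heatmap.csv")
        _record("prevalence.tsv", len(prev))
        _record("heatmap.csv", len(heat))
    except Exception as exc:
        raise PipelineError(f"stage 'prevalence' failed: {exc}") from exc

    # ---- stage: group statistics -------------------------------------
    try:
        stats = trait_statistics(
            score_set.unified_scores,
            ss_type=config.ss_type,
            posthoc_method=config.posthoc_method,
        )
        stats.to_csv(out / "stats.tsv", sep="\t", index=False)
        _record("stats.tsv", len(stats))
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc

    # ---- stage: DEG attribution (optional) ---------------------------
    attribution = None
    deg_paths = (config.deg_tgwt_path, config.deg_tgntg_path, config.deg_ntgwt_path)
    if any(deg_paths):
        if not all(deg_paths):
            raise PipelineError(
                "stage 'deg' failed: all three DEG contrast paths are required"
            )
        try:
            tgwt = read_deg_table(
                deg_paths[0], contrast="TgWT",
                region=config.deg_region, sex=config.deg_sex,
            )
            tgntg = read_deg_table(
                deg_paths[1], contrast="TgNTg",
                region=config.deg_region, sex=config.deg_sex,
            )
            ntgwt = read_deg_table(
                deg_paths[2], contrast="NTgWT",
                region=config.deg_region, sex=config.deg_sex,
            )
            result = attribute_effects(tgwt, tgntg, ntgwt, alpha=config.alpha)
            attribution = result.to_dict()
            write_json(attribution, out / "attribution.json")
            counts = summarize_counts([result])
            counts.to_csv(out / "attribution_counts.tsv", sep="\t", index=False)
            _record("attribution_counts.tsv", len(counts))
        except Exception as exc:
            raise PipelineError(f"stage 'deg' failed: {exc}") from exc

    write_json(manifest, out / "manifest.json")
    return PipelineResult(
        score_set=score_set,
        prevalence=prev,
        heatmap=heat,
        stats=stats,
        attribution=attribution,
        manifest=manifest,
    )
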