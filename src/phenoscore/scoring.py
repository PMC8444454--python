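"""Unified behavioural trait scoring.

Raw outcome measures from a behavioural battery are combined into a
single composite per animal and trait in three steps:

1. **Measure score** ``X(i) = M(i) / M(m)``, where ``M(i)`` is the
   animal's raw value and ``M(m)`` the maximum raw value in the
   normalization stratum (by default, animals of the same sex and
   cohort).  Negative raw values score 0.  Time-outs on latency-type
   measures score 1 (failure to act is the maximal deficit).  Measures
   negatively associated with the trait are inverted, ``X(i) -> 1 - X(i)``,
   so that a greater score always indicates more of the trait.
2. **Test score** ``T(i)``: the mean of an animal's measure scores for
   all measures of one behavioural test mapped to one trait.
3. **Unified score**: the mean of the animal's test scores across the
   tests probing that trait, so every test carries equal weight
   regardless of how many measures it contributes.

All scores lie in [0, 1]; missing values are excluded from every mean,
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .traitmap import TraitMap

__all__ = [
    "ScoreSet",
    "ScoringError",
    "normalize_measure",
    "score_measures",
    "compute_test_scores",
    "compute_unified_scores",
    "score_cohort",
]

#: Columns identifying an animal in every score table.
ANIMAL_COLS = ["animal_id", "sex", "group", "cohort"]


class ScoringError(ValueError):
    pass


@dataclass
class ScoreSet:
    """All three score levels for one dataset.

    Attributes
    ----------
    measure_scores
        Tidy frame: animal columns + ``test, measure, trait, score``.
    test_scores
        Tidy frame: animal columns + ``trait, test, score`` (the T(i) values).
    unified_scores
        Tidy frame: animal columns + ``trait, score``.
    normalization
        One row per (stratum, test, measure) with the maximum ``m_max``
        used as the denominator and a ``degenerate`` flag.
    stratum_cols
        Columns defining the normalization stratum (e.g. ``["sex", "cohort"]``).
    """

    measure_scores: pd.DataFrame
    test_scores: pd.DataFrame
    unified_scores: pd.DataFrame
    normalization: pd.DataFrame
    stratum_cols: list[str] = field(default_factory=lambda: ["sex", "cohort"])

    def to_long(self) -> pd.DataFrame:
        """Stack the three levels into one tidy export frame."""
        m = self.measure_scores.assign(level="measure")
        t = self.test_scores.assign(level="test", measure=pd.NA)
        u = self.unified_scores.assign(level="unified", test=pd.NA, measure=pd.NA)
        cols = ANIMAL_COLS + ["level", "trait", "test", "measure", "score"]
        out = pd.concat([m[cols], t[cols], u[cols]], ignore_index=True)
        return out.sort_values(cols[:-1], kind="stable").reset_index(drop=True)


def normalize_measure(
    values: Sequence[float] | np.ndarray,
    direction: int,
    timeouts: Sequence[bool] | np.ndarray | None = None,
    *,
    timeout_policy: str = "deficit",
    clamp_after_inversion: bool = False,
) -> np.ndarray:
    """Normalize one measure's raw values within one stratum to [0, 1].

    Pipeline order: ratio to the stratum maximum, negative-value clamp to 0,
    time-out override to 1, then inversion for ``direction == -1``.  The
    maximum is taken over non-missing, non-timeout values only, so censoring
    cannot inflate the denominator.

    Parameters
    ----------
    values
        Raw values for every animal in the stratum (NaN = missing).
    direction
        ``+1`` (larger raw value = more of the trait) or ``-1`` (= less;
        the score is inverted).
    timeouts
        Per-animal censoring flags; only meaningful for latency measures.
    timeout_policy
        ``"deficit"`` (default): a time-out always yields a *final* score
        of 1 — failure to act is the maximal deficit even on an inverted
        measure.  ``"literal"``: the time-out sets the pre-inversion score
        to 1, so an inverted measure scores 0.
    clamp_after_inversion
        If True, the negative-value clamp to 0 is applied to the final
        (post-inversion) score instead of the raw ratio.

    Returns
    -------
    numpy.ndarray
        Scores in [0, 1]; NaN where the input was missing, or everywhere
        if the stratum is degenerate (no positive non-timeout value).
    """
    if direction not in (+1, -1):
        raise ScoringError(f"direction must be +1 or -1, got {direction!r}")
    if timeout_policy not in ("deficit", "literal"):
        raise ScoringError(f"unknown timeout_policy {timeout_policy!r}")

    v = np.asarray(values, dtype=float)
    to = (
        np.zeros(v.shape, dtype=bool)
        if timeouts is None
        else np.asarray(timeouts, dtype=bool)
    )
    if to.shape != v.shape:
        raise ScoringError("values and timeouts must have equal length")
    missing = np.isnan(v)
    if missing.all():
        raise ScoringError("all values missing in stratum")

    usable = ~missing & ~to
    m_max = np.max(v[usable]) if usable.any() else np.nan
    if not np.isfinite(m_max) or m_max <= 0:
        # Degenerate stratum: no positive value to anchor the scale.
        return np.full(v.shape, np.nan)

    score = v / m_max
    negative = ~missing & (v < 0)
    if not clamp_after_inversion:
        score[negative] = 0.0
    if timeout_policy == "literal":
        score[to & ~missing] = 1.0
    if direction == -1:
        score = 1.0 - score
    if clamp_after_inversion:
        score[negative] = 0.0
    if timeout_policy == "deficit":
        score[to & ~missing] = 1.0
    score = np.clip(score, 0.0, 1.0)
    score[missing] = np.nan
    return score


def _check_trait_map_covers(records: pd.DataFrame, trait_map: TraitMap) -> None:
    pairs = set(map(tuple, records[["test", "measure"]].drop_duplicates().to_numpy()))
    unmapped = pairs - set(trait_map)
    if unmapped:
        raise ScoringError(
            f"(test, measure) pairs missing from trait map: {sorted(unmapped)}"
        )


def score_measures(
    records: pd.DataFrame,
    trait_map: TraitMap,
    *,
    stratum_cols: Sequence[str] = ("sex", "cohort"),
    timeout_policy: str = "deficit",
    clamp_after_inversion: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute measure scores X(i) for a long-format record table.

    ``records`` must have columns ``animal_id, sex, group, cohort, test,
    measure, value, is_timeout``.  Normalization is performed independently
    within each ``stratum_cols`` stratum (default sex-by-cohort; pass
    ``("sex",)`` to pool cohorts).

    Returns ``(measure_scores, normalization)``.
    """
    required = set(ANIMAL_COLS + ["test", "measure", "value", "is_timeout"])
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ScoringError(f"record table missing columns: {sorted(missing_cols)}")
    stratum_cols = list(stratum_cols)
    _check_trait_map_covers(records, trait_map)

    dup = records.duplicated(subset=["animal_id", "test", "measure"])
    if dup.any():
        raise ScoringError(
            "duplicate (animal_id, test, measure) records: "
            f"{records.loc[dup, ['animal_id', 'test', 'measure']].head().to_dict('records')}"
        )

    out_parts: list[pd.DataFrame] = []
    norm_rows: list[dict] = []
    for keys, grp in records.groupby(stratum_cols + ["test", "measure"], sort=True):
        *stratum, test, measure = keys
        entry = trait_map[(test, measure)]
        timeouts = grp["is_timeout"].fillna(False).astype(bool).to_numpy()
        if timeouts.any() and not entry.latency_type:
            raise ScoringError(
                f"time-out flagged on non-latency measure ({test!r}, {measure!r})"
            )
        values = grp["value"].to_numpy(dtype=float)
        usable = ~np.isnan(values) & ~timeouts
        m_max = float(np.max(values[usable])) if usable.any() else np.nan
        degenerate = not (np.isfinite(m_max) and m_max > 0)
        if np.isnan(values).all():
            raise ScoringError(
                f"all values missing for ({test!r}, {measure!r}) in stratum {stratum}"
            )
        if degenerate:
            warnings.warn(
                f"degenerate stratum {dict(zip(stratum_cols, stratum))} for "
                f"({test}, {measure}): no positive non-timeout value; scores set missing",
                stacklevel=2,
            )
            scores = np.full(values.shape, np.nan)
        else:
            scores = normalize_measure(
                values,
                entry.direction,
                timeouts,
                timeout_policy=timeout_policy,
                clamp_after_inversion=clamp_after_inversion,
            )
        part = grp[ANIMAL_COLS].copy()
        part["test"] = test
        part["measure"] = measure
        part["trait"] = entry.trait
        part["score"] = scores
        out_parts.append(part)
        norm_rows.append(
            dict(zip(stratum_cols, stratum))
            | {"test": test, "measure": measure, "m_max": m_max, "degenerate": degenerate}
        )

    measure_scores = pd.concat(out_parts, ignore_index=True)
    normalization = pd.DataFrame(norm_rows)
    return measure_scores, normalization


def compute_test_scores(measure_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-animal test scores T(i): mean measure score per (trait, test).

    Missing measure scores are ignored; T(i) is missing only when every
    contributing measure score is missing.
    """
    grouped = measure_scores.groupby(
        ANIMAL_COLS + ["trait", "test"], sort=True, dropna=False
    )["score"].mean()  # pandas mean skips NaN; all-NaN -> NaN
    return grouped.reset_index()


def compute_unified_scores(test_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-animal unified trait score: unweighted mean of T(i) over tests.

    Each test has equal influence on the composite — a test contributing
    five measures counts exactly as much as a test contributing one.
    Traits with no non-missing test score anywhere are dropped with a
    warning.
    """
    unified = (
        test_scores.groupby(ANIMAL_COLS + ["trait"], sort=True, dropna=False)["score"]
        .mean()
        .reset_index()
    )
    dead = (
        unified.groupby("trait")["score"].apply(lambda s: s.isna().all()).pipe(
            lambda s: s[s].index.tolist()
        )
    )
    if dead:
        warnings.warn(f"traits with no contributing test dropped: {dead}", stacklevel=2)
        unified = unified[~unified["trait"].isin(dead)].reset_index(drop=True)
    return unified


def score_cohort(
    records: pd.DataFrame,
    trait_map: TraitMap,
    *,
    stratum_cols: Sequence[str] = ("sex", "cohort"),
    timeout_policy: str = "deficit",
    clamp_after_inversion: bool = False,
) -> ScoreSet:
    """Run the full measure -> test -> unified scoring pipeline."""
    measure_scores, normalization = score_measures(
        records,
        trait_map,
        stratum_cols=stratum_cols,
        timeout_policy=timeout_policy,
        clamp_after_inversion=clamp_after_inversion,
    )
    test_scores = compute_test_scores(measure_scores)
    unified = compute_unified_scores(test_scores)
    return ScoreSet(
        measure_scores=measure_scores,
        test_scores=test_scores,
        unified_scores=unified,
        normalization=normalization,
        stratum_cols=list(stratum_cols),
    )
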