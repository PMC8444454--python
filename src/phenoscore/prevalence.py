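"""Prevalence-above-median summary and fold-change heatmap.

For each behavioural trait the unified scores of all groups within one
sex are pooled and their median taken; the *prevalence* of a trait
deficit in an experimental group is the proportion of its animals
scoring strictly greater than that cohort median.  Each group's
prevalence is then expressed as a change relative to the wildtype
baseline, giving the cells of a traits-by-(group, sex) summary heatmap:
0 means the group matches the wildtype incidence, positive values an
increased incidence of high-deficit animals, negative a decreased one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceError",
    "PrevalenceChange",
    "cohort_median",
    "prevalence_above_median",
    "prevalence_change",
    "compute_prevalence",
    "build_heatmap",
    "render_heatmap",
]


class PrevalenceError(ValueError):
    pass


@dataclass(frozen=True)
class PrevalenceChange:
    """Relative change in prevalence vs the wildtype baseline.

    When the baseline prevalence is 0 while the group's is positive the
    relative change is undefined; the absolute difference is reported
    instead and ``undefined_baseline`` is set.
    """

    value: float
    undefined_baseline: bool = False


def cohort_median(scores: Sequence[float] | np.ndarray) -> float:
    """Median unified score over all groups pooled within one sex stratum."""
    v = np.asarray(scores, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise PrevalenceError("empty stratum: no non-missing unified scores")
    return float(np.median(v))


def prevalence_above_median(scores: Sequence[float] | np.ndarray, median: float) -> float:
    """Proportion of scores *strictly* greater than the cohort median.

    Ties at the median do not count.
    """
    if not np.isfinite(median):
        raise PrevalenceError(f"median must be finite, got {median!r}")
    v = np.asarray(scores, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise PrevalenceError("empty group")
    return float(np.mean(v > median))


def prevalence_change(
    p_group: float, p_wt: float, *, mode: str = "relative"
) -> PrevalenceChange:
    """Change in prevalence of an experimental group vs the WT baseline.

    ``mode="relative"`` (default) returns ``(p_group - p_wt) / p_wt``, a
    fold-change anchored at 0; ``mode="ratio"`` returns ``p_group / p_wt``.
    A zero baseline with positive group prevalence is flagged and the
    absolute difference returned.  Both prevalences where zero give 0
    (relative) or 1 (ratio).
    """
    for name, p in (("p_group", p_group), ("p_wt", p_wt)):
        if not (0.0 <= p <= 1.0):
            raise PrevalenceError(f"{name} must be in [0, 1], got {p!r}")
    if mode not in ("relative", "ratio"):
        raise PrevalenceError(f"unknown mode {mode!r}")
    if p_wt == 0.0:
        if p_group == 0.0:
            return PrevalenceChange(0.0 if mode == "relative" else 1.0)
        return PrevalenceChange(p_group - p_wt, undefined_baseline=True)
    if mode == "ratio":
        return PrevalenceChange(p_group / p_wt)
    return PrevalenceChange((p_group - p_wt) / p_wt)


def compute_prevalence(
    unified_scores: pd.DataFrame,
    *,
    reference_group: str = "WT",
    mode: str = "relative",
    median_within_sex: bool = True,
) -> pd.DataFrame:
    """Per (sex, group, trait) prevalence table.

    ``unified_scores`` is the tidy frame produced by the scoring stage
    (columns ``animal_id, sex, group, cohort, trait, score``).  The median
    is pooled across all groups, within sex by default (scores are
    sex-normalized; set ``median_within_sex=False`` for a whole-cohort
    median).

    Returns a frame with columns ``sex, group, trait, n, p, p_wt, change,
    undefined_baseline``.
    """
    if reference_group not in set(unified_scores["group"]):
        raise PrevalenceError(f"reference group {reference_group!r} absent from scores")

    median_cols = ["trait", "sex"] if median_within_sex else ["trait"]
    rows: list[dict] = []
    for med_keys, stratum in unified_scores.groupby(median_cols, sort=True):
        med = cohort_median(stratum["score"])
        for (sex, group), grp in stratum.groupby(["sex", "group"], sort=True):
            v = grp["score"].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "sex": sex,
                    "group": group,
                    "trait": med_keys[0],
                    "median": med,
                    "n": int(v.size),
                    "p": prevalence_above_median(v, med) if v.size else np.nan,
                }
            )
    out = pd.DataFrame(rows)

    # attach the WT baseline within (sex, trait) and the change vs it
    base = (
        out[out["group"] == reference_group][["sex", "trait", "p"]]
        .rename(columns={"p": "p_wt"})
    )
    out = out.merge(base, on=["sex", "trait"], how="left")
    changes = [
        prevalence_change(p, p_wt, mode=mode)
        if np.isfinite(p) and np.isfinite(p_wt)
        else PrevalenceChange(np.nan)
        for p, p_wt in zip(out["p"], out["p_wt"])
    ]
    out["change"] = [c.value for c in changes]
    out["undefined_baseline"] = [c.undefined_baseline for c in changes]
    cols = ["sex", "group", "trait", "n", "median", "p", "p_wt", "change", "undefined_baseline"]
    return out[cols].sort_values(["trait", "sex", "group"], kind="stable").reset_index(drop=True)


def build_heatmap(
    prevalence: pd.DataFrame, *, reference_group: str = "WT"
) -> pd.DataFrame:
    """Pivot the prevalence table into the traits x (group, sex) heatmap.

    The reference-group column is omitted (its change is identically 0).
    Missing cells stay missing, never 0.
    """
    body = prevalence[prevalence["group"] != reference_group]
    if body.empty:
        raise PrevalenceError("no non-reference groups in prevalence table")
    mat = body.pivot_table(
        index="trait", columns=["group", "sex"], values="change", aggfunc="first",
        dropna=False,
    )
    mat.columns = [f"{g}_{s}" for g, s in mat.columns]
    return mat.sort_index()


def render_heatmap(matrix: pd.DataFrame, path: str | Path, *, cmap: str = "RdBu_r") -> None:
    """Convenience image export of the heatmap matrix (not a pipeline contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.to_numpy(dtype=float)
    lim = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    fig, ax = plt.subplots(figsize=(1.2 * matrix.shape[1] + 2, 0.5 * matrix.shape[0] + 2))
    im = ax.imshow(data, cmap=cmap, vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="prevalence change vs WT")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
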