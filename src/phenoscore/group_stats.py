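"""Group-comparison statistics: ANOVA and pairwise post-hoc tests.

Implements the testing scheme applied to unified trait scores and
individual outcome measures: a two-way factorial ANOVA with GROUP, SEX
and their interaction, sex-split one-way ANOVA, and all pairwise group
contrasts on the pooled error term with Tukey (studentized-range) or
Bonferroni correction.

The sums of squares are computed here directly — classical factorial
decomposition for balanced designs and Type II (model-comparison) sums
of squares for unbalanced ones, the conventional choice when the
interaction is not the primary focus.  F-distribution and
studentized-range tail probabilities come from scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsError",
    "AnovaTerm",
    "AnovaResult",
    "one_way_anova",
    "two_way_anova",
    "pairwise_posthoc",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    ss: float
    df: int
    F: float
    p: float

    @property
    def ms(self) -> float:
        return self.ss / self.df


@dataclass
class AnovaResult:
    terms: dict[str, AnovaTerm]
    residual_ss: float
    residual_df: int
    total_ss: float
    balanced: bool
    ss_type: str
    degenerate: bool = False
    n_obs: int = 0
    group_levels: list[str] = field(default_factory=list)

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def __getitem__(self, term: str) -> AnovaTerm:
        return self.terms[term]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.term, "ss": t.ss, "df": t.df, "F": t.F, "p": t.p}
            for t in self.terms.values()
        ]
        rows.append(
            {
                "term": "residual",
                "ss": self.residual_ss,
                "df": self.residual_df,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _clean(values, labels, name: str):
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if v.shape != lab.shape:
        raise StatsError(f"values and {name} labels must have equal length")
    keep = ~np.isnan(v)
    return v[keep], lab[keep], keep


def _f_term(ss: float, df: int, ms_res: float, df_res: int) -> tuple[float, float]:
    if ms_res <= 0:
        return np.nan, np.nan
    F = (ss / df) / ms_res
    return F, float(stats.f.sf(F, df, df_res))


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA of ``values`` across ``groups``.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom.  A
    dataset with zero between-group and zero within-group variance has an
    undefined F; the result is flagged ``degenerate`` with NaN statistics.
    """
    v, g, _ = _clean(values, groups, "group")
    levels = sorted(set(g))
    if len(levels) < 2:
        raise StatsError(f"one-way ANOVA needs >= 2 groups, got {levels}")
    counts = {lev: int(np.sum(g == lev)) for lev in levels}
    small = [lev for lev, n in counts.items() if n < 2]
    if small:
        raise StatsError(f"groups with < 2 observations: {small}")

    grand = v.mean()
    ss_between = sum(counts[lev] * (v[g == lev].mean() - grand) ** 2 for lev in levels)
    ss_within = sum(((v[g == lev] - v[g == lev].mean()) ** 2).sum() for lev in levels)
    df_b = len(levels) - 1
    df_w = v.size - len(levels)

    degenerate = ss_within == 0 and ss_between == 0
    if degenerate:
        F = p = np.nan
    else:
        F, p = _f_term(ss_between, df_b, ss_within / df_w, df_w)
        if ss_within == 0:  # perfect separation
            F, p = np.inf, 0.0
    return AnovaResult(
        terms={"GROUP": AnovaTerm("GROUP", float(ss_between), df_b, F, p)},
        residual_ss=float(ss_within),
        residual_df=df_w,
        total_ss=float(ss_between + ss_within),
        balanced=len(set(counts.values())) == 1,
        ss_type="classical",
        degenerate=degenerate,
        n_obs=int(v.size),
        group_levels=[str(x) for x in levels],
    )


def _dummy(labels: np.ndarray, levels: list) -> np.ndarray:
    """Treatment-coded dummy columns (reference = first level)."""
    return np.column_stack([(labels == lev).astype(float) for lev in levels[1:]])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    *,
    names: tuple[str, str] = ("GROUP", "SEX"),
    ss_type: str = "auto",
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction.

    ``ss_type``: ``"classical"`` (balanced factorial decomposition),
    ``"type2"`` (model-comparison Type II sums of squares), or ``"auto"``
    (classical when every cell has equal n, Type II otherwise).  Both
    agree on balanced data.  Every cell of the design must be non-empty.
    """
    v, a, keep = _clean(values, factor_a, names[0])
    b = np.asarray(factor_b, dtype=object)[keep]
    a_levels, b_levels = sorted(set(a)), sorted(set(b))
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise StatsError(
            f"both factors need >= 2 levels; {names[0]}={a_levels}, {names[1]}={b_levels}"
        )
    cells = {}
    for la, lb in itertools.product(a_levels, b_levels):
        mask = (a == la) & (b == lb)
        if not mask.any():
            raise StatsError(f"empty design cell ({names[0]}={la}, {names[1]}={lb})")
        cells[(la, lb)] = v[mask]
    cell_ns = {k: len(x) for k, x in cells.items()}
    balanced = len(set(cell_ns.values())) == 1
    if ss_type == "auto":
        ss_type = "classical" if balanced else "type2"
    if ss_type not in ("classical", "type2"):
        raise StatsError(f"unknown ss_type {ss_type!r}")
    if ss_type == "classical" and not balanced:
        raise StatsError("classical decomposition requires a balanced design")

    df_a, df_b_ = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b_
    df_res = v.size - len(a_levels) * len(b_levels)
    if df_res < 1:
        raise StatsError("no residual degrees of freedom (one observation per cell)")

    cell_mean = {k: x.mean() for k, x in cells.items()}
    ss_res = sum(((x - cell_mean[k]) ** 2).sum() for k, x in cells.items())
    total_ss = float(((v - v.mean()) ** 2).sum())

    if ss_type == "classical":
        n = next(iter(cell_ns.values()))
        grand = v.mean()
        mean_a = {la: v[a == la].mean() for la in a_levels}
        mean_b = {lb: v[b == lb].mean() for lb in b_levels}
        ss_a = n * len(b_levels) * sum((mean_a[la] - grand) ** 2 for la in a_levels)
        ss_b = n * len(a_levels) * sum((mean_b[lb] - grand) ** 2 for lb in b_levels)
        ss_ab = n * sum(
            (cell_mean[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
            for la, lb in itertools.product(a_levels, b_levels)
        )
    else:
        ones = np.ones((v.size, 1))
        Xa, Xb = _dummy(a, a_levels), _dummy(b, b_levels)
        Xab = np.column_stack(
            [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        )
        rss_a = _rss(np.hstack([ones, Xa]), v)
        rss_b = _rss(np.hstack([ones, Xb]), v)
        rss_main = _rss(np.hstack([ones, Xa, Xb]), v)
        rss_full = _rss(np.hstack([ones, Xa, Xb, Xab]), v)
        ss_a = rss_b - rss_main      # SS(A | B)
        ss_b = rss_a - rss_main      # SS(B | A)
        ss_ab = rss_main - rss_full  # SS(AB | A, B)
        ss_res = rss_full

    ms_res = ss_res / df_res
    terms = {}
    for name, ss, df in (
        (names[0], ss_a, df_a),
        (names[1], ss_b, df_b_),
        (f"{names[0]}x{names[1]}", ss_ab, df_ab),
    ):
        ss = max(float(ss), 0.0)  # guard tiny negative round-off
        F, p = _f_term(ss, df, ms_res, df_res)
        terms[name] = AnovaTerm(name, ss, df, F, p)
    return AnovaResult(
        terms=terms,
        residual_ss=float(ss_res),
        residual_df=df_res,
        total_ss=total_ss,
        balanced=balanced,
        ss_type=ss_type,
        n_obs=int(v.size),
        group_levels=[str(x) for x in a_levels],
    )


def pairwise_posthoc(
    values: Sequence[float],
    groups: Sequence,
    *,
    method: str = "tukey",
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise group contrasts after a one-way ANOVA.

    By default each pair's t statistic uses the pooled within-group error
    term and residual df from the one-way ANOVA; ``welch=True`` computes
    per-pair Welch t statistics with Satterthwaite df instead.

    ``method="tukey"`` adjusts via the studentized-range distribution
    (q = |t|*sqrt(2) compared against k groups); ``method="bonferroni"``
    multiplies the raw two-sided p by the number of pairs, capped at 1.

    Returns a tidy frame: pair, estimate, t, df, p_raw, p_adj, method.
    """
    if method not in ("tukey", "bonferroni"):
        raise StatsError(f"unknown post-hoc method {method!r}")
    v, g, _ = _clean(values, groups, "group")
    levels = sorted(set(g))
    k = len(levels)
    if k < 2:
        raise StatsError("post-hoc tests need >= 2 groups")
    anova = one_way_anova(v, g)
    ms_w, df_w = anova.residual_ms, anova.residual_df
    pairs = list(itertools.combinations(levels, 2))

    rows = []
    for l1, l2 in pairs:
        x1, x2 = v[g == l1], v[g == l2]
        est = x1.mean() - x2.mean()
        if welch:
            se = np.sqrt(x1.var(ddof=1) / x1.size + x2.var(ddof=1) / x2.size)
            num = (x1.var(ddof=1) / x1.size + x2.var(ddof=1) / x2.size) ** 2
            den = (x1.var(ddof=1) / x1.size) ** 2 / (x1.size - 1) + (
                x2.var(ddof=1) / x2.size
            ) ** 2 / (x2.size - 1)
            df = num / den if den > 0 else np.nan
        else:
            se = np.sqrt(ms_w * (1.0 / x1.size + 1.0 / x2.size))
            df = df_w
        if se == 0:
            t = 0.0 if est == 0 else np.inf * np.sign(est)
        else:
            t = est / se
        if not np.isfinite(t):
            p_raw = 0.0
        else:
            p_raw = float(2.0 * stats.t.sf(abs(t), df))
        if method == "tukey":
            if np.isfinite(t):
                p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            else:
                p_adj = 0.0
        else:
            p_adj = min(1.0, p_raw * len(pairs))
        p_adj = min(1.0, max(p_adj, p_raw if np.isfinite(p_raw) else 0.0))
        rows.append(
            {
                "pair": f"{l1}-{l2}",
                "estimate": float(est),
                "t": float(t),
                "df": float(df),
                "p_raw": p_raw,
                "p_adj": p_adj,
                "method": method + ("-welch" if welch else ""),
            }
        )
    return pd.DataFrame(rows)
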