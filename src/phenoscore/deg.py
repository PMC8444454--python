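"""Multi-contrast differential-expression attribution.

Three pairwise contrasts are available for each brain region and sex:
transgenic vs wildtype (TgWT), transgenic vs non-transgenic littermate
(TgNTg), and non-transgenic littermate vs wildtype (NTgWT).  Genes
differentially expressed in TgWT that are *also* differentially
expressed in TgNTg implicate the transgene itself (a "gene" effect);
TgWT genes shared with NTgWT implicate the adverse maternal environment
common to Tg and NTg offspring (an "environment" effect).  Each
attributed set is split into up- and down-regulated counts using the
TgWT log2 fold-change sign.

DEG calling uses Benjamini-Hochberg adjusted p-values at a strict
threshold (adjusted p < alpha); when a table does not already carry
adjusted p-values they are computed per table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEGError",
    "ContrastTable",
    "AttributionResult",
    "bh_adjust",
    "call_degs",
    "attribute_effects",
    "summarize_counts",
]

CONTRASTS = ("TgWT", "TgNTg", "NTgWT")


class DEGError(ValueError):
    pass


@dataclass
class ContrastTable:
    """Per-gene DE statistics for one pairwise contrast in one stratum.

    ``data`` columns: ``gene`` (unique), ``log2fc``, ``pval`` and
    optionally ``adj_pval``.
    """

    contrast: str
    data: pd.DataFrame
    region: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise DEGError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")
        required = {"gene", "log2fc", "pval"}
        missing = required - set(self.data.columns)
        if missing:
            raise DEGError(f"contrast table missing columns: {sorted(missing)}")
        if self.data["gene"].duplicated().any():
            dupes = self.data.loc[self.data["gene"].duplicated(), "gene"].tolist()[:5]
            raise DEGError(f"duplicate gene identifiers: {dupes}")
        p = self.data["pval"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise DEGError("raw p-values outside [0, 1]")

    @property
    def adjusted(self) -> pd.Series:
        """Adjusted p-values: verbatim if provided, else BH per table."""
        if "adj_pval" in self.data.columns and self.data["adj_pval"].notna().all():
            return self.data["adj_pval"].astype(float)
        return pd.Series(
            bh_adjust(self.data["pval"].to_numpy(dtype=float)),
            index=self.data.index,
            name="adj_pval",
        )


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    With the m raw p-values sorted ascending, the adjusted value at rank
    i is ``min_{j >= i} (p_j * m / j)`` capped at 1; output order matches
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DEGError("bh_adjust expects a 1-d collection")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DEGError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_degs(table: ContrastTable, alpha: float = 0.05) -> dict[str, str]:
    """Genes with adjusted p strictly below ``alpha``, mapped to direction.

    Direction is ``"up"`` for positive log2 fold-change, ``"down"`` for
    negative; an exactly-zero fold-change in a called gene is labelled
    ``"flat"`` with a warning.
    """
    if not (0 < alpha <= 1):
        raise DEGError(f"alpha must be in (0, 1], got {alpha!r}")
    adj = table.adjusted.to_numpy(dtype=float)
    called = adj < alpha  # strict
    out: dict[str, str] = {}
    flat: list[str] = []
    for gene, lfc in zip(
        table.data.loc[called, "gene"], table.data.loc[called, "log2fc"]
    ):
        if lfc > 0:
            out[gene] = "up"
        elif lfc < 0:
            out[gene] = "down"
        else:
            out[gene] = "flat"
            flat.append(gene)
    if flat:
        warnings.warn(
            f"{len(flat)} called DEG(s) with log2fc exactly 0 labelled 'flat': "
            f"{flat[:5]}",
            stacklevel=2,
        )
    return out


@dataclass
class AttributionResult:
    """Gene-effect and environment-effect DEG sets for one stratum."""

    region: str
    sex: str
    alpha: float
    gene_effect: dict[str, str] = field(default_factory=dict)  # gene -> up/down/flat
    env_effect: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def _counts(d: Mapping[str, str]) -> tuple[int, int]:
        up = sum(1 for v in d.values() if v == "up")
        down = sum(1 for v in d.values() if v == "down")
        return up, down

    @property
    def n_gene_up(self) -> int:
        return self._counts(self.gene_effect)[0]

    @property
    def n_gene_down(self) -> int:
        return self._counts(self.gene_effect)[1]

    @property
    def n_env_up(self) -> int:
        return self._counts(self.env_effect)[0]

    @property
    def n_env_down(self) -> int:
        return self._counts(self.env_effect)[1]

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "sex": self.sex,
            "alpha": self.alpha,
            "gene_effect": dict(sorted(self.gene_effect.items())),
            "env_effect": dict(sorted(self.env_effect.items())),
            "n_gene_up": self.n_gene_up,
            "n_gene_down": self.n_gene_down,
            "n_env_up": self.n_env_up,
            "n_env_down": self.n_env_down,
        }


def attribute_effects(
    tgwt: ContrastTable,
    tgntg: ContrastTable,
    ntgwt: ContrastTable,
    alpha: float = 0.05,
    *,
    strict_direction: bool = False,
) -> AttributionResult:
    """Intersect DEG sets across contrasts into gene vs environment effects.

    gene effect  = DEGs(TgWT) ∩ DEGs(TgNTg)  — driven by the transgene;
    env effect   = DEGs(TgWT) ∩ DEGs(NTgWT)  — driven by the shared
    maternal environment.  Direction (up/down) is taken from the TgWT
    contrast.  With ``strict_direction=True`` a gene is attributed only
    when its fold-change sign agrees across the two intersected contrasts.
    """
    expected = dict(zip(CONTRASTS, (tgwt, tgntg, ntgwt)))
    for name, table in expected.items():
        if table.contrast != name:
            raise DEGError(
                f"expected contrast {name!r} in position, got {table.contrast!r}"
            )
    strata = {(t.region, t.sex) for t in expected.values()}
    if len(strata) != 1:
        raise DEGError(f"contrast tables from mismatched strata: {sorted(strata)}")

    d_tgwt = call_degs(tgwt, alpha)
    d_tgntg = call_degs(tgntg, alpha)
    d_ntgwt = call_degs(ntgwt, alpha)

    def _intersect(other: dict[str, str]) -> dict[str, str]:
        genes = set(d_tgwt) & set(other)
        if strict_direction:
            genes = {g for g in genes if d_tgwt[g] == other[g]}
        return {g: d_tgwt[g] for g in sorted(genes)}

    return AttributionResult(
        region=tgwt.region,
        sex=tgwt.sex,
        alpha=alpha,
        gene_effect=_intersect(d_tgntg),
        env_effect=_intersect(d_ntgwt),
    )


def summarize_counts(results: Iterable[AttributionResult]) -> pd.DataFrame:
    """Count table across strata, one row per (region, sex, effect type).

    Strata with no shared DEGs for an effect type are marked ``n/a`` in
    the status column (too few shared genes to analyse further).
    """
    results = list(results)
    if not results:
        raise DEGError("summarize_counts needs >= 1 attribution result")
    rows = []
    for r in results:
        for effect, d in (("gene", r.gene_effect), ("environment", r.env_effect)):
            up, down = AttributionResult._counts(d)
            rows.append(
                {
                    "region": r.region,
                    "sex": r.sex,
                    "effect": effect,
                    "n_shared": len(d),
                    "n_up": up,
                    "n_down": down,
                    "genes": ";".join(sorted(d)),
                    "status": "ok" if d else "n/a",
                }
            )
    return pd.DataFrame(rows)
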