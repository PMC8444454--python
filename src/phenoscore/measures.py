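"""Derived per-animal outcome measures.

Several outcome measures in a behavioural battery are not read directly
off an apparatus but derived from two or more component values recorded
for the same animal: discrimination *differences* (novel minus familiar
presentation), stress-response *percent changes* (stressed relative to
baseline corticosterone metabolites), and acquisition *slopes* (ordinary
least-squares slope of a response count across learning sessions).  The
derived values are then treated as ordinary measures by the scoring
stage.

Missing components propagate: a derived measure with a missing input is
NaN and is excluded (not zero-filled) from all downstream means.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np


class MeasureError(ValueError):
    """Invalid input to a derived-measure computation."""


def difference(novel: float, familiar: float) -> float:
    """Novel-minus-familiar difference; may be negative.

    Used e.g. for social odour discrimination, where the number of visits
    to a novel odour on its first presentation is compared with the third
    presentation of the familiar odour.  NaN inputs propagate.
    """
    novel = float(novel)
    familiar = float(familiar)
    if math.isnan(novel) or math.isnan(familiar):
        return math.nan
    if math.isinf(novel) or math.isinf(familiar):
        raise MeasureError("difference requires finite components")
    return novel - familiar


def percent_change(baseline: float, stressed: float) -> float:
    """Percent change of ``stressed`` relative to ``baseline``.

    Returns ``100 * (stressed - baseline) / baseline``.  The baseline must
    be strictly positive; a non-positive baseline makes the relative change
    undefined and raises :class:`MeasureError` so the record can be flagged
    upstream.  NaN inputs propagate.
    """
    baseline = float(baseline)
    stressed = float(stressed)
    if math.isnan(baseline) or math.isnan(stressed):
        return math.nan
    if baseline <= 0:
        raise MeasureError(f"percent_change undefined for baseline {baseline!r} <= 0")
    return 100.0 * (stressed - baseline) / baseline


def least_squares_slope(
    series: Iterable[tuple[float, float]] | None = None,
    *,
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    relative_to_baseline: bool = False,
) -> float:
    """Ordinary least-squares slope of a response across ordered sessions.

    Accepts either an iterable of ``(index, response)`` pairs or separate
    ``x``/``y`` sequences.  With ``relative_to_baseline=True`` the slope is
    divided by the first response (baseline-normalised relative slope); the
    default is the raw OLS slope.

    Raises :class:`MeasureError` for fewer than two points or a constant
    index.  Pairs with a NaN response are dropped first.
    """
    if series is not None:
        pts = [(float(a), float(b)) for a, b in series]
        xv = np.array([p[0] for p in pts], dtype=float)
        yv = np.array([p[1] for p in pts], dtype=float)
    else:
        if x is None or y is None:
            raise MeasureError("provide either `series` or both `x` and `y`")
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise MeasureError("x and y must have equal length")

    keep = ~np.isnan(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 2:
        raise MeasureError("least_squares_slope needs >= 2 non-missing points")
    if np.unique(xv).size < 2:
        raise MeasureError("least_squares_slope needs >= 2 distinct index values")

    slope = float(np.polyfit(xv, yv, 1)[0])
    if relative_to_baseline:
        baseline = yv[np.argmin(xv)]
        if baseline == 0:
            raise MeasureError("relative slope undefined for zero baseline response")
        slope /= baseline
    return slope
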