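"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written with explicit Python loops and dicts, on
purpose: it shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from collections import defaultdict


def brute_force_unified(rows, trait_map, stratum_cols=("sex", "cohort")):
    """Recompute unified trait scores from raw records with explicit loops.

    ``rows`` is a list of record dicts (animal_id, sex, group, cohort,
    test, measure, value, is_timeout).  Returns
    ``{(animal_id, trait): unified_score}`` with NaN for all-missing.
    Implements: ratio to stratum max (non-timeout, non-missing), negative
    clamp to 0, inversion for direction -1, final score 1 for time-outs,
    then per-(trait, test) means and per-trait means over tests.
    """
    by_measure = defaultdict(list)
    for r in rows:
        stratum = tuple(r[c] for c in stratum_cols)
        by_measure[(stratum, r["test"], r["measure"])].append(r)

    mscores = {}  # (animal, test, measure) -> score
    for (stratum, test, measure), rs in by_measure.items():
        entry = trait_map[(test, measure)]
        usable = [
            r["value"]
            for r in rs
            if not math.isnan(r["value"]) and not r["is_timeout"]
        ]
        mmax = max(usable)
        assert mmax > 0, "oracle fixture must avoid degenerate strata"
        for r in rs:
            v = r["value"]
            if math.isnan(v):
                s = math.nan
            elif r["is_timeout"]:
                s = 1.0
            else:
                s = v / mmax
                if v < 0:
                    s = 0.0
                if entry.direction == -1:
                    s = 1.0 - s
                s = min(max(s, 0.0), 1.0)
            mscores[(r["animal_id"], test, measure)] = s

    animals = {}
    for r in rows:
        animals[r["animal_id"]] = True

    # test scores: mean of measure scores per (animal, trait, test)
    tscores = defaultdict(list)
    for (stratum, test, measure), rs in by_measure.items():
        trait = trait_map[(test, measure)].trait
        for r in rs:
            s = mscores[(r["animal_id"], test, measure)]
            if not math.isnan(s):
                tscores[(r["animal_id"], trait, test)].append(s)

    tmean = {k: sum(v) / len(v) for k, v in tscores.items()}

    # which (trait, test) combinations exist at all
    trait_tests = defaultdict(set)
    for (test, measure), entry in trait_map.items():
        trait_tests[entry.trait].add(test)

    unified = {}
    for animal in animals:
        for trait, tests in trait_tests.items():
            contributing = [
                tmean[(animal, trait, t)]
                for t in tests
                if (animal, trait, t) in tmean
            ]
            unified[(animal, trait)] = (
                sum(contributing) / len(contributing) if contributing else math.nan
            )
    return unified


def anova_oneway_oracle(groups):
    """Hand sums-of-squares one-way ANOVA; returns (F, df1, df2)."""
    all_v = [x for g in groups for x in g]
    grand = sum(all_v) / len(all_v)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df1 = len(groups) - 1
    df2 = len(all_v) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


def bh_oracle(pvals):
    """Step-up BH by explicit sort-and-scan."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj
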