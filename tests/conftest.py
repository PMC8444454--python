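from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoscore.traitmap import TraitEntry, TraitMap

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def simple_trait_map() -> TraitMap:
    """Two tests probing anxiety, one probing sociability."""
    return TraitMap(
        {
            ("light_dark", "time_in_light"): TraitEntry("anxiety", -1),
            ("light_dark", "latency_to_light"): TraitEntry(
                "anxiety", +1, latency_type=True
            ),
            ("reluctance", "latency_to_approach"): TraitEntry(
                "anxiety", +1, latency_type=True
            ),
            ("interaction", "time_following"): TraitEntry("sociability", +1),
        }
    )


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Fill in boilerplate columns for terse test fixtures."""
    defaults = {"sex": "F", "group": "WT", "cohort": "C1", "is_timeout": False}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def random_mini_cohort(rng: np.random.Generator):
    """Random small cohort (<=10 animals, <=3 tests) plus its trait map.

    Measures get random traits/directions; latency measures may time
    out; some values are negative or missing.  Every (stratum, measure)
    keeps at least one positive usable value so no stratum degenerates.
    """
    n_animals = int(rng.integers(3, 11))
    n_tests = int(rng.integers(1, 4))
    traits = ["anxiety", "sociability", "cognition"]
    sexes = rng.choice(["F", "M"], size=n_animals)
    cohorts = rng.choice(["C1", "C2"], size=n_animals)
    groups = rng.choice(["WT", "NTg", "Tg"], size=n_animals)

    entries = {}
    rows = []
    for t in range(n_tests):
        test = f"test{t}"
        n_measures = int(rng.integers(1, 4))
        for m in range(n_measures):
            measure = f"m{m}"
            latency = bool(rng.uniform() < 0.3)
            entries[(test, measure)] = TraitEntry(
                trait=str(rng.choice(traits)),
                direction=int(rng.choice([1, -1])),
                latency_type=latency,
            )
            for i in range(n_animals):
                v = float(rng.normal(5.0, 3.0))
                is_to = latency and rng.uniform() < 0.15
                if rng.uniform() < 0.1:
                    v = float("nan")
                rows.append(
                    {
                        "animal_id": f"a{i}",
                        "sex": str(sexes[i]),
                        "group": str(groups[i]),
                        "cohort": str(cohorts[i]),
                        "test": test,
                        "measure": measure,
                        "value": v,
                        "is_timeout": bool(is_to),
                    }
                )
    # guarantee a positive usable value in every (sex, cohort, test, measure)
    seen = {}
    for r in rows:
        key = (r["sex"], r["cohort"], r["test"], r["measure"])
        usable = not r["is_timeout"] and r["value"] == r["value"] and r["value"] > 0
        seen.setdefault(key, False)
        seen[key] = seen[key] or usable
    for key, ok in seen.items():
        if not ok:
            for r in rows:
                if (r["sex"], r["cohort"], r["test"], r["measure"]) == key:
                    r["value"] = float(rng.uniform(1.0, 10.0))
                    r["is_timeout"] = False
                    break
    return pd.DataFrame(rows), TraitMap(entries)
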