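"""Trait map: which outcome measures probe which behavioural traits.

Each (test, measure) pair is assigned to exactly one behavioural trait
together with a direction of association: ``+1`` means a larger raw value
indicates *more* of the trait (e.g. latency to enter the light and
anxiety), ``-1`` means a larger raw value indicates *less* of it (e.g.
time spent in the light and anxiety).  Latency-type measures can be
right-censored by a session time-out, which the scoring stage treats as
the maximal deficit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

#: Controlled vocabulary of behavioural traits.
TRAITS = frozenset(
    {
        "anxiety",
        "sociability",
        "cognition",
        "depression",
        "motivation",
        "stress",
        "impulsivity",
        "attention",
        "activity",
    }
)


class TraitMapError(ValueError):
    """Invalid trait-map configuration."""


@dataclass(frozen=True)
class TraitEntry:
    """Assignment of one (test, measure) to a trait.

    Parameters
    ----------
    trait
        Trait label from the controlled vocabulary.
    direction
        ``+1`` if a larger raw value means more of the trait, ``-1`` if less.
    latency_type
        Whether the measure is a latency that can be censored by a time-out.
    """

    trait: str
    direction: int
    latency_type: bool = False

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise TraitMapError(
                f"unknown trait {self.trait!r}; expected one of {sorted(TRAITS)}"
            )
        if self.direction not in (+1, -1):
            raise TraitMapError(f"direction must be +1 or -1, got {self.direction!r}")


class TraitMap:
    """Mapping ``(test, measure) -> TraitEntry``.

    The canonical on-disk form is a two-level YAML document::

        light_dark_box:
          time_in_light:   {trait: anxiety, direction: -1}
          latency_to_light: {trait: anxiety, direction: 1, latency_type: true}
    """

    def __init__(self, entries: Mapping[tuple[str, str], TraitEntry]):
        self._entries = dict(entries)
        for (test, measure), entry in self._entries.items():
            if not isinstance(entry, TraitEntry):
                raise TraitMapError(
                    f"entry for ({test!r}, {measure!r}) is not a TraitEntry"
                )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._entries)

    def __getitem__(self, key: tuple[str, str]) -> TraitEntry:
        try:
            return self._entries[key]
        except KeyError:
            raise TraitMapError(f"(test, measure) pair {key!r} not in trait map") from None

    def items(self):
        return self._entries.items()

    @property
    def traits(self) -> list[str]:
        """Traits referenced by at least one measure, sorted."""
        return sorted({e.trait for e in self._entries.values()})

    def tests_for_trait(self, trait: str) -> list[str]:
        return sorted({t for (t, _), e in self._entries.items() if e.trait == trait})

    def measures_for(self, test: str, trait: str | None = None) -> list[str]:
        return sorted(
            m
            for (t, m), e in self._entries.items()
            if t == test and (trait is None or e.trait == trait)
        )

    def is_latency(self, test: str, measure: str) -> bool:
        return self[(test, measure)].latency_type

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TraitMap":
        entries: dict[tuple[str, str], TraitEntry] = {}
        for test, measures in doc.items():
            if not isinstance(measures, Mapping):
                raise TraitMapError(f"test {test!r} must map measures to entries")
            for measure, spec in measures.items():
                entries[(str(test), str(measure))] = TraitEntry(
                    trait=spec["trait"],
                    direction=int(spec["direction"]),
                    latency_type=bool(spec.get("latency_type", False)),
                )
        return cls(entries)

    def to_dict(self) -> dict:
        doc: dict = {}
        for (test, measure), e in sorted(self._entries.items()):
            doc.setdefault(test, {})[measure] = {
                "trait": e.trait,
                "direction": e.direction,
                "latency_type": e.latency_type,
            }
        return doc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise TraitMapError(f"{path}: trait map YAML must be a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
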