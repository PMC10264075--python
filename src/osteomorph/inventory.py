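"""Skeletal-element bookkeeping: MNE, MNI, and staged specimen filters.

An inventory counts the minimum number of elements (MNE) per bone
element, side, and portion (proximal / distal fragment, or complete).
The minimum number of individuals (MNI) an element implies is taken as

    MNI = max over (side, portion) of
          fragment MNE(side, portion) + complete MNE(same side)

since a complete bone contains both of its portions, a same-side
complete element adds one countable portion of either kind.  Sample
attrition (fragmentation, surface alteration, distortion) is recorded as
an ordered ledger of named removal events so that every published count
— discovered, digitised, integrated — is reproducible from the raw
inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

ELEMENTS = ("femur", "tibia")
SIDES = ("left", "right")
PORTIONS = ("proximal", "distal", "complete")
FRAGMENT_PORTIONS = ("proximal", "distal")


@dataclass
class FilterEvent:
    """One named removal stage: ``removals[(element, portion)] = count``
    subtracted across sides (side-less bookkeeping, as counts of
    removed specimens are reported per portion only)."""

    name: str
    removals: dict


@dataclass
class ElementInventory:
    """MNE counts keyed by (element, side, portion), plus the filter ledger."""

    counts: dict = field(default_factory=dict)
    ledger: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for key, v in self.counts.items():
            element, side, portion = key
            if element not in ELEMENTS or side not in SIDES or portion not in PORTIONS:
                raise ValueError(f"unknown inventory key {key}")
            if int(v) != v or v < 0:
                raise ValueError(f"count for {key} must be a non-negative integer, got {v}")
        self.counts = {k: int(v) for k, v in self.counts.items()}

    def count(self, element: str, side: str, portion: str) -> int:
        return self.counts.get((element, side, portion), 0)

    def portion_totals(self, element: str) -> dict:
        """Counts per portion summed over sides."""
        return {
            portion: sum(self.count(element, side, portion) for side in SIDES)
            for portion in PORTIONS
        }


def compute_mni(inv: ElementInventory, element: str) -> int:
    """Minimum number of individuals implied by one element's counts."""
    if element not in ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    best = 0
    for side, portion in product(SIDES, FRAGMENT_PORTIONS):
        best = max(best, inv.count(element, side, portion) + inv.count(element, side, "complete"))
    return best


def apply_filters(inv: ElementInventory, removals) -> dict:
    """Apply an ordered ledger of :class:`FilterEvent` to an inventory.

    Removal counts are per (element, portion), side-agnostic.  Returns
    the per-stage survivor totals:

    ``{"stages": [{name, survivors{(element, portion): n}}, ...],
       "final": survivors after the last stage}``

    Raises if any stage would drive a count negative, naming the stage.
    """
    current = {
        (element, portion): inv.portion_totals(element)[portion]
        for element in ELEMENTS
        for portion in PORTIONS
    }
    stages = []
    for event in removals:
        for key, n in event.removals.items():
            if key not in current:
                raise ValueError(f"stage {event.name!r}: unknown category {key}")
            if n < 0:
                raise ValueError(f"stage {event.name!r}: negative removal for {key}")
            current[key] -= n
            if current[key] < 0:
                raise ValueError(
                    f"stage {event.name!r}: removal of {n} from {key} leaves a negative count"
                )
        stages.append({"name": event.name, "survivors": dict(current)})
    return {"stages": stages, "final": dict(current)}
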