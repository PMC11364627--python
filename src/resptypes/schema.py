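"""Item roster for the biodiversity-loss questionnaire.

The survey asks respondents to rate, on a 1 ("minor impact") to 5 ("major
impact") Likert scale, how strongly each presented driver contributes to the
global decline of biodiversity.  Five items are the established *main* drivers
of biodiversity loss; three are *minor* (distractor) drivers with negligible
global impact, used to probe whether respondents discriminate real drivers
from plausible-sounding ones.  A ninth distractor item ("entering nature
reserves") is accepted in input files but excluded from every computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


MAIN_ITEMS = (
    "climate_change",
    "exploitation",
    "invasive_species",
    "habitat_loss",
    "pollution",
)

MINOR_ITEMS = (
    "electromagnetic_pollution",
    "factory_vehicle_noise",
    "internet",
)

DROPPED_ITEMS = ("entering_nature_reserves",)

#: aliases mapping free-text column headers onto canonical item names
_ALIASES = {
    "overexploitation": "exploitation",
    "factory_and_vehicle_noise": "factory_vehicle_noise",
    "the_internet": "internet",
}

LIKERT_MIN, LIKERT_MAX = 1, 5


def canonical_item(label: str) -> str:
    """Normalise a column header to a canonical item name."""
    key = re.sub(r"[^a-z0-9]+", "_", label.strip().lower()).strip("_")
    return _ALIASES.get(key, key)


@dataclass(frozen=True)
class ItemSchema:
    """Fixed roster of analysed questionnaire items.

    Attributes
    ----------
    main_items : tuple of str
        The five main drivers, in canonical column order.
    minor_items : tuple of str
        The three analysed minor (distractor) drivers.
    dropped_items : tuple of str
        Items accepted on input but removed before analysis.
    """

    main_items: tuple[str, ...] = MAIN_ITEMS
    minor_items: tuple[str, ...] = MINOR_ITEMS
    dropped_items: tuple[str, ...] = DROPPED_ITEMS

    def __post_init__(self) -> None:
        if len(self.main_items) != 5:
            raise ValueError("schema requires exactly 5 main items")
        if len(self.minor_items) != 3:
            raise ValueError("schema requires exactly 3 minor items")
        overlap = set(self.main_items) & set(self.minor_items)
        if overlap:
            raise ValueError(f"items listed as both main and minor: {overlap}")

    @property
    def items(self) -> tuple[str, ...]:
        """All eight analysed items, main first."""
        return self.main_items + self.minor_items

    @property
    def n_items(self) -> int:
        return len(self.items)


DEFAULT_SCHEMA = ItemSchema()

#: feature column name for the main-minus-minor mean difference
DISCRIMINATION = "discrimination"

#: country-index names screened against fingerprint components
INDEX_NAMES = ("CO2", "EPI", "GBI", "NIS", "LPI")
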