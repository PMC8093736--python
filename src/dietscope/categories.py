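"""Closed prey-category vocabulary for mosquitofish gut contents.

Ten countable invertebrate categories plus two presence/absence-only
classes: detritus (DET) and unidentifiable material (UNID). Detritus and
unidentifiable items cannot be counted as discrete prey, so they never
carry integer counts; they enter frequency-of-occurrence and niche-width
calculations as presence/absence only.
"""

from __future__ import annotations

# Countable prey categories, lexicographic order (the canonical order used
# for every matrix and vector in the package).
COUNTABLE_CATEGORIES: tuple[str, ...] = (
    "ARA",  # Araneae (terrestrial spiders)
    "BI",   # Bivalvia
    "BRA",  # Branchiopoda
    "CLA",  # Cladocera
    "COL",  # Coleoptera
    "DIP",  # Diptera (incl. mosquito larvae/pupae)
    "ENT",  # Entognatha
    "HEM",  # Hemiptera
    "HYM",  # Hymenoptera
    "OST",  # Ostracoda
)

DETRITUS = "DET"
UNIDENTIFIABLE = "UNID"

PRESENCE_ONLY_CATEGORIES: tuple[str, ...] = (DETRITUS, UNIDENTIFIABLE)

ALL_CATEGORIES: tuple[str, ...] = COUNTABLE_CATEGORIES + PRESENCE_ONLY_CATEGORIES

CATEGORY_NAMES: dict[str, str] = {
    "ARA": "Araneae",
    "BI": "Bivalvia",
    "BRA": "Branchiopoda",
    "CLA": "Cladocera",
    "COL": "Coleoptera",
    "DIP": "Diptera",
    "ENT": "Entognatha",
    "HEM": "Hemiptera",
    "HYM": "Hymenoptera",
    "OST": "Ostracoda",
    DETRITUS: "Detritus",
    UNIDENTIFIABLE: "Unidentifiable",
}

#: Default total number of food categories for relative niche width:
#: the ten countable prey categories plus detritus. Unidentifiable material
#: is not a food category (it is a residual class), so it is excluded.
DEFAULT_TOTAL_CATEGORIES = len(COUNTABLE_CATEGORIES) + 1


def is_countable(code: str) -> bool:
    return code in COUNTABLE_CATEGORIES


def validate_code(code: str) -> str:
    from .errors import VocabularyError

    if code not in ALL_CATEGORIES:
        raise VocabularyError(
            f"unknown prey-category code {code!r}; known codes: "
            f"{', '.join(ALL_CATEGORIES)}"
        )
    return code
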