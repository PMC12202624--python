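"""Benthic category vocabulary shared by every stage of the pipeline.

Six categories are tracked per image: four coral morphology groups
(branching *Acropora*, plating *Acropora*, massive-form corals, and all
other corals), plus reef substrate (hard surface colonisable by coral) and
a water/sand/shadow background class. Cover is always expressed in percent
on the 0-100 scale, either of the total image or of colonisable substrate
(total image minus water/sand/shadow).
"""

from __future__ import annotations

BRANCHING = "branching"
PLATING = "plating"
MASSIVE = "massive"
OTHER_CORAL = "other_coral"
REEF_SUBSTRATE = "reef_substrate"
WATER_SAND_SHADOW = "water_sand_shadow"

#: All six categories, in canonical order. Mask rasters index this tuple.
CATEGORIES: tuple[str, ...] = (
    BRANCHING,
    PLATING,
    MASSIVE,
    OTHER_CORAL,
    REEF_SUBSTRATE,
    WATER_SAND_SHADOW,
)

#: The four coral morphology categories accuracy is assessed on.
CORAL_CATEGORIES: tuple[str, ...] = (BRANCHING, PLATING, MASSIVE, OTHER_CORAL)

#: Categories remaining after normalisation to colonisable substrate.
COLONISABLE_CATEGORIES: tuple[str, ...] = (
    BRANCHING,
    PLATING,
    MASSIVE,
    OTHER_CORAL,
    REEF_SUBSTRATE,
)

#: Sentinel raster value for pixels without a category assignment.
MISSING_PIXEL = 255

#: Label used for image area covered by no polygon (includes "I don't know").
UNANNOTATED = "unannotated"

#: Analysis methods recognised in cover tables.
METHODS = ("expert_detailed", "expert_visual", "ai", "citizen", "best")

#: analyst_id marker for multi-analyst averages.
AGGREGATE_ANALYST = "__mean__"

BASIS_TOTAL = "total_image"
BASIS_COLONISABLE = "colonisable"


class ReefCoverError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ReefCoverError):
    """Malformed input: bad category index, out-of-range value, bad schema."""


class UndefinedCoverError(ReefCoverError):
    """Cover cannot be computed (e.g. every pixel of a mask is missing)."""


class NonColonisableError(ReefCoverError):
    """Image is (almost) entirely water/sand/shadow; no colonisable basis."""


class MissingDataError(ReefCoverError):
    """An operation received no records where at least one is required."""


def category_index(label: str) -> int:
    try:
        return CATEGORIES.index(label)
    except ValueError:
        raise FormatError(f"unknown category label: {label!r}") from None
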