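"""Per-image percent cover from raw annotations.

Three annotation sources are supported, mirroring the three ways reef
images get analysed in practice:

* segmentation masks (per-pixel category indices) — the AI route;
* labelled polygons with areas — the "detailed" expert protocol;
* a 3x3 visual grid scored per cell — the "visual" expert protocol.

All three reduce to one cover vector per image on the 0-100 scale, first
as percent of the total image, then optionally renormalised to percent of
colonisable substrate (excluding water/sand/shadow). Multiple analysts of
the same image are combined by an unweighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    AGGREGATE_ANALYST,
    BASIS_COLONISABLE,
    CATEGORIES,
    MISSING_PIXEL,
    UNANNOTATED,
    WATER_SAND_SHADOW,
    FormatError,
    MissingDataError,
    NonColonisableError,
    UndefinedCoverError,
)

#: Data-entry slack allowed on per-cell grid sums above 100.
GRID_CELL_SUM_SLACK = 0.5

#: Slack allowed on total polygon area above the image area.
POLYGON_AREA_SLACK = 1e-9


@dataclass
class MaskRaster:
    """A per-pixel category raster for one image.

    ``values`` holds indices into :data:`reefcover.categories.CATEGORIES`;
    ``MISSING_PIXEL`` (255) marks pixels with no assignment.
    """

    image_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise FormatError("mask must be a non-empty 2-D array")


@dataclass
class PolygonAnnotation:
    """Polygon areas drawn by one analyst on one image.

    Areas are assumed overlap-resolved (each pixel counted once); see
    :func:`rasterize_rectangles` for the deterministic z-order rule used
    when resolving overlapping shapes.
    """

    image_id: str
    analyst_id: str
    polygons: list[tuple[str, float]] = field(default_factory=list)
    image_area: float = 1.0


@dataclass
class GridAnnotation:
    """A 3x3 visual grid assessment: nine cells, each scored 0-100 percent
    per category by eye."""

    image_id: str
    analyst_id: str
    cells: list[dict[str, float]] = field(default_factory=list)


def _empty_cover() -> pd.Series:
    return pd.Series(0.0, index=list(CATEGORIES))


def cover_from_mask(mask: MaskRaster) -> pd.Series:
    """Percent of total image per category from a segmentation mask.

    Each category's pixel count is divided by the number of non-missing
    pixels; the result sums to 100 exactly (up to float rounding).
    """
    vals = mask.values
    valid = vals != MISSING_PIXEL
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedCoverError(f"mask {mask.image_id!r}: all pixels missing")
    flat = vals[valid].astype(np.int64)
    if flat.min() < 0 or flat.max() >= len(CATEGORIES):
        raise FormatError(
            f"mask {mask.image_id!r}: category index outside 0..{len(CATEGORIES) - 1}"
        )
    counts = np.bincount(flat, minlength=len(CATEGORIES))
    return pd.Series(100.0 * counts / n_valid, index=list(CATEGORIES))


def cover_from_polygons(ann: PolygonAnnotation) -> pd.Series:
    """Percent of total image per category from polygon areas.

    Area in no polygon (or labelled "I don't know") is reported under the
    explicit ``unannotated`` key rather than being folded into reef
    substrate; see :func:`fold_residual`.
    """
    if ann.image_area <= 0:
        raise FormatError(f"image {ann.image_id!r}: image_area must be > 0")
    cover = _empty_cover()
    total = 0.0
    for cat, area in ann.polygons:
        if area < 0:
            raise FormatError(f"image {ann.image_id!r}: negative polygon area")
        total += area
        if cat in ("i_dont_know", UNANNOTATED):
            continue  # maps to the unannotated residual
        if cat not in CATEGORIES:
            raise FormatError(f"image {ann.image_id!r}: unknown category {cat!r}")
        cover[cat] += 100.0 * area / ann.image_area
    if total > ann.image_area * (1 + POLYGON_AREA_SLACK) + POLYGON_AREA_SLACK:
        raise FormatError(
            f"image {ann.image_id!r}: polygon areas exceed image area "
            f"({total} > {ann.image_area})"
        )
    cover[UNANNOTATED] = max(0.0, 100.0 - cover.sum())
    return cover


def fold_residual(cover: pd.Series) -> pd.Series:
    """Merge the unannotated residual into reef substrate.

    Only valid when the annotation protocol was exhaustive, i.e. every
    region not drawn as coral or water was in fact bare substrate.
    """
    out = cover.drop(UNANNOTATED).copy()
    out["reef_substrate"] += cover.get(UNANNOTATED, 0.0)
    return out


def cover_from_grid(ann: GridAnnotation) -> pd.Series:
    """Percent of total image per category from a 3x3 visual grid.

    Each cell covers exactly 1/9 of the image, so the image cover is the
    arithmetic mean of the nine cell scores. The exact weight 1/9 is used
    (a full cell is 100/9 ~ 11.1% of the image, and nine full cells sum to
    100, not 99.9).
    """
    if len(ann.cells) != 9:
        raise FormatError(
            f"image {ann.image_id!r}: grid needs 9 cells, got {len(ann.cells)}"
        )
    cover = _empty_cover()
    for idx, cell in enumerate(ann.cells, start=1):
        cell_sum = 0.0
        for cat, val in cell.items():
            if cat not in CATEGORIES:
                raise FormatError(f"image {ann.image_id!r}: unknown category {cat!r}")
            if not (0.0 <= val <= 100.0):
                raise FormatError(
                    f"image {ann.image_id!r} cell {idx}: value {val} outside [0, 100]"
                )
            cell_sum += val
            cover[cat] += val
        if cell_sum > 100.0 + GRID_CELL_SUM_SLACK:
            raise FormatError(
                f"image {ann.image_id!r} cell {idx}: category sum {cell_sum} > 100"
            )
    # single division keeps nine full cells at exactly 100
    return cover / 9.0


def normalize_to_colonisable(cover: pd.Series, eps: float = 1e-3) -> pd.Series:
    """Rescale a total-image cover vector to percent of colonisable substrate.

    Drops water/sand/shadow and divides the rest by (100 - w)/100. An image
    that is (almost) all water/sand/shadow has no colonisable denominator
    and raises :class:`NonColonisableError` so callers can exclude it
    explicitly instead of propagating a 0/0.
    """
    w = float(cover.get(WATER_SAND_SHADOW, 0.0))
    if w >= 100.0 - eps:
        raise NonColonisableError(f"water/sand/shadow {w} leaves no colonisable area")
    rest = cover.drop(WATER_SAND_SHADOW, errors="ignore")
    return rest * (100.0 / (100.0 - w))


def denormalize_from_colonisable(cover: pd.Series, water_pct: float) -> pd.Series:
    """Inverse of :func:`normalize_to_colonisable` given the water fraction."""
    return cover * ((100.0 - water_pct) / 100.0)


def aggregate_analysts(
    covers: pd.DataFrame, image_id: str, method: str
) -> tuple[pd.Series, int]:
    """Unweighted per-category mean over all analysts of one (image, method).

    Returns the mean cover vector and the number of contributing analysts.
    """
    sub = covers[(covers["image_id"] == image_id) & (covers["method"] == method)]
    if sub.empty:
        raise MissingDataError(f"no records for image {image_id!r} method {method!r}")
    n = sub["analyst_id"].nunique()
    mean = sub.groupby("category")["cover_pct"].mean()
    return mean, n


def aggregate_analysts_table(covers: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long cover table to one record per (image, method, category)
    by averaging analysts; ``n_analysts`` records how many contributed."""
    if covers.empty:
        raise MissingDataError("empty cover table")
    keys = ["image_id", "site_id", "reef_id", "method", "basis", "category"]
    agg = covers.groupby(keys, as_index=False, sort=False).agg(
        cover_pct=("cover_pct", "mean"),
        n_analysts=("analyst_id", "nunique"),
    )
    agg["analyst_id"] = AGGREGATE_ANALYST
    return agg


def normalize_table(covers: pd.DataFrame, eps: float = 1e-3) -> tuple[pd.DataFrame, list]:
    """Normalise every total-image record group to the colonisable basis.

    Returns the normalised long table and the list of image ids excluded by
    the non-colonisable rule (flagged, never silently dropped).
    """
    out_rows: list[pd.DataFrame] = []
    excluded: list = []
    group_keys = ["image_id", "method", "analyst_id"]
    for (img, method, analyst), grp in covers.groupby(group_keys, sort=False):
        vec = grp.set_index("category")["cover_pct"]
        try:
            norm = normalize_to_colonisable(vec, eps=eps)
        except NonColonisableError:
            excluded.append(img)
            continue
        sub = grp[grp["category"] != WATER_SAND_SHADOW].copy()
        sub["cover_pct"] = sub["category"].map(norm).astype(float)
        sub["basis"] = BASIS_COLONISABLE
        out_rows.append(sub)
    if not out_rows:
        return covers.iloc[0:0].copy(), excluded
    return pd.concat(out_rows, ignore_index=True), excluded


def train_val_split(pool_size: int, ratio: float = 0.8) -> tuple[int, int]:
    """Deterministic train/validation counts for an annotation pool.

    ``train = floor(pool_size * ratio)``, validation takes the remainder
    (7505 images at 80:20 gives 6004 train / 1501 validation).
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    train = math.floor(pool_size * ratio)
    return train, pool_size - train


def rasterize_rectangles(
    rects: list[tuple[str, int, int, int, int]], height: int, width: int
) -> MaskRaster:
    """Paint labelled axis-aligned rectangles onto a raster.

    Rectangles are painted in input order, so where two overlap the
    later-drawn one wins (a deterministic z-order; colonies rarely overlap
    but the rule must exist). Unpainted pixels stay missing.
    """
    vals = np.full((height, width), MISSING_PIXEL, dtype=np.uint8)
    for cat, r0, c0, r1, c1 in rects:
        vals[r0:r1, c0:c1] = CATEGORIES.index(cat)
    return MaskRaster(image_id="rasterized", values=vals)
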