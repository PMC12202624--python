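"""Reading and writing the pipeline's tabular formats.

All tables are UTF-8 CSV with a header row and '.' decimal; percentages
are serialised to 4 decimals so repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import CATEGORIES, MISSING_PIXEL, METHODS, FormatError
from .cover import GridAnnotation, MaskRaster, PolygonAnnotation

FLOAT_FORMAT = "%.4f"

COVER_COLUMNS = [
    "image_id", "site_id", "reef_id", "method", "analyst_id",
    "basis", "category", "cover_pct",
]
GRID_COLUMNS = [
    "image_id", "site_id", "reef_id", "analyst_id", "method",
    "cell_index", "category", "value_pct",
]
POLYGON_COLUMNS = [
    "image_id", "site_id", "reef_id", "analyst_id", "method",
    "polygon_id", "category", "area", "image_area",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_covers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "site_id": str, "reef_id": str,
                                  "analyst_id": str})
    missing = set(COVER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_grid_annotations(path: str | Path) -> list[GridAnnotation]:
    """Parse a long grid-annotation CSV into per-(image, analyst) grids.

    Cells absent from the file are treated as all-zero scores; a cell
    index outside 1..9 is a format error.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "analyst_id": str})
    missing = set(GRID_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if ((df["cell_index"] < 1) | (df["cell_index"] > 9)).any():
        raise FormatError(f"{path}: cell_index outside 1..9")
    anns = []
    for (img, analyst), grp in df.groupby(["image_id", "analyst_id"], sort=True):
        cells: list[dict[str, float]] = [dict() for _ in range(9)]
        for _, row in grp.iterrows():
            cells[int(row["cell_index"]) - 1][row["category"]] = float(row["value_pct"])
        anns.append(GridAnnotation(image_id=img, analyst_id=analyst, cells=cells))
    return anns


def read_polygon_annotations(path: str | Path) -> list[PolygonAnnotation]:
    df = pd.read_csv(path, dtype={"image_id": str, "analyst_id": str})
    missing = set(POLYGON_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    anns = []
    for (img, analyst), grp in df.groupby(["image_id", "analyst_id"], sort=True):
        areas = set(grp["image_area"])
        if len(areas) != 1:
            raise FormatError(f"{path}: inconsistent image_area for image {img!r}")
        anns.append(
            PolygonAnnotation(
                image_id=img,
                analyst_id=analyst,
                polygons=list(zip(grp["category"], grp["area"].astype(float))),
                image_area=float(areas.pop()),
            )
        )
    return anns


def read_mask_text(path: str | Path, image_id: str | None = None) -> MaskRaster:
    """Plain-text mask: rows of space-separated category indices,
    255 = missing."""
    vals = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return MaskRaster(image_id=image_id or Path(path).stem, values=vals)


def write_mask_text(mask: MaskRaster, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, mask.values, fmt="%d")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_covers(path: str | Path) -> ValidationReport:
    """Schema, bounds and duplicate-key checks on a cover table.

    Out-of-range covers and duplicated (image, method, analyst, category)
    keys are fatal; unknown methods are warnings (forward compatibility).
    """
    report = ValidationReport()
    try:
        df = read_covers(path)
    except (FormatError, OSError, pd.errors.ParserError) as exc:
        report.errors.append(str(exc))
        return report
    bad = df[(df["cover_pct"] < 0) | (df["cover_pct"] > 100)]
    for _, row in bad.head(20).iterrows():
        report.errors.append(
            f"cover out of bounds: image {row['image_id']} "
            f"{row['category']}={row['cover_pct']}"
        )
    key = ["image_id", "method", "analyst_id", "category"]
    dups = df[df.duplicated(key, keep=False)]
    for k, _ in dups.groupby(key):
        report.errors.append(f"duplicate cover record for key {k}")
    unknown = set(df["method"].unique()) - set(METHODS)
    if unknown:
        report.warnings.append(f"unrecognised methods: {sorted(unknown)}")
    unknown_cat = set(df["category"].unique()) - set(CATEGORIES) - {"unannotated"}
    if unknown_cat:
        report.errors.append(f"unknown categories: {sorted(unknown_cat)}")
    return report
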