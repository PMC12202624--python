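"""Signed per-image accuracy of automated methods against expert cover.

Accuracy is defined as the signed difference in percentage points of
cover, method minus expert, per image and coral category. A method that
reports 5% branching cover where the expert saw 10% scores -5. The
"best" method picks, for each coral category independently, whichever of
AI-alone or AI+Citizen has the smaller absolute mean difference over all
images, and applies that choice everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .categories import (
    CORAL_CATEGORIES,
    MissingDataError,
    ReefCoverError,
)

BIN_EDGES = np.arange(0.0, 110.0, 10.0)


@dataclass
class MethodSummary:
    """Per-category mean signed difference from expert for one method.

    ``table`` has one row per coral category plus ``total_coral`` (the per
    image sum of all coral-category differences), with columns
    ``mean_diff``, ``se`` and ``n_images``.
    """

    method: str
    table: pd.DataFrame

    def mean_diff(self, category: str) -> float:
        return float(self.table.loc[category, "mean_diff"])


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank comparison of two annotation protocols on the
    same images, on total coral cover."""

    n: int
    mean_difference: float
    statistic: float
    p_value: float


def _wide(covers: pd.DataFrame, categories=CORAL_CATEGORIES) -> pd.DataFrame:
    """Pivot a long (aggregated) cover table to image x category."""
    dups = covers.duplicated(["image_id", "category"])
    if dups.any():
        raise ReefCoverError(
            "cover table has multiple records per (image, category); "
            "aggregate analysts first"
        )
    wide = covers.pivot(index="image_id", columns="category", values="cover_pct")
    return wide.reindex(columns=list(categories))


def per_image_accuracy(
    method_covers: pd.DataFrame,
    expert_covers: pd.DataFrame,
    method: str,
) -> pd.DataFrame:
    """Signed difference (method - expert) per image and coral category.

    Both tables must be analyst-aggregated and on the colonisable basis;
    only images present in both contribute a record. For the citizen
    method, images with zero citizen analyses are excluded. Returns a long
    table: image_id, site_id, method, category, diff_pct,
    n_citizen_analyses.
    """
    for tbl, name in ((method_covers, "method"), (expert_covers, "expert")):
        bases = set(tbl["basis"].unique())
        if bases and bases != {"colonisable"}:
            raise ReefCoverError(f"{name} table not on colonisable basis: {bases}")
    m = method_covers[method_covers["method"] == method]
    if method == "citizen" and "n_analysts" in m.columns:
        m = m[m["n_analysts"] > 0]
    mw = _wide(m)
    ew = _wide(expert_covers)
    shared = mw.index.intersection(ew.index)
    diff = mw.loc[shared] - ew.loc[shared]

    meta = m.drop_duplicates("image_id").set_index("image_id")
    n_analyses = (
        meta["n_analysts"].reindex(shared).fillna(1).astype(int)
        if "n_analysts" in meta.columns
        else pd.Series(1, index=shared)
    )
    if method != "citizen":
        n_analyses = pd.Series(0, index=shared)

    long = diff.reset_index().melt(
        id_vars="image_id", var_name="category", value_name="diff_pct"
    )
    long["method"] = method
    long["site_id"] = long["image_id"].map(meta["site_id"])
    long["n_citizen_analyses"] = long["image_id"].map(n_analyses)
    return long[
        ["image_id", "site_id", "method", "category", "diff_pct", "n_citizen_analyses"]
    ].dropna(subset=["diff_pct"])


def summarize_method(acc: pd.DataFrame) -> MethodSummary:
    """Per-category mean difference and standard error over images.

    ``total_coral`` is the mean over images of the summed coral-category
    differences, i.e. the bias of total coral cover.
    """
    if acc.empty:
        raise MissingDataError("empty accuracy table")
    method = acc["method"].iloc[0]
    rows = {}
    for cat, grp in acc.groupby("category"):
        d = grp["diff_pct"].to_numpy(dtype=float)
        rows[cat] = _mean_se(d)
    wide = acc.pivot(index="image_id", columns="category", values="diff_pct")
    total = wide.reindex(columns=list(CORAL_CATEGORIES)).dropna().sum(axis=1)
    if len(total):
        rows["total_coral"] = _mean_se(total.to_numpy())
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "category"
    return MethodSummary(method=method, table=table)


def _mean_se(d: np.ndarray) -> dict:
    se = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
    return {"mean_diff": float(np.mean(d)), "se": se, "n_images": len(d)}


def select_best_method(
    ai: MethodSummary, citizen: MethodSummary
) -> dict[str, str]:
    """Per coral category, the method with the smaller absolute mean
    difference from expert; ties go to AI (no analyst effort needed)."""
    mapping = {}
    for cat in CORAL_CATEGORIES:
        for s in (ai, citizen):
            if cat not in s.table.index:
                raise MissingDataError(f"{s.method} summary missing {cat!r}")
        mapping[cat] = (
            "citizen"
            if abs(citizen.mean_diff(cat)) < abs(ai.mean_diff(cat))
            else "ai"
        )
    return mapping


def apply_best(
    ai_acc: pd.DataFrame, cit_acc: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Assemble the per-image "best" accuracy table from the chosen method
    per category. Images lacking the mapped method's value for a category
    simply contribute no cell there, so per-category n can differ."""
    parts = []
    tables = {"ai": ai_acc, "citizen": cit_acc}
    for cat in CORAL_CATEGORIES:
        src = tables[mapping[cat]]
        parts.append(src[src["category"] == cat])
    best = pd.concat(parts, ignore_index=True).copy()
    best["method"] = "best"
    return best


def bin_by_reef_state(
    best_acc: pd.DataFrame,
    expert_covers: pd.DataFrame,
    min_bin_images: int = 80,
) -> pd.DataFrame:
    """Mean accuracy within 10%-wide expert-cover bins, per category.

    Each image is re-assigned to a bin for every category independently,
    using the EXPERT cover of that category. Bins are [lo, hi) with the
    final [90, 100] bin closed; only bins holding at least
    ``min_bin_images`` images are reported.
    """
    ew = _wide(expert_covers)
    rows = []
    for cat, grp in best_acc.groupby("category"):
        expert_vals = ew[cat].reindex(grp["image_id"])
        ok = expert_vals.notna().to_numpy()
        d = grp["diff_pct"].to_numpy(dtype=float)[ok]
        ev = expert_vals.to_numpy(dtype=float)[ok]
        # right-open bins; clip so an exact 100 lands in [90, 100]
        idx = np.minimum(np.digitize(ev, BIN_EDGES[1:], right=False), 9)
        for b in range(10):
            sel = idx == b
            n = int(sel.sum())
            if n < min_bin_images or n == 0:
                continue
            stats_ = _mean_se(d[sel])
            rows.append(
                {
                    "category": cat,
                    "bin_lo": BIN_EDGES[b],
                    "bin_hi": BIN_EDGES[b + 1],
                    **stats_,
                }
            )
    return pd.DataFrame(
        rows, columns=["category", "bin_lo", "bin_hi", "mean_diff", "se", "n_images"]
    )


def assign_bin(value: float) -> int:
    """Index of the 10%-wide cover bin containing ``value`` ([lo, hi),
    [90, 100] closed)."""
    return int(np.minimum(np.digitize([value], BIN_EDGES[1:], right=False)[0], 9))


def correct_with_offset(
    covers: pd.DataFrame, offsets: dict[str, float]
) -> tuple[pd.DataFrame, int]:
    """Subtract a constant per-category offset from every cover value.

    A known systematic bias (e.g. a method that overestimates plating by
    9 points) can be corrected by subtracting the measured mean accuracy.
    Results are clamped to [0, 100]; the number of clamped cells is
    returned alongside the corrected table.
    """
    out = covers.copy()
    shift = out["category"].map(offsets).fillna(0.0)
    raw = out["cover_pct"] - shift
    clamped = raw.clip(0.0, 100.0)
    out["cover_pct"] = clamped
    return out, int((raw != clamped).sum())


def compare_annotation_methods(
    a: pd.DataFrame, b: pd.DataFrame
) -> PairedComparison:
    """Paired comparison of two annotation protocols on total coral cover.

    Computes per-image total coral cover (sum of the four coral
    categories) in each table, takes paired differences a - b over shared
    images, and runs a two-sided Wilcoxon signed-rank test.
    """
    ta = _wide(a).dropna().sum(axis=1)
    tb = _wide(b).dropna().sum(axis=1)
    shared = ta.index.intersection(tb.index)
    if len(shared) < 2:
        raise MissingDataError("need at least 2 paired images")
    d = (ta.loc[shared] - tb.loc[shared]).to_numpy(dtype=float)
    if np.allclose(d, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(d)
    return PairedComparison(
        n=len(shared),
        mean_difference=float(np.mean(d)),
        statistic=float(stat),
        p_value=float(p),
    )
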