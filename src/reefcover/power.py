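"""Images per site needed to detect a cover difference between sites.

Beyond method accuracy, a survey must cope with the natural patchiness of
a reef: images from one site scatter around the site mean. Treating
images as replicates, the question "how many images per site distinguish
two sites differing by 10 percentage points of cover?" is a two-sample
t-test power problem with Cohen's d = effect / sd, where sd is the
typical within-site standard deviation of per-image cover. Site SDs are
aggregated per coral category and 10%-wide reef-state bin (binned by the
expert site mean), and the required equal group size n solves the
noncentral-t power equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import _wide, assign_bin
from .categories import CORAL_CATEGORIES, MissingDataError

#: Search floor: a t-test needs at least 2 observations per group.
MIN_N_PER_GROUP = 2
_MAX_N = 10_000_000


@dataclass
class PowerConfig:
    effect: float = 10.0          # absolute percentage points of cover
    power: float = 0.8
    alpha: float = 0.05
    sides: str = "two"            # "two" or "one"
    min_images_per_site: int = 10

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect must be > 0")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sides not in ("two", "one"):
            raise ValueError("sides must be 'two' or 'one'")


def power_of_n(n: int, sd: float, cfg: PowerConfig) -> float:
    """Achieved power of the two-sample pooled-variance t test.

    Equal group sizes n, true mean difference ``cfg.effect``, common
    standard deviation ``sd``. Uses the noncentral-t distribution with
    df = 2n - 2 and noncentrality d * sqrt(n/2).
    """
    if n < MIN_N_PER_GROUP:
        raise ValueError(f"n must be >= {MIN_N_PER_GROUP}")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    d = cfg.effect / sd
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    if cfg.sides == "two":
        tcrit = stats.t.ppf(1.0 - cfg.alpha / 2.0, df)
        return float(
            stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        )
    tcrit = stats.t.ppf(1.0 - cfg.alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def required_n(sd: float, cfg: PowerConfig) -> tuple[int, bool]:
    """Smallest per-group image count achieving the target power.

    Returns ``(n, degenerate)``; ``degenerate`` is True when sd <= 0, in
    which case the search floor of 2 is returned with the flag set.
    Power is monotone in n, so the exact argmin is found by doubling to
    bracket then bisecting.
    """
    if sd <= 0:
        return MIN_N_PER_GROUP, True
    lo = MIN_N_PER_GROUP
    if power_of_n(lo, sd, cfg) >= cfg.power:
        return lo, False
    hi = lo
    while power_of_n(hi, sd, cfg) < cfg.power:
        hi *= 2
        if hi > _MAX_N:
            raise OverflowError("required n exceeds search bound")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_of_n(mid, sd, cfg) >= cfg.power:
            hi = mid
        else:
            lo = mid
    return hi, False


def site_sd_table(
    best_covers: pd.DataFrame,
    expert_covers: pd.DataFrame,
    cfg: PowerConfig,
) -> pd.DataFrame:
    """Per-site, per-category SD of best-method cover across images.

    Images are never mixed across sites. Each site is assigned, per
    category, to the 10%-wide reef-state bin containing the EXPERT mean
    cover at that site. Sites with fewer than ``cfg.min_images_per_site``
    analysed images are dropped (the count of dropped sites is implicit in
    the returned table's length versus the input).
    """
    bw = _wide(best_covers, CORAL_CATEGORIES)
    ew = _wide(expert_covers, CORAL_CATEGORIES)
    site_of = best_covers.drop_duplicates("image_id").set_index("image_id")["site_id"]
    rows = []
    for site, imgs in site_of.groupby(site_of):
        ids = imgs.index
        sub = bw.reindex(ids)
        esub = ew.reindex(ids)
        for cat in CORAL_CATEGORIES:
            vals = sub[cat].dropna()
            if len(vals) < cfg.min_images_per_site:
                continue
            expert_mean = esub[cat].dropna().mean()
            if np.isnan(expert_mean):
                continue
            rows.append(
                {
                    "site_id": site,
                    "category": cat,
                    "n_images": len(vals),
                    "site_mean_cover": float(vals.mean()),
                    "site_sd": float(vals.std(ddof=1)),
                    "bin": assign_bin(float(expert_mean)),
                }
            )
    if not rows:
        raise MissingDataError(
            f"no site reaches {cfg.min_images_per_site} images in any category"
        )
    return pd.DataFrame(rows)


def bin_mean_sd(site_stats: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean site SD per (category, bin), with its standard error.

    A bin holding a single site reports se 0 and is flagged low-confidence
    rather than being dropped.
    """
    if site_stats.empty:
        raise MissingDataError("empty site-stats table")
    rows = []
    for (cat, b), grp in site_stats.groupby(["category", "bin"]):
        sds = grp["site_sd"].to_numpy(dtype=float)
        se = float(np.std(sds, ddof=1) / np.sqrt(len(sds))) if len(sds) > 1 else 0.0
        rows.append(
            {
                "category": cat,
                "bin": int(b),
                "n_sites": len(sds),
                "mean_site_sd": float(np.mean(sds)),
                "se_of_sd": se,
                "low_confidence": len(sds) == 1,
            }
        )
    return pd.DataFrame(rows)


def power_table(site_stats: pd.DataFrame, cfg: PowerConfig) -> pd.DataFrame:
    """Required images per site per (category, reef-state bin)."""
    out = bin_mean_sd(site_stats)
    n_req, degen = [], []
    for sd in out["mean_site_sd"]:
        n, flag = required_n(float(sd), cfg)
        n_req.append(n)
        degen.append(flag)
    out["required_n_per_site"] = n_req
    out["degenerate_sd"] = degen
    return out
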