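"""Hierarchical synthetic reef survey data with known ground truth.

The real validation imagery behind this kind of survey is not public, so
every pipeline stage is exercised against generated data whose latent
state is known exactly: reefs contain sites, sites contain images, and
each image is "analysed" by a noisy expert, a biased AI, and one to six
citizen analysts each carrying a personal offset. Site and image covers
are drawn on the logit scale around configured population means, which
keeps covers inside [0, 100] at the cost of slightly shrunken realised
SDs near the bounds.

Default parameters emulate the study conditions this pipeline is designed
for: ~1,500 sites across ~200 reefs with ~20 images per site, six benthic
categories, within-site heterogeneity of several percentage points, a
segmentation model that under-calls plating coral by ~9 points, and
citizen analysts who over-call branching coral by ~9.5 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .categories import (
    BASIS_COLONISABLE,
    CATEGORIES,
    CORAL_CATEGORIES,
    REEF_SUBSTRATE,
    WATER_SAND_SHADOW,
    ReefCoverError,
)
from .cover import GridAnnotation, MaskRaster

_LOGIT_EPS = 1e-4


def _default_means() -> dict[str, float]:
    return {
        "branching": 8.0,
        "plating": 6.0,
        "massive": 6.0,
        "other_coral": 8.0,
        "reef_substrate": 42.0,
        "water_sand_shadow": 30.0,
    }


def _default_ai_bias() -> dict[str, float]:
    return {"branching": -1.1, "plating": -9.1, "massive": -3.0, "other_coral": 6.9}


def _default_citizen_bias() -> dict[str, float]:
    return {"branching": 9.5, "plating": -0.99, "massive": -0.1, "other_coral": 4.5}


@dataclass
class GeneratorConfig:
    """Population parameters of the synthetic survey.

    All covers and SDs are in percentage points on the 0-100 scale.
    ``category_mean_cover`` is on the total-image basis and must sum to
    100. Method biases apply to the four coral categories on the
    colonisable basis; reef substrate absorbs the complement so observed
    compositions still close to 100.
    """

    n_reefs: int = 210
    sites_per_reef: int = 7
    images_per_site: int = 20
    category_mean_cover: dict[str, float] = field(default_factory=_default_means)
    between_site_sd: float = 8.0
    within_site_sd: float = 8.0
    expert_noise_sd: float = 2.0
    ai_bias: dict[str, float] = field(default_factory=_default_ai_bias)
    citizen_bias: dict[str, float] = field(default_factory=_default_citizen_bias)
    ai_noise_sd: float = 6.0
    citizen_noise_sd: float = 8.0
    analyst_effect_sd: float = 3.0
    n_citizen_analysts: int = 200
    analyses_per_image: tuple[int, int] = (1, 6)
    cell_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("between_site_sd", "within_site_sd", "expert_noise_sd",
                     "ai_noise_sd", "citizen_noise_sd", "analyst_effect_sd",
                     "cell_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_reefs", "sites_per_reef", "images_per_site"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        total = sum(self.category_mean_cover.values())
        if abs(total - 100.0) > 0.01:
            raise ReefCoverError(f"category means sum to {total}, expected 100")
        if any(v < 0 for v in self.category_mean_cover.values()):
            raise ReefCoverError("category means must be >= 0")
        lo, hi = self.analyses_per_image
        if lo < 1 or hi < lo:
            raise ValueError("analyses_per_image must be a (lo, hi) range, lo >= 1")

    @property
    def n_images(self) -> int:
        return self.n_reefs * self.sites_per_reef * self.images_per_site


@dataclass
class SyntheticTruth:
    """Latent state of one generated survey.

    ``images``: wide DataFrame, one row per image with identifiers and the
    six true total-image covers. ``colonisable()`` derives the true
    colonisable-basis composition the observation models perturb.
    """

    images: pd.DataFrame
    config: GeneratorConfig

    def colonisable(self) -> pd.DataFrame:
        w = self.images[WATER_SAND_SHADOW].to_numpy()
        out = self.images[["image_id", "site_id", "reef_id"]].copy()
        scale = 100.0 / (100.0 - w)
        for cat in CORAL_CATEGORIES + (REEF_SUBSTRATE,):
            out[cat] = self.images[cat].to_numpy() * scale
        return out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return special.expit(z)


def _perturb_logit(
    mean_rows: np.ndarray,
    sd_pct: float,
    rng: np.random.Generator,
    group_size: int = 1,
) -> np.ndarray:
    """Draw one composition per row of ``mean_rows`` with ~sd_pct spread.

    Noise is added on the logit scale (which keeps covers inside the
    bounds), with the noise SD seeded by the delta method
    (dz/dp = 1/(p(1-p))) and then numerically calibrated: because expit is
    nonlinear and rows are renormalised to 100, the raw delta-method SD
    realises several percent short of the request at mid covers, so a few
    fixed-point iterations rescale each category's logit SD until the
    realised within-group sample SD matches ``sd_pct``. Categories with
    mean 0 stay exactly 0. Near the 0/100 bounds the realised SD still
    shrinks; that residual compression is inherent to bounded covers.

    ``group_size`` sets the grouping used to measure the realised SD
    (consecutive rows share a group, e.g. the images of one site).
    """
    p = np.clip(mean_rows / 100.0, 0.0, 1.0 - _LOGIT_EPS)
    n_rows, n_cat = p.shape
    if sd_pct == 0.0:
        out = p * 100.0
        return out * (100.0 / out.sum(axis=1))[:, None]
    positive = p > 0.0
    eps_draw = rng.standard_normal(p.shape)
    with np.errstate(divide="ignore"):
        base_s = np.where(positive, (sd_pct / 100.0) / (p * (1.0 - p)), 0.0)
    z0 = np.where(positive, _logit(np.maximum(p, _LOGIT_EPS)), 0.0)
    scale = np.ones(n_cat)
    ever_positive = positive.any(axis=0)
    vals = None
    for _ in range(12):
        vals = np.where(positive, 100.0 * _expit(z0 + scale * base_s * eps_draw), 0.0)
        vals *= (100.0 / vals.sum(axis=1))[:, None]
        grouped = vals.reshape(n_rows // group_size, group_size, n_cat)
        if group_size > 1:
            realised = grouped.std(axis=1, ddof=1).mean(axis=0)
        else:
            realised = vals.std(axis=0, ddof=1)
        ok = ever_positive & (realised > 1e-9)
        ratio = np.ones(n_cat)
        ratio[ok] = sd_pct / realised[ok]
        scale *= np.clip(ratio, 0.5, 2.0) ** 0.8
    return vals


def generate_truth(cfg: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    """Draw the latent site and image covers of one survey."""
    cats = list(CATEGORIES)
    means = np.array([cfg.category_mean_cover.get(c, 0.0) for c in cats])
    n_sites = cfg.n_reefs * cfg.sites_per_reef

    site_means = _perturb_logit(
        np.tile(means, (n_sites, 1)), cfg.between_site_sd, rng
    )
    img_means = np.repeat(site_means, cfg.images_per_site, axis=0)
    img_covers = _perturb_logit(
        img_means, cfg.within_site_sd, rng, group_size=cfg.images_per_site
    )

    site_idx = np.repeat(np.arange(n_sites), cfg.images_per_site)
    images = pd.DataFrame(
        {
            "image_id": [f"img{k:06d}" for k in range(cfg.n_images)],
            "site_id": [f"site{s:05d}" for s in site_idx],
            "reef_id": [f"reef{s // cfg.sites_per_reef:04d}" for s in site_idx],
        }
    )
    for j, cat in enumerate(cats):
        images[cat] = img_covers[:, j]
    return SyntheticTruth(images=images, config=cfg)


def _close_composition(coral: np.ndarray) -> np.ndarray:
    """Clamp coral covers to [0, 100], rescale rows exceeding 100, and
    return the full 5-column colonisable composition with reef substrate
    as the complement."""
    coral = np.clip(coral, 0.0, 100.0)
    totals = coral.sum(axis=1)
    over = totals > 100.0
    if over.any():
        coral[over] *= (100.0 / totals[over])[:, None]
        totals = coral.sum(axis=1)
    substrate = np.maximum(0.0, 100.0 - totals)
    return np.column_stack([coral, substrate])


def _to_long(
    comp: np.ndarray,
    meta: pd.DataFrame,
    method: str,
    analyst_id: np.ndarray | str,
) -> pd.DataFrame:
    cats = list(CORAL_CATEGORIES) + [REEF_SUBSTRATE]
    n = len(meta)
    df = pd.DataFrame(
        {
            "image_id": np.repeat(meta["image_id"].to_numpy(), len(cats)),
            "site_id": np.repeat(meta["site_id"].to_numpy(), len(cats)),
            "reef_id": np.repeat(meta["reef_id"].to_numpy(), len(cats)),
            "method": method,
            "analyst_id": np.repeat(
                np.full(n, analyst_id) if isinstance(analyst_id, str) else analyst_id,
                len(cats),
            ),
            "basis": BASIS_COLONISABLE,
            "category": np.tile(np.array(cats), n),
            "cover_pct": comp.ravel(),
        }
    )
    return df


def generate_method_observations(
    truth: SyntheticTruth, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate expert, AI and citizen analyses of every image.

    Observations live on the colonisable basis. The four coral categories
    receive the configured bias (AI, citizen) plus Gaussian noise; citizen
    analyses additionally carry a per-analyst offset drawn from a finite
    analyst pool, and each image receives a uniform-random number of
    analyses in ``cfg.analyses_per_image``. Reef substrate closes each
    composition to 100, so configured coral biases survive unchanged into
    downstream accuracy estimates (except in the rare clamped tail).
    Returns a long cover table.
    """
    colon = truth.colonisable()
    meta = colon[["image_id", "site_id", "reef_id"]]
    coral_true = colon[list(CORAL_CATEGORIES)].to_numpy()
    n = len(colon)
    ai_bias = np.array([cfg.ai_bias.get(c, 0.0) for c in CORAL_CATEGORIES])
    cit_bias = np.array([cfg.citizen_bias.get(c, 0.0) for c in CORAL_CATEGORIES])

    expert = _close_composition(
        coral_true + rng.normal(0.0, cfg.expert_noise_sd, coral_true.shape)
    )
    ai = _close_composition(
        coral_true + ai_bias + rng.normal(0.0, cfg.ai_noise_sd, coral_true.shape)
    )

    parts = [
        _to_long(expert, meta, "expert_visual", "expert1"),
        _to_long(ai, meta, "ai", "segmodel"),
    ]

    lo, hi = cfg.analyses_per_image
    if hi > cfg.n_citizen_analysts:
        raise ReefCoverError("analyst pool smaller than analyses_per_image upper bound")
    counts = rng.integers(lo, hi + 1, size=n)
    analyst_offsets = rng.normal(0.0, cfg.analyst_effect_sd, cfg.n_citizen_analysts)
    img_idx = np.repeat(np.arange(n), counts)
    # distinct analysts per image: random keys, take each image's top-k
    keys = rng.random((n, cfg.n_citizen_analysts))
    topk = np.argpartition(keys, hi - 1, axis=1)[:, :hi]
    take = np.arange(hi)[None, :] < counts[:, None]
    analyst_idx = topk[take]
    cit = _close_composition(
        coral_true[img_idx]
        + cit_bias
        + analyst_offsets[analyst_idx][:, None]
        + rng.normal(0.0, cfg.citizen_noise_sd, (img_idx.size, len(CORAL_CATEGORIES)))
    )
    analyst_ids = np.array([f"cit{a:04d}" for a in analyst_idx])
    parts.append(_to_long(cit, meta.iloc[img_idx], "citizen", analyst_ids))
    return pd.concat(parts, ignore_index=True)


def largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` items proportional to ``fractions``,
    by largest remainder; deterministic (ties broken by index order) and
    exactly conserving the total."""
    fractions = np.asarray(fractions, dtype=float)
    quotas = fractions / fractions.sum() * total
    counts = np.floor(quotas).astype(np.int64)
    short = total - counts.sum()
    order = np.lexsort((np.arange(len(quotas)), -(quotas - counts)))
    counts[order[:short]] += 1
    return counts


def generate_masks(
    truth: SyntheticTruth,
    height: int,
    width: int,
    rng: np.random.Generator,
    shuffle: bool = True,
    image_ids: list[str] | None = None,
) -> list[MaskRaster]:
    """Segmentation masks whose pixel tallies reproduce the true covers.

    Pixel counts per category come from largest-remainder rounding of the
    true total-image fractions, so the mask round-trips through pixel
    counting to within one pixel quantum (100 / (height*width)).
    """
    if height * width < 100:
        raise ValueError("mask must have at least 100 pixels")
    rows = truth.images
    if image_ids is not None:
        rows = rows[rows["image_id"].isin(image_ids)]
    masks = []
    total = height * width
    for _, row in rows.iterrows():
        fracs = np.array([row[c] for c in CATEGORIES])
        counts = largest_remainder_counts(fracs, total)
        flat = np.repeat(np.arange(len(CATEGORIES), dtype=np.uint8), counts)
        if shuffle:
            rng.shuffle(flat)
        masks.append(MaskRaster(image_id=row["image_id"], values=flat.reshape(height, width)))
    return masks


def generate_grid_annotations(
    truth: SyntheticTruth,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    analyst_id: str = "expert1",
    image_ids: list[str] | None = None,
) -> list[GridAnnotation]:
    """3x3 visual-grid assessments around the true total-image covers.

    Each cell scores the non-water categories at the true image cover plus
    independent cell-level noise, clamped to [0, 100]; absent categories
    (true cover 0) stay pinned at 0, and water/sand/shadow closes each
    cell to 100 so entries remain valid grid scores. The grid mean
    recovers the image cover up to noise of order cell_sd / 3.
    """
    rows = truth.images
    if image_ids is not None:
        rows = rows[rows["image_id"].isin(image_ids)]
    anns = []
    cats = [c for c in CATEGORIES if c != WATER_SAND_SHADOW]
    for _, row in rows.iterrows():
        base = np.array([row[c] for c in cats])
        present = base > 0.0  # absent categories stay pinned at 0
        cells = []
        for _ in range(9):
            noise = rng.normal(0.0, cfg.cell_noise_sd, len(cats)) * present
            vals = np.clip(base + noise, 0.0, 100.0)
            s = vals.sum()
            if s > 100.0:
                vals *= 100.0 / s
                s = 100.0
            cell = {c: float(v) for c, v in zip(cats, vals)}
            cell[WATER_SAND_SHADOW] = float(100.0 - s)
            cells.append(cell)
        anns.append(GridAnnotation(image_id=row["image_id"], analyst_id=analyst_id, cells=cells))
    return anns
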