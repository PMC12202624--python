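"""Monte-Carlo resampling: how many images (and analyses) per site?

A site estimate is the mean cover over the n images photographed there.
Because single-image accuracy varies, the site mean only becomes reliable
once enough images are averaged. Each simulation run draws n images from
the pooled per-image accuracy library and records the run mean; a design
(n, m) is deemed reliable when the run mean falls within +/-5 percentage
points of zero in 95% of runs. When images are analysed by citizens, m
analyses per image are drawn with replacement from that image's analyst
pool, so the effect of repeated analysis (variance ~ (sigma_i^2 +
sigma_a^2/m)/n) can be measured too.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import ReefCoverError

#: Marker value for the m column when no analyst resampling is performed.
NO_RESAMPLING = 0


@dataclass
class SimConfig:
    """Knobs of the sampling-design simulation.

    Defaults mirror the design question asked of real survey data:
    n from 1 to 120 images per site, 1 to 6 citizen analyses per image,
    10,000 runs per (n, m) cell, and the +/-5 pp / 95%-of-runs criterion.
    """

    n_values: list[int] = field(default_factory=lambda: list(range(1, 121)))
    m_values: list[int] = field(default_factory=lambda: list(range(1, 7)))
    runs: int = 10_000
    threshold: float = 5.0
    target_fraction: float = 0.95
    seed: int = 0
    sample_images_with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not (0.0 < self.target_fraction < 1.0):
            raise ValueError("target_fraction must be in (0, 1)")
        if any(n < 1 for n in self.n_values):
            raise ValueError("n_values must be positive")


@dataclass
class ImageAccuracyPool:
    """The per-image accuracy library for one coral category.

    ``values`` holds one best-method difference per image. When analyst
    resampling is wanted, ``analyst_values`` holds each image's individual
    per-analysis differences (a ragged list of non-empty arrays).
    """

    category: str
    values: np.ndarray
    analyst_values: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ReefCoverError("empty image pool")
        if self.analyst_values is not None:
            self.analyst_values = [
                np.asarray(a, dtype=float) for a in self.analyst_values
            ]
            if any(a.size == 0 for a in self.analyst_values):
                raise ReefCoverError("image with empty analyst list")
            if len(self.analyst_values) != self.values.size:
                raise ReefCoverError("analyst lists do not match image pool size")

    @property
    def size(self) -> int:
        return int(self.values.size)


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    # deterministic substream per (category, n, m): reproducible grids
    # even under partial recomputation
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _sample_image_indices(
    pool_size: int, n: int, runs: int, rng: np.random.Generator, replace: bool
) -> np.ndarray:
    if replace:
        return rng.integers(0, pool_size, size=(runs, n))
    if n > pool_size:
        raise ReefCoverError(f"cannot draw {n} distinct images from pool of {pool_size}")
    if n == pool_size:
        return np.broadcast_to(np.arange(pool_size), (runs, n))
    # without replacement for many runs at once: random keys + argpartition,
    # chunked to bound memory at ~16 MB of keys
    out = np.empty((runs, n), dtype=np.int64)
    chunk = max(1, int(2_000_000 // pool_size))
    for s in range(0, runs, chunk):
        e = min(runs, s + chunk)
        keys = rng.random((e - s, pool_size))
        out[s:e] = np.argpartition(keys, n - 1, axis=1)[:, :n]
    return out


def simulate_site_accuracy(
    pool: ImageAccuracyPool,
    n: int,
    runs: int,
    rng: np.random.Generator,
    replace: bool = False,
) -> np.ndarray:
    """Run means of n randomly sampled per-image accuracies, ``runs`` times.

    Images are sampled without replacement within a run by default,
    mimicking n distinct photographs of one site.
    """
    idx = _sample_image_indices(pool.size, n, runs, rng, replace)
    return pool.values[idx].mean(axis=1)


def simulate_with_analyst_resampling(
    pool: ImageAccuracyPool,
    n: int,
    m: int,
    runs: int,
    rng: np.random.Generator,
    replace: bool = False,
) -> np.ndarray:
    """Run means with m analyses per image resampled with replacement.

    Per run: draw n images; per image, draw m of its analyst differences
    with replacement and average them; the run value is the mean over the
    n per-image averages.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if pool.analyst_values is None:
        raise ReefCoverError("pool carries no per-analyst values")
    counts = np.array([a.size for a in pool.analyst_values], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    flat = np.concatenate(pool.analyst_values)

    idx = _sample_image_indices(pool.size, n, runs, rng, replace)
    draw = rng.integers(0, counts[idx][..., None], size=(runs, n, m))
    vals = flat[offsets[idx][..., None] + draw]
    return vals.mean(axis=2).mean(axis=1)


def fraction_within(run_means: np.ndarray, threshold: float) -> float:
    """Fraction of runs whose mean accuracy lies within +/-threshold
    (boundary inclusive)."""
    run_means = np.asarray(run_means)
    if run_means.size == 0:
        raise ReefCoverError("empty run-mean vector")
    return float(np.mean(np.abs(run_means) <= threshold))


def compute_grid(pool: ImageAccuracyPool, cfg: SimConfig) -> pd.DataFrame:
    """The full simulation grid for one category.

    Without analyst values, one row per n (m recorded as 0); with them,
    one row per (n, m). Each row carries the mean of run means, the
    central 95% band of run means, and the fraction within threshold.
    Bit-reproducible for a fixed ``cfg.seed``.
    """
    m_values = (
        [NO_RESAMPLING] if pool.analyst_values is None else list(cfg.m_values)
    )
    rows = []
    for m in m_values:
        for n in cfg.n_values:
            if n > pool.size and not cfg.sample_images_with_replacement:
                continue
            rng = _rng_for(cfg.seed, zlib.crc32(pool.category.encode()), n, m)
            if m == NO_RESAMPLING:
                means = simulate_site_accuracy(
                    pool, n, cfg.runs, rng, cfg.sample_images_with_replacement
                )
            else:
                means = simulate_with_analyst_resampling(
                    pool, n, m, cfg.runs, rng, cfg.sample_images_with_replacement
                )
            rows.append(
                {
                    "category": pool.category,
                    "n": n,
                    "m": m,
                    "runs": cfg.runs,
                    "mean_of_means": float(means.mean()),
                    "p2_5": float(np.percentile(means, 2.5)),
                    "p97_5": float(np.percentile(means, 97.5)),
                    "fraction_within": fraction_within(means, cfg.threshold),
                }
            )
    return pd.DataFrame(rows)


def min_images_required(
    grid: pd.DataFrame, target_fraction: float = 0.95
) -> pd.DataFrame:
    """Smallest n per (category, m) whose within-threshold fraction meets
    the target; ``reached`` is False when no simulated n qualifies (some
    categories plateau below the target no matter how many images are
    taken). No smoothing is applied, so the answer carries Monte-Carlo
    noise of order 1/sqrt(runs).
    """
    rows = []
    for (cat, m), grp in grid.groupby(["category", "m"]):
        grp = grp.sort_values("n")
        ok = grp[grp["fraction_within"] >= target_fraction]
        rows.append(
            {
                "category": cat,
                "m": m,
                "min_n": int(ok["n"].iloc[0]) if len(ok) else -1,
                "reached": bool(len(ok)),
            }
        )
    return pd.DataFrame(rows)
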