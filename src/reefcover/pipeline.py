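"""End-to-end orchestration: synthetic data -> covers -> accuracy ->
best-method fusion -> reef-state bins -> site simulation -> power tables.

The pipeline is a pure function of (inputs, configuration, seed): rerunning
with the same seed writes byte-identical CSVs, and a manifest records the
seed, a configuration hash and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import power as pwr
from . import sitesim
from . import synthetic
from .categories import CORAL_CATEGORIES
from .cover import aggregate_analysts_table
from .io import write_table

log = logging.getLogger("reefcover")


@dataclass
class PipelineConfig:
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    sim: sitesim.SimConfig = field(default_factory=sitesim.SimConfig)
    power: pwr.PowerConfig = field(default_factory=pwr.PowerConfig)
    expert_method: str = "expert_visual"
    min_bin_images: int = 80
    seed: int = 0
    out_dir: str = "out"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "generator" in kwargs:
            gen = dict(kwargs["generator"])
            if "analyses_per_image" in gen:
                gen["analyses_per_image"] = tuple(gen["analyses_per_image"])
            kwargs["generator"] = synthetic.GeneratorConfig(**gen)
        if "sim" in kwargs:
            kwargs["sim"] = sitesim.SimConfig(**kwargs["sim"])
        if "power" in kwargs:
            kwargs["power"] = pwr.PowerConfig(**kwargs["power"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_accuracy_pools(
    best_acc: pd.DataFrame,
    citizen_covers_raw: pd.DataFrame,
    expert_agg: pd.DataFrame,
    mapping: dict[str, str],
) -> dict[str, sitesim.ImageAccuracyPool]:
    """One image-accuracy pool per coral category for the site simulation.

    Categories served best by the citizen method also carry each image's
    individual per-analysis differences so the effect of m analyses per
    image can be simulated; AI-served categories have a single
    deterministic value per image.
    """
    ew = acc._wide(expert_agg)
    pools: dict[str, sitesim.ImageAccuracyPool] = {}
    cit = citizen_covers_raw[citizen_covers_raw["method"] == "citizen"]
    for cat in CORAL_CATEGORIES:
        sub = best_acc[best_acc["category"] == cat].sort_values("image_id")
        values = sub["diff_pct"].to_numpy(dtype=float)
        analyst_values = None
        if mapping[cat] == "citizen":
            per_img = cit[cit["category"] == cat]
            grouped = {
                img: grp["cover_pct"].to_numpy(dtype=float)
                for img, grp in per_img.groupby("image_id")
            }
            analyst_values = []
            keep = []
            expert_cat = ew[cat]
            for i, img in enumerate(sub["image_id"]):
                if img in grouped and img in expert_cat.index:
                    analyst_values.append(grouped[img] - expert_cat.loc[img])
                    keep.append(i)
            values = values[keep]
        pools[cat] = sitesim.ImageAccuracyPool(
            category=cat, values=values, analyst_values=analyst_values
        )
    return pools


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage in order and write the artifact bundle.

    Returns the in-memory tables keyed by output file stem. Outputs:
    covers.csv, accuracy.csv, summaries.csv, best_map.csv, bins.csv,
    simgrid.csv, min_images.csv, site_stats.csv, power.csv, manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    t0 = time.perf_counter()

    def stage(name: str, df: pd.DataFrame, fname: str | None = None) -> None:
        tables[name] = df
        counts[name] = len(df)
        write_table(df, out / (fname or f"{name}.csv"))
        log.info("stage %-12s %7d rows  %.1fs", name, len(df), time.perf_counter() - t0)

    # --- synthetic survey -------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2024)))
    truth = synthetic.generate_truth(cfg.generator, rng)
    covers = synthetic.generate_method_observations(truth, cfg.generator, rng)
    stage("covers", covers)

    # --- analyst aggregation & accuracy -----------------------------------
    agg = aggregate_analysts_table(covers)
    expert_agg = agg[agg["method"] == cfg.expert_method]
    ai_acc = acc.per_image_accuracy(agg, expert_agg, "ai")
    cit_acc = acc.per_image_accuracy(agg, expert_agg, "citizen")

    ai_summary = acc.summarize_method(ai_acc)
    cit_summary = acc.summarize_method(cit_acc)
    mapping = acc.select_best_method(ai_summary, cit_summary)
    best_acc = acc.apply_best(ai_acc, cit_acc, mapping)
    best_summary = acc.summarize_method(best_acc)

    stage("accuracy", pd.concat([ai_acc, cit_acc, best_acc], ignore_index=True))
    summaries = pd.concat(
        [s.table.assign(method=s.method).reset_index()
         for s in (ai_summary, cit_summary, best_summary)],
        ignore_index=True,
    )
    stage("summaries", summaries)
    stage("best_map", pd.DataFrame(
        [{"category": c, "method": m} for c, m in mapping.items()]
    ))

    bins = acc.bin_by_reef_state(best_acc, expert_agg, cfg.min_bin_images)
    stage("bins", bins)

    # --- site-level sampling simulation ------------------------------------
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    pools = build_accuracy_pools(best_acc, covers, expert_agg, mapping)
    grids = [sitesim.compute_grid(pool, sim_cfg) for pool in pools.values()]
    grid = pd.concat(grids, ignore_index=True)
    stage("simgrid", grid)
    stage("min_images", sitesim.min_images_required(grid, sim_cfg.target_fraction))

    # --- power analysis -----------------------------------------------------
    best_covers = _best_cover_table(agg, expert_agg, mapping)
    site_stats = pwr.site_sd_table(best_covers, expert_agg, cfg.power)
    stage("site_stats", site_stats)
    stage("power", pwr.power_table(site_stats, cfg.power))

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "row_counts": counts,
        "best_method_map": mapping,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables


def _best_cover_table(
    agg: pd.DataFrame, expert_agg: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Cover table of the fused best method: per category, the rows of the
    mapped method."""
    parts = []
    for cat in CORAL_CATEGORIES:
        m = mapping[cat]
        sub = agg[(agg["method"] == m) & (agg["category"] == cat)].copy()
        sub["method"] = "best"
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
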