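import numpy as np
import pandas as pd
import pytest

from reefcover import GeneratorConfig, generate_method_observations, generate_truth
from reefcover.categories import BASIS_COLONISABLE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but fully featured synthetic survey (10 sites x 15 images)."""
    return GeneratorConfig(
        n_reefs=5,
        sites_per_reef=2,
        images_per_site=15,
        within_site_sd=5.0,
        between_site_sd=5.0,
        seed=7,
    )


@pytest.fixture
def small_survey(small_config):
    rng = np.random.default_rng(small_config.seed)
    truth = generate_truth(small_config, rng)
    covers = generate_method_observations(truth, small_config, rng)
    return truth, covers


def make_cover_table(values_by_image: dict, method: str = "expert_visual",
                     site_id: str = "s1", analyst_id: str = "a1") -> pd.DataFrame:
    """Long cover table on the colonisable basis from {image: {cat: pct}}."""
    rows = []
    for img, cats in values_by_image.items():
        total = sum(cats.values())
        full = dict(cats)
        if "reef_substrate" not in full:
            full["reef_substrate"] = 100.0 - total
        for cat, val in full.items():
            rows.append({
                "image_id": img, "site_id": site_id, "reef_id": "r1",
                "method": method, "analyst_id": analyst_id,
                "basis": BASIS_COLONISABLE, "category": cat, "cover_pct": val,
            })
    return pd.DataFrame(rows)
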