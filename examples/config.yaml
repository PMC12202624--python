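# Example pipeline configuration (see src/reefcover/config_schema.json).
# Covers and SDs are percentage points on the 0-100 scale; the generator's
# category means are on the total-image basis and must sum to 100.
seed: 1
out_dir: out
expert_method: expert_visual
min_bin_images: 30

generator:
  n_reefs: 10
  sites_per_reef: 3
  images_per_site: 20
  within_site_sd: 8.0
  between_site_sd: 8.0
  analyses_per_image: [1, 6]

sim:
  n_values: [1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30, 40]
  m_values: [1, 2, 4, 6]
  runs: 2000
  threshold: 5.0
  target_fraction: 0.95

power:
  effect: 10.0
  power: 0.8
  alpha: 0.05
  min_images_per_site: 10
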