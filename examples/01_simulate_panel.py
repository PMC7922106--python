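"""Simulate a small synthetic study panel and look at what it contains.

The generator builds pixel-level 8-day NDVI composites from double-logistic
seasonal curves (with noise and cloud-like dropout suppressed by the 8-day
maximum-value compositing), mixed-pixel corn fractions, and county-year
yields that are a known linear function of the true growth-phase metrics.
"""

import warnings

from phenoyield import SimConfig, simulate_panel

config = SimConfig(n_counties=4, pixels_per_county=3,
                   years=(2016, 2017, 2018), seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panel = simulate_panel(config)

print("composites (one row per pixel-year-window):")
print(panel.composites.head(5).to_string(index=False))
print("\ncorn fractions (area share of corn in each 250-m pixel):")
print(panel.fractions.head(5).round(3).to_string(index=False))
print("\nyields (kg/ha, linear in true metrics + noise):")
print(panel.yields.head(5).round(1).to_string(index=False))

gen = panel.truth.generating
print(f"\ngenerating R^2 of the yield model: {gen['generating_r2']:.3f}")
print(f"yield noise sd (calibrated): {gen['noise_sd']:.0f} kg/ha")
print("active generating coefficients:",
      {k: v for k, v in gen["betas"].items() if k != "intercept"})
print("\ntrue county stage dates (analytic, fractional DOY):")
cols = ["county_id", "year", "true_v1", "true_v6", "true_vt",
        "true_r4", "true_r6"]
print(panel.truth.county_truth[cols].head(4).round(1).to_string(index=False))
# Each row's dates bound the four growth phases whose durations (days) and
# NDVI change rates (per day) are the predictors the pipeline must recover.
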