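# phenoyield

Phenology-adjusted NDVI metrics and county-level corn yield regression.

County corn yields can be predicted from the *shape* of the seasonal NDVI
trajectory: when each growth stage starts, how long it lasts, and how fast
greenness changes within it. `phenoyield` implements that analysis as a
tested, reusable pipeline driven by a synthetic-data generator with known
ground truth:

1. **Per-pixel preparation** — NDVI from red/NIR reflectance, 8-day
   maximum-value composites (MVC), Savitzky–Golay smoothing, natural cubic
   spline to daily resolution, detection of the growing-season start/end
   (SD/ED) at the valley bottoms flanking the seasonal peak, and
   *phenological adjustment* (truncate to [SD, ED], re-index time as
   days-since-SD).
2. **County aggregation** — pixels with corn area fraction > 70% are
   averaged, weighted by corn fraction, on the adjusted time axis.
3. **Stage dates and metrics** — five stage dates bound four growth phases
   (GP1–GP4): emergence V1 and tasseling VT at 10%/90% of the SD-to-maximum
   NDVI range, dough R4 at 10% below the maximum toward the ED value,
   jointing V6 and maturity R6 at the inflections −a/b of logistics
   `NDVI(t) = c/(1 + e^(a+bt)) + d` fitted to the rising and falling limbs.
   Each phase yields `Duration = GPend − GPstart` and
   `Rate = (NDVI_GPend − NDVI_GPstart)/Duration`, and a ninth predictor
   Max-R² is the NDVI value at the days-since-SD index most correlated
   with yield across county-years.
4. **Yield models** — univariate screens (linear/quadratic/logarithmic),
   forward–backward stepwise multiple linear regression with standardized
   coefficients and variance inflation factors (VIF = 1/(1 − Rᵢ²), < 4
   read as non-collinear), and leave-one-year-out cross-validation
   (per-fold predictive R² and RMSE in kg ha⁻¹).

The synthetic generator builds mixed 250-m pixels whose seasonal curves are
double logistics `base + amplitude·(logistic(rise) − logistic(fall))`, so
every true stage date and metric is known analytically and each pipeline
stage is testable by recovery.

## Worked example

```python
import numpy as np
from phenoyield import (DailySeries, DoubleLogisticParams,
                        detect_growing_season, extract_phenology,
                        phenologically_adjust, simulate_pixel_curve)

params = DoubleLogisticParams(base=0.18, amplitude=0.55, rise_midpoint=155,
                              rise_rate=0.13, fall_midpoint=252,
                              fall_rate=0.11)
day = np.arange(1, 366)
series = DailySeries("demo-pixel", 2018, day, simulate_pixel_curve(params, day))
season = detect_growing_season(series)
dates, rising, falling = extract_phenology(phenologically_adjust(series, season))
print(season)
print({k: v + season.sd for k, v in dates.as_dict().items()})
```

prints

```
GrowingSeason(sd=119, ed=294)
{'v1': 139, 'v6': 155, 'vt': 172, 'r4': 232, 'r6': 252}
```

— the season runs DOY 119–294, and the extracted jointing (V6 = 155) and
maturity (R6 = 252) dates land exactly on the generating curve's rise and
fall midpoints, which is what the logistic-inflection definition promises
on noise-free input.

Running the full pipeline on a synthetic panel
(`python examples/03_yield_models.py`) ends in a report like

```
stepwise [pheno]: R2=0.710  n=84
  Y = -8751.93 +1199193.30*gp2r + +322.99*gp2d + +55.15*gp3d
  max VIF = 3.14
LOYO-CV: median R2=0.700, median RMSE=1491.5 kg/ha
```

— the stepwise model selects the jointing-to-tasseling rate and duration
(GP2R, GP2D) and the tasseling-to-dough duration (GP3D), explains 71% of
yield variance in training and 70% (median) on held-out years, with no
collinearity problem (all VIF < 4).

The `examples/` directory holds one short script per capability:
panel simulation, stage-date extraction, yield modelling, and
recovery-versus-truth checks.

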