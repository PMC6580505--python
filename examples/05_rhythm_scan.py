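"""Rolling Lomb-Scargle rhythm detection and the rhythm-probability curve.

A 15-day window slides over the raw T_b series; in each window the
periodogram is scanned over 2-30 h, the highest peak is tested against the
95% white-noise confidence limit and rounded to the full hour: 24 h and
12 h rhythms are the classes of interest. The daily 0/1 outcomes then feed
a binomial spline for the annual probability-of-rhythm curve.
"""

import numpy as np
import pandas as pd

from gulotherm import (RawSeries, SimConfig, fit_binomial_curve,
                       predict_curve, rhythm_prevalence,
                       rhythm_probability_inputs, rolling_rhythm_scan,
                       simulate_cohort)

# strong noise and a weak winter rhythm, so detection waxes and wanes over
# the year instead of saturating at 100%
cohort = simulate_cohort(SimConfig(
    n_animals=2, years=1, seed=6, pregnancy_fraction=0.0, noise_sd=1.4,
    ar1_rho=0.3,
    circadian_amplitude_by_season={"winter": 0.1, "spring": 0.45,
                                   "summer": 0.7, "autumn": 0.45}))
records = []
for aid, grp in cohort.tb.groupby("animal_id"):
    s = RawSeries(aid, "tb", pd.DatetimeIndex(grp["timestamp"]),
                  grp["tb_c"].to_numpy())
    records.extend(rolling_rhythm_scan(s))

prev = rhythm_prevalence(records)
print("rhythm prevalence over all scanned windows:")
for cls in ("h24", "h12", "other", "none"):
    print(f"  {cls:6s} {100 * prev[cls]:5.1f}%")
print(f"  24h+12h share of significant windows: "
      f"{100 * prev['combined_24_12_share']:.1f}%")

inputs = rhythm_probability_inputs(records)
if inputs["h24"].nunique() > 1:
    fit = fit_binomial_curve(inputs, "h24")
    pc = predict_curve(fit, np.arange(1.0, 367.0))
    lo = int(pc["estimate"].idxmin())
    print(f"\np(24-h rhythm) bottoms out at DOY {int(pc['doy'][lo])} with "
          f"{100 * pc['estimate'][lo]:.0f}% "
          f"[{100 * pc['ci_low'][lo]:.0f}-{100 * pc['ci_high'][lo]:.0f}%] "
          "(mid-winter, short days, weak rhythm)")
    print("Mid-summer windows are all-significant, so the curve saturates "
          "near 100% there and its CI is uninformative at the boundary.")
else:
    print("\n24-h rhythm present in every scanned window; "
          "probability curve is degenerate at 100%.")
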