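"""Convert per-trap damage thresholds into soil-sampling densities.

Per species: intercept-only ZINB of soil counts and the soil-predictor
ZINB of trap counts give per-method abundance means/SDs; their ratio R
(delta-method SD, zero covariance) divides the established per-trap
threshold (1/2/5 larvae) into a per-core threshold, scaled by 88 cores
per square metre.  Expected magnitudes: R of roughly 5-25 and per-m2
thresholds around 15 larvae.
"""

import pandas as pd

from common import RESULTS, load_pairs
from wireworm.count_models import Family, fit_count_model
from wireworm.data import Species
from wireworm.threshold import (
    DAMAGE_THRESHOLDS,
    Method,
    abundance_from_fit,
    convert_threshold,
    ratio_estimate,
)

rows = []
for sp in Species:
    pairs = load_pairs(sp)
    soil_fit = fit_count_model(pairs, Family.zinb, response="soil", intercept_only=True)
    trap_fit = fit_count_model(pairs, Family.zinb)
    core = abundance_from_fit(soil_fit, method=Method.soil_core, species=sp)
    trap = abundance_from_fit(trap_fit, method=Method.bait_trap, species=sp)
    r = ratio_estimate(trap, core)
    conv = convert_threshold(DAMAGE_THRESHOLDS[sp], r)
    rows.append(
        {
            "species": sp.value,
            "damage_threshold_per_trap": conv.threshold_per_trap,
            "core_mean": core.mean, "core_sd": core.sd,
            "trap_mean": trap.mean, "trap_sd": trap.sd,
            "ratio": r.ratio, "ratio_sd": r.sd,
            "threshold_per_core": conv.threshold_per_core,
            "threshold_per_core_sd": conv.threshold_per_core_sd,
            "threshold_per_m2": conv.threshold_per_m2,
            "threshold_per_m2_sd": conv.threshold_per_m2_sd,
        }
    )
    print(
        f"{sp.value}: cores {core.mean:.3f}±{core.sd:.3f}, "
        f"traps {trap.mean:.3f}±{trap.sd:.3f}, R={r.ratio:.2f}±{r.sd:.2f} -> "
        f"threshold {conv.threshold_per_core:.3f} larvae/core "
        f"= {conv.threshold_per_m2:.1f} larvae/m2"
    )

pd.DataFrame(rows).to_csv(RESULTS / "thresholds.csv", index=False)
print("wrote thresholds.csv")
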