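"""Per-method summary statistics and four-way concordance classification.

Expected pattern: soil cores with ~90% zeros and tiny means, traps with
far fewer zeros and larger means; joint absences dominating the pair
classification, trap-only detections second, soil-only detections rare.
"""

import pandas as pd

from common import RESULTS, load_pairs
from wireworm.data import Species, read_dataset
from wireworm.descriptive import classify_pairs, summarize
from common import DATASETS

summary_rows, conc_rows = [], []
for sp in Species:
    ds = read_dataset(DATASETS / f"{sp.value}.csv")
    for method, attr in (("soil_cores", "soil_count"), ("traps", "trap_count")):
        vals = [getattr(o, attr) for o in ds]
        s = summarize(vals, total_n=len(vals))
        summary_rows.append({"species": sp.value, "method": method, **s.__dict__})
    c = classify_pairs(load_pairs(sp))
    conc_rows.append({"species": sp.value, "n": c.n, **c.__dict__})
    props = c.proportions()
    print(
        f"{sp.value}: n={c.n} both-zero {100*props['both_zero']:.0f}%, "
        f"trap-only {100*props['trap_only']:.0f}%, "
        f"soil-only {100*props['soil_only']:.0f}%, "
        f"concordant {100*props['concordant']:.0f}%"
    )

pd.DataFrame(summary_rows).to_csv(RESULTS / "summary_stats.csv", index=False)
pd.DataFrame(conc_rows).to_csv(RESULTS / "concordance.csv", index=False)
print("wrote summary_stats.csv and concordance.csv")
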