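"""Gaussian-assumption diagnostics on raw, log(y+1) and sqrt(y) responses.

Shapiro-Wilk, studentized Breusch-Pagan and Durbin-Watson on OLS
residuals of trap counts on soil counts, pooled across species.  The
expected verdicts — non-normal and heteroscedastic under every transform
— are what motivates the count-model suite.
"""

import pandas as pd

from common import RESULTS, SEED, load_pairs
from wireworm.data import Species
from wireworm.lm_diagnostics import Transform, diagnose_lm

pairs = []
for sp in Species:
    pairs += load_pairs(sp)

rows = []
for tr in Transform:
    rep = diagnose_lm(pairs, tr, seed=SEED)
    rows.append(
        {
            "transform": tr.value,
            "shapiro_p": rep.shapiro_p,
            "breusch_pagan_p": rep.breusch_pagan_p,
            "durbin_watson": rep.durbin_watson_stat,
            "durbin_watson_p": rep.durbin_watson_p,
            **{f"verdict_{k}": v for k, v in rep.verdicts.items()},
        }
    )
    print(
        f"{tr.value:>5}: shapiro p={rep.shapiro_p:.2e}, "
        f"breusch-pagan p={rep.breusch_pagan_p:.2e}, DW={rep.durbin_watson_stat:.2f} "
        f"-> {rep.verdicts['shapiro_wilk']}, {rep.verdicts['breusch_pagan']}"
    )

pd.DataFrame(rows).to_csv(RESULTS / "lm_diagnostics.csv", index=False)
print("wrote lm_diagnostics.csv")
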