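"""Daily climate -> monthly aggregates, VPD, PET, water balance, SPEI, CMI.

Computes the Tetens VPD, the Hargreaves-type PET, monthly P - PET, the
multiscalar SPEI (1-24 months, log-logistic standardization) and the
growing-season (May-October) climate moisture index per site.
"""

import pandas as pd

from _common import get_config
from dendrowue.pipeline import stage_climate

cfg = get_config(__doc__)
stage_climate(cfg)

sp = pd.read_csv(cfg.root / "spei.csv")
oct18 = sp[(sp.scale == 18) & (sp.month == 10)]
print("18-month SPEI, October value (dry years < -1):")
for sid, sub in oct18.groupby("site"):
    driest = sub.nsmallest(3, "value")
    yrs = ", ".join(f"{int(r.year)} ({r.value:.2f})" for r in driest.itertuples())
    print(f"  {sid}: driest {yrs}")
gs = pd.read_csv(cfg.root / "cmi_growing_season.csv")
print("mean growing-season CMI (negative = dry):")
print(gs.groupby("site")["cmi"].mean().round(2).to_string())
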