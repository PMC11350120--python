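"""Long-term growth trends: loess chronology smooths, linear/Theil-Sen
trends of delta13C and iWUE, and the additive growth model.

The additive model (BAI ~ s(year) + s(age) + s(SPEI-18) + tree intercepts,
cubic penalized splines with 4 basis functions per term) is fitted per site
and ranked by AIC against reduced candidates.
"""

import json

import pandas as pd

from _common import get_config
from dendrowue.pipeline import stage_trends

cfg = get_config(__doc__)
stage_trends(cfg)

lin = pd.read_csv(cfg.root / "linear_trends.csv")
print("linear trends 1965-2014 (Theil-Sen slope, Mann-Kendall p):")
for row in lin.itertuples():
    print(
        f"  {row.site} {row.variable}: {10 * row.sen_slope_per_yr:+.2f}/decade"
        f" (p={row.mk_p:.1e})"
    )
am = json.loads((cfg.root / "additive_model.json").read_text())
print("additive growth model AIC ranking (best first):")
for sid, info in am.items():
    order = " > ".join(r["model"] for r in info["ranking"])
    print(f"  {sid}: {order}; best edf {info['edf']}")
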