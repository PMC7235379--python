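"""Annual monotherapy prescription trend with injected prescribing drift.

The generator is told to prefer valproic acid early (2004) and avoid it
late (2015); the trend table — counts of cohort members on exactly one ASM
ingredient per calendar year — recovers the injected direction of change.
"""

import numpy as np

from epipathways import (
    CohortDefinition,
    annual_monotherapy_trend,
    build_cohort,
    generate,
    make_paperlike_config,
)

cfg = make_paperlike_config(n_patients=1200, seed=17, p_dropout=0.0)
cfg.year_drug_weights = {
    year: {"valproic acid": w}
    for year, w in zip(range(2004, 2016), np.linspace(3.0, 0.1, 12))
}
tables, _ = generate(cfg)
members = build_cohort(tables, CohortDefinition())

trend = annual_monotherapy_trend(tables, members)
vpa = trend[trend["ingredient"] == "valproic acid"].set_index("year")["n_patients"]
totals = trend.groupby("year")["n_patients"].sum()
print("year  monotherapy_total  valproic_acid_share")
for year in sorted(totals.index):
    share = vpa.get(year, 0) / totals[year]
    print(f"{year}  {totals[year]:17d}  {100 * share:18.1f}%")
# The valproic-acid share of monotherapy patients falls across the span,
# mirroring the injected per-year preference weights.
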