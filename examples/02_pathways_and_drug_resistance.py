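"""Mine treatment pathways and classify drug-resistant epilepsy (DRE).

Builds per-patient ordered ingredient sequences over the first 730 treatment
days, counts distinct pathways, and partitions the cohort by number of
distinct ASMs: patients reaching a third distinct ingredient are classified
drug-resistant.
"""

from epipathways import (
    CohortDefinition,
    asm_count_distribution,
    asm_frequency,
    build_all_sequences,
    build_cohort,
    count_pathways,
    generate,
    make_paperlike_config,
)
from epipathways.cdm_tables import ingredient_names

tables, _ = generate(make_paperlike_config(n_patients=1000, seed=11))
members = build_cohort(tables, CohortDefinition())
sequences = build_all_sequences(tables, members)

table = count_pathways(sequences, tables.vocabulary)
print(f"cohort: {table.total_patients} patients, {len(table.rows)} distinct pathways")
print("top 5 pathways (sequence -> n patients):")
print(table.to_frame(tables.vocabulary).head(5).to_string(index=False))

dist = asm_count_distribution(sequences)
pct = dist["percentages"]
print(f"\nASMs used: one {pct['1']}%, two {pct['2']}%, three+ {pct['3+']}%")
print(f"drug-resistant (>= 3 distinct ASMs in first 2 years): {pct['3+']}%")

names = ingredient_names(tables.vocabulary)
shares = sorted(asm_frequency(sequences).items(), key=lambda kv: -kv[1])[:5]
print("top-5 ASM slot shares:",
      ", ".join(f"{names[c]} {100 * s:.1f}%" for c, s in shares))
# Slot share = fraction of all pathway positions occupied by the drug.
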