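"""Export the pathway frequency table as a lossless sunburst hierarchy.

Each node carries the number of patients whose sequence starts with the
node's prefix; flattening the tree reproduces the pathway table exactly, so
the JSON can feed any sunburst renderer without information loss.
"""

import json

from epipathways import (
    CohortDefinition,
    build_all_sequences,
    build_cohort,
    count_pathways,
    generate,
    make_paperlike_config,
    pathway_to_sunburst,
    sunburst_to_table,
)

tables, _ = generate(make_paperlike_config(n_patients=400, seed=19))
members = build_cohort(tables, CohortDefinition())
table = count_pathways(build_all_sequences(tables, members), tables.vocabulary)

root = pathway_to_sunburst(table, tables.vocabulary)
print(f"root: {root.n_patients} patients, {len(root.children)} first-line drugs")
for child in sorted(root.children, key=lambda c: -c.n_patients)[:3]:
    print(f"  first-line {child.name}: {child.n_patients} patients, "
          f"{len(child.children)} second-line branches")

back = sunburst_to_table(root)
print("lossless round trip:", dict(back.rows) == dict(table.rows))
print("\nJSON fragment:")
print(json.dumps(root.to_dict(), indent=2)[:400], "...")
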