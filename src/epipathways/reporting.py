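"""End-to-end pipeline assembly and export of figure-ready data structures.

The sunburst export is the lossless prefix-tree aggregation behind the
radial pathway plots: each node carries the number of patients whose
sequence starts with the node's prefix, and the original pathway frequency
table can be reconstructed exactly from the tree.  ``run_all`` chains
validate -> cohort -> sequences -> pathways -> strata -> trend and writes
all outputs plus a human-readable summary, logging one line per stage with
row counts so the inclusion cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .cdm_tables import CdmTables, ingredient_names, read_cdm
from .cohort_builder import CohortDefinition, build_cohort, cohort_to_frame
from .pathway_sequencer import (
    PathwayTable,
    asm_count_distribution,
    asm_frequency,
    build_all_sequences,
    count_pathways,
)
from .stratify_trends import annual_monotherapy_trend, stratified_pathways

__all__ = ["SunburstNode", "RunConfig", "pathway_to_sunburst", "sunburst_to_table", "run_all"]

logger = logging.getLogger("epipathways")


@dataclasses.dataclass
class SunburstNode:
    """One prefix-tree node: an ingredient (or the root) with patient count."""

    name: str
    n_patients: int
    children: list["SunburstNode"] = dataclasses.field(default_factory=list)
    concept_id: int | None = None  # None for the root

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concept_id": self.concept_id,
            "n_patients": self.n_patients,
            "children": [c.to_dict() for c in self.children],
        }


def pathway_to_sunburst(
    table: PathwayTable, vocabulary: pd.DataFrame | None = None
) -> SunburstNode:
    """Aggregate a pathway table into a prefix tree (root count = cohort size)."""
    names = ingredient_names(vocabulary) if vocabulary is not None else {}
    root = SunburstNode("root", table.total_patients)
    index: dict[tuple[int, ...], SunburstNode] = {(): root}
    for seq, n in sorted(table.rows, key=lambda r: r[0]):
        for depth in range(1, len(seq) + 1):
            prefix = seq[:depth]
            if prefix not in index:
                node = SunburstNode(
                    names.get(prefix[-1], str(prefix[-1])), 0, concept_id=int(prefix[-1])
                )
                index[prefix[:-1]].children.append(node)
                index[prefix] = node
            index[prefix].n_patients += n
    return root


def sunburst_to_table(root: SunburstNode) -> PathwayTable:
    """Invert :func:`pathway_to_sunburst` exactly.

    A node's terminal count (its own count minus its children's sum) is the
    number of patients whose sequence ends there.
    """
    rows: list[tuple[tuple[int, ...], int]] = []

    def walk(node: SunburstNode, prefix: tuple[int, ...]) -> None:
        terminal = node.n_patients - sum(c.n_patients for c in node.children)
        if prefix and terminal > 0:
            rows.append((prefix, terminal))
        for child in node.children:
            walk(child, prefix + (child.concept_id,))

    walk(root, ())
    rows.sort(key=lambda kv: (-kv[1], tuple(map(str, kv[0]))))
    return PathwayTable(rows=rows, total_patients=root.n_patients)


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    cdm_dir: str
    out_dir: str
    definition: CohortDefinition = dataclasses.field(default_factory=CohortDefinition)
    sequence_window_days: int | None = 730
    dre_threshold: int = 3
    stratify_kinds: tuple[str, ...] = ("epilepsy_type", "onset_age", "syndrome")
    log_level: str = "INFO"


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the in-memory report bundle.

    Writes cohort.csv, pathways.csv, dist.json, sunburst.json,
    strata/<kind>.csv, trend.csv and summary.txt under ``config.out_dir``.
    Output is deterministic for fixed inputs and config.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=read_cdm dir=%s", config.cdm_dir)
    tables = read_cdm(config.cdm_dir)
    logger.info("stage=validate persons=%d exposures=%d",
                len(tables.persons), len(tables.drug_exposures))

    members = build_cohort(tables, config.definition)
    logger.info("stage=build_cohort in=%d out=%d", len(tables.persons), len(members))
    cohort_df = cohort_to_frame(members)
    cohort_out = cohort_df.copy()
    cohort_out["index_date"] = pd.to_datetime(cohort_out["index_date"]).dt.strftime("%Y-%m-%d")
    cohort_out["age_at_index"] = cohort_out["age_at_index"].round(4)
    cohort_out.to_csv(out / "cohort.csv", index=False)

    sequences = build_all_sequences(tables, members, window_days=config.sequence_window_days)
    logger.info("stage=sequences n=%d", len(sequences))

    table = count_pathways(sequences, tables.vocabulary)
    table.to_frame(tables.vocabulary).to_csv(out / "pathways.csv", index=False)
    logger.info("stage=pathways distinct=%d", len(table.rows))

    dist = asm_count_distribution(sequences, threshold=config.dre_threshold)
    (out / "dist.json").write_text(json.dumps(dist, indent=2, sort_keys=True))

    sunburst = pathway_to_sunburst(table, tables.vocabulary)
    (out / "sunburst.json").write_text(json.dumps(sunburst.to_dict(), indent=2, sort_keys=True))

    strata_results = {}
    strata_dir = out / "strata"
    strata_dir.mkdir(exist_ok=True)
    for kind in config.stratify_kinds:
        results = stratified_pathways(tables, members, sequences, kind)
        strata_results[kind] = results
        rows = []
        for name, res in results.items():
            rows.append({
                "stratum": name,
                "n_patients": res.distribution["total"],
                "dre_pct": res.dre_pct,
                "pct_1": res.distribution["percentages"]["1"],
                "pct_2": res.distribution["percentages"]["2"],
                "pct_3plus": res.distribution["percentages"]["3+"],
            })
        pd.DataFrame(rows).to_csv(strata_dir / f"{kind}.csv", index=False)
        logger.info("stage=stratify kind=%s strata=%d", kind, len(results))

    trend = annual_monotherapy_trend(tables, members)
    trend.to_csv(out / "trend.csv", index=False)
    logger.info("stage=trend rows=%d", len(trend))

    shares = asm_frequency(sequences)
    names = ingredient_names(tables.vocabulary)
    top5 = sorted(shares.items(), key=lambda kv: (-kv[1], names.get(kv[0], "")))[:5]

    lines = [
        f"cohort size: {len(members)}",
        f"distinct treatment pathways: {len(table.rows)}",
        "ASM count distribution (% of cohort): "
        + ", ".join(f"{k}: {v}%" for k, v in dist["percentages"].items()),
        f"drug-resistant (>= {config.dre_threshold} ASMs): {dist['percentages']['3+']}%",
        "top-5 ASM shares: "
        + ", ".join(f"{names.get(cid, cid)} {100 * share:.1f}%" for cid, share in top5),
    ]
    for kind, results in strata_results.items():
        for name, res in results.items():
            lines.append(
                f"stratum[{kind}] {name}: n={res.distribution['total']}, DRE={res.dre_pct}%"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("stage=summary written=%s", out / "summary.txt")

    return {
        "tables": tables,
        "members": members,
        "sequences": sequences,
        "pathways": table,
        "distribution": dist,
        "sunburst": sunburst,
        "strata": strata_results,
        "trend": trend,
        "asm_shares": shares,
    }
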