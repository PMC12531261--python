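#!/usr/bin/env python
"""Differential taxa across disease stages.

Per site: pairwise Wilcoxon rank-sum volcano tables (NM vs NC, M vs NC,
M vs NM) with BH-FDR and log2 fold changes on mean relative abundance
(enriched: log2FC > 1 and p < 0.05; depleted: mirrored), plus the
Kruskal-Wallis three-group screen and the monotone-trend taxa along
NC -> NM -> M. Genus-level aggregates use the synthetic taxonomy.

Writes volcano tables and monotone-taxon lists under results/differential/.
"""

import json
from pathlib import Path

import pandas as pd

from microstage import diff_abundance, tables_io
from microstage.tables_io import GROUPS

BASE = Path(__file__).resolve().parent.parent / "results"
COMPARISONS = [("NM", "NC"), ("M", "NC"), ("M", "NM")]


def main() -> None:
    meta = tables_io.read_metadata(BASE / "cohort" / "metadata.tsv")
    out = BASE / "differential"
    out.mkdir(parents=True, exist_ok=True)
    monotone = {}
    for site in ("feces", "saliva"):
        table = tables_io.read_asv_table(BASE / "cohort" / f"{site}.tsv", site=site)
        props = tables_io.relative_abundance(table)
        groups = meta.groups_for(table.sample_ids)
        for front, rear in COMPARISONS:
            res = diff_abundance.compare_groups(props, groups, front, rear)
            res.to_csv(out / f"volcano_{site}_{front}_vs_{rear}.tsv", sep="\t")
            counts = diff_abundance.volcano_classify(res)
            print(f"{site} {front} vs {rear}: {counts['differential']} differential "
                  f"ASVs ({counts['enriched']} enriched, {counts['depleted']} depleted)")
        kw = diff_abundance.kruskal_three(
            [props.loc[groups[groups == g].index] for g in GROUPS])
        means = pd.DataFrame(
            {g: props.loc[groups[groups == g].index].mean(axis=0) for g in GROUPS})
        mono = diff_abundance.monotone_taxa(means, kw["p"], top_k=10)
        monotone[site] = mono
        print(f"{site}: {len(mono['increasing'])} monotonically increasing, "
              f"{len(mono['decreasing'])} decreasing taxa (top 10 each)")
    (out / "monotone_taxa.json").write_text(json.dumps(monotone, indent=2))


if __name__ == "__main__":
    main()
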