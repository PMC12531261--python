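#!/usr/bin/env python
"""Three-class diagnostic staging (NC / NM / M) from key-ASV abundances.

Per site: rank ASVs by MeanDecreaseGini and MeanDecreaseAccuracy, then run
stratified five-fold cross-validation with top-8 Gini selection repeated
inside each training fold (leakage-safe), and report accuracy, Cohen's
kappa, log loss, macro/micro F1 and one-vs-rest per-class/macro/micro AUC
on the pooled out-of-fold probabilities.

Writes importance tables and classifier reports under results/classifier/.
"""

import json
from pathlib import Path

from microstage import stage_classifier, tables_io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    meta = tables_io.read_metadata(BASE / "cohort" / "metadata.tsv")
    out = BASE / "classifier"
    out.mkdir(parents=True, exist_ok=True)
    for site in ("feces", "saliva"):
        table = tables_io.read_asv_table(BASE / "cohort" / f"{site}.tsv", site=site)
        key = tables_io.prevalence_filter(table, 1 / 3)
        props = key.counts.div(table.counts.sum(axis=1), axis=0)
        y = meta.groups_for(key.counts.index.tolist()).to_numpy()
        importance = stage_classifier.rank_features(props, y, n_trees=500, seed=SEED)
        importance.sort_values("rank_gini").to_csv(
            out / f"{site}_importance.tsv", sep="\t")
        report = stage_classifier.evaluate_cv(
            props, y, top_k=8, folds=5, n_trees=500, seed=SEED)
        (out / f"{site}_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        print(f"{site} model ({key.n_asvs} candidate ASVs, top-8 Gini panel):")
        print(f"  accuracy {100 * report.accuracy:.2f}%, kappa {report.kappa:.2f}, "
              f"log loss {report.log_loss:.2f}")
        print(f"  macro-F1 {report.macro_f1:.2f}, macro-AUC "
              f"{100 * report.macro_auc:.2f}%, micro-AUC {100 * report.micro_auc:.2f}%")


if __name__ == "__main__":
    main()
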