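"""End-to-end orchestration of the stage-stratified analysis.

One config drives the full chain per body site: prevalence filter to the key
ASVs, per-group SparCC correlations, co-occurrence networks, natural-
connectivity robustness curves, oral-to-gut source tracking (feces only),
ordination + ANOSIM, pairwise differential abundance with volcano counts,
and the three-class random-forest stage classifier. The report is a plain
dict (JSON-serializable, no timestamps) so identical config + seed gives a
byte-identical report; per-stage seeds are derived from the global seed by
hashing the stage name, so adding a stage never perturbs the others.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (
    cooc_network,
    diff_abundance,
    ordination,
    robustness,
    source_tracker,
    sparcc,
    synthetic_data,
    tables_io,
)
from .tables_io import GROUPS

logger = logging.getLogger("microstage")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a stable hash of
    the stage name (crc32, not Python's randomized hash)."""
    return int((global_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    prevalence_fraction: float = 1 / 3
    prevalence_mode: str = "pooled"
    sparcc_pseudocount: float = 1.0
    sparcc_exclusion_threshold: float = 0.1
    sparcc_max_exclusions: int = 10
    sparcc_bootstraps: int = 99
    network_r_min: float = 0.3
    network_alpha: float = 0.05
    robustness_strategy: str = "random"
    robustness_repeats: int = 100
    source_rarefaction_depth: int = 1000
    source_burn: int = 100
    source_draws: int = 100
    source_restarts: int = 10
    source_alpha: float = 0.001
    source_beta: float = 0.01
    source_detection_threshold: float = 0.001
    anosim_permutations: int = 999
    volcano_p_max: float = 0.05
    volcano_lfc_min: float = 1.0
    classifier_top_k: int = 8
    classifier_folds: int = 5
    classifier_trees: int = 500
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # forwarded to CohortConfig

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.prevalence_fraction <= 1:
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if not 0 <= self.network_alpha <= 1:
            raise ValueError("network_alpha must be in [0, 1]")
        if self.network_r_min < 0:
            raise ValueError("network_r_min must be >= 0")
        if self.classifier_folds < 2:
            raise ValueError("classifier_folds must be >= 2")


def _log_stage(name, t0, **shapes):
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
                " ".join(f"{k}={v}" for k, v in shapes.items()))


def run_pipeline(config: PipelineConfig, feces=None, saliva=None, metadata=None,
                 out_dir=None) -> dict:
    """Run every stage; returns the JSON-ready report.

    If tables are not supplied, a synthetic cohort is generated from
    ``config.cohort`` (seeded from the global seed). Stage failures are
    recorded in the report and dependent stages are skipped; independent
    stages still run.
    """
    config.validate()
    report: dict = {"config": asdict(config), "stages": {}, "errors": {}}

    if feces is None or saliva is None or metadata is None:
        t0 = time.time()
        cc = synthetic_data.CohortConfig(
            **{"seed": stage_seed(config.seed, "simulate"), **config.cohort}
        )
        feces, saliva, metadata, truth = synthetic_data.generate_cohort(cc)
        report["stages"]["simulate"] = {
            "n_fecal_samples": feces.n_samples, "n_salivary_samples": saliva.n_samples,
            "depth": cc.depth,
        }
        _log_stage("simulate", t0, feces=feces.counts.shape, saliva=saliva.counts.shape)

    tables = {"feces": feces, "saliva": saliva}
    key_tables: dict = {}

    # --- key ASVs (prevalence filter per site, pooled across groups) ---
    for site, tab in tables.items():
        key = tables_io.prevalence_filter(
            tab, config.prevalence_fraction, metadata=metadata,
            mode=config.prevalence_mode,
        )
        key_tables[site] = key
        report["stages"].setdefault("key_asvs", {})[site] = key.n_asvs

    # --- ordination + ANOSIM per site ---
    for site, tab in tables.items():
        t0 = time.time()
        try:
            d = ordination.bray_curtis(tab)
            groups = metadata.groups_for(tab.sample_ids)
            res = ordination.anosim(
                d, groups, n_permutations=config.anosim_permutations,
                seed=stage_seed(config.seed, f"anosim_{site}"),
            )
            report["stages"].setdefault("anosim", {})[site] = {
                "R": res.R, "p": res.p, "n_permutations": res.n_permutations,
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report["errors"][f"anosim_{site}"] = str(exc)
        _log_stage(f"anosim_{site}", t0, n=tab.n_samples)

    # --- per-group SparCC -> networks -> robustness, per site ---
    networks: dict = {}
    for site, key in key_tables.items():
        curves = []
        for group in GROUPS:
            t0 = time.time()
            name = f"network_{site}_{group}"
            try:
                ids = [s for s in metadata.samples_of(group=group, site=site)
                       if s in key.counts.index]
                sub = key.counts.loc[ids]
                if key.n_asvs < 4:
                    raise ValueError("fewer than 4 key ASVs; network skipped")
                corr = sparcc.sparcc(
                    tables_io.AsvTable(sub, site=site, require_positive_totals=False),
                    pseudocount=config.sparcc_pseudocount,
                    exclusion_threshold=config.sparcc_exclusion_threshold,
                    max_exclusions=config.sparcc_max_exclusions,
                    n_bootstrap=config.sparcc_bootstraps,
                    seed=stage_seed(config.seed, name),
                )
                net = cooc_network.build_network(
                    corr, r_min=config.network_r_min, alpha=config.network_alpha,
                    group=group, site=site,
                )
                networks[(group, site)] = net
                summary = cooc_network.network_summary(net)
                report["stages"].setdefault("networks", {})[f"{site}_{group}"] = summary
                curve = robustness.removal_curve(
                    net, strategy=config.robustness_strategy,
                    repeats=config.robustness_repeats,
                    seed=stage_seed(config.seed, f"robustness_{site}_{group}"),
                )
                curves.append(curve)
            except Exception as exc:  # noqa: BLE001
                report["errors"][name] = str(exc)
            _log_stage(name, t0, n_asvs=key.n_asvs)
        if curves:
            ranking = robustness.compare_curves(curves)
            report["stages"].setdefault("robustness", {})[site] = {
                row["group"]: {"auc": row["auc"], "rank": int(row["rank"]),
                               "n_nodes": int(row["n_nodes"])}
                for _, row in ranking.iterrows()
            }

    # --- Venn / shared ASVs per group ---
    shared_tables = {}
    for group in GROUPS:
        for site, tab in tables.items():
            ids = [s for s in metadata.samples_of(group=group, site=site)
                   if s in tab.counts.index]
            shared_tables[(group, site)] = tables_io.AsvTable(
                tab.counts.loc[ids], site=site)
    venn = cooc_network.shared_asv_counts(shared_tables)
    report["stages"]["shared_asvs"] = {
        g: {k: int(v) for k, v in row.items()} for g, row in venn.iterrows()
    }

    # --- source tracking: saliva -> feces ---
    t0 = time.time()
    try:
        estimates = source_tracker.track_cohort(
            feces, saliva, metadata,
            n_burn=config.source_burn, n_draws=config.source_draws,
            restarts=config.source_restarts,
            rarefaction_depth=config.source_rarefaction_depth,
            alpha=config.source_alpha, beta=config.source_beta,
            seed=stage_seed(config.seed, "source_tracking"),
        )
        summary = source_tracker.cohort_source_summary(
            estimates, metadata,
            detection_threshold=config.source_detection_threshold,
        )
        report["stages"]["source_tracking"] = {
            g: {k: float(v) for k, v in row.items()} for g, row in summary.iterrows()
        }
    except Exception as exc:  # noqa: BLE001
        report["errors"]["source_tracking"] = str(exc)
    _log_stage("source_tracking", t0, n_sinks=feces.n_samples)

    # --- differential abundance, pairwise volcano counts per site ---
    comparisons = [("NM", "NC"), ("M", "NC"), ("M", "NM")]
    for site, tab in tables.items():
        t0 = time.time()
        try:
            props = tables_io.relative_abundance(tab)
            groups = metadata.groups_for(tab.sample_ids)
            for front, rear in comparisons:
                res = diff_abundance.compare_groups(
                    props, groups, front, rear, eps=1e-6)
                counts = diff_abundance.volcano_classify(
                    res, p_max=config.volcano_p_max, lfc_min=config.volcano_lfc_min)
                report["stages"].setdefault("differential", {}).setdefault(site, {})[
                    f"{front}_vs_{rear}"] = counts
        except Exception as exc:  # noqa: BLE001
            report["errors"][f"differential_{site}"] = str(exc)
        _log_stage(f"differential_{site}", t0, n_taxa=tab.n_asvs)

    # --- stage classifier per site, on key-ASV relative abundances ---
    from . import stage_classifier  # local import: heaviest dependency chain
    for site, key in key_tables.items():
        t0 = time.time()
        try:
            if key.n_asvs == 0:
                raise ValueError("no key ASVs to classify on")
            props = key.counts.div(tables[site].counts.sum(axis=1), axis=0)
            y = metadata.groups_for(key.counts.index.tolist()).to_numpy()
            rep = stage_classifier.evaluate_cv(
                props, y, top_k=config.classifier_top_k,
                folds=config.classifier_folds, n_trees=config.classifier_trees,
                seed=stage_seed(config.seed, f"classifier_{site}"),
            )
            report["stages"].setdefault("classifier", {})[site] = rep.to_dict()
        except Exception as exc:  # noqa: BLE001
            report["errors"][f"classifier_{site}"] = str(exc)
        _log_stage(f"classifier_{site}", t0, n_features=key.n_asvs)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report_json(report))
        for (group, site), net in networks.items():
            cooc_network.write_edge_list(net, out_dir / f"edges_{site}_{group}.tsv")
    return report


def report_json(report: dict) -> str:
    """Canonical serialization: sorted keys, fixed float formatting."""
    return json.dumps(report, indent=2, sort_keys=True, default=float)
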