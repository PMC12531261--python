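"""Synthetic three-group, two-site ASV cohort generator.

Emulates a case/control colorectal-cancer cohort: three groups (NC healthy,
NM nonmetastatic, M metastatic), each subject contributing one fecal and one
matching salivary sample. Three signals are planted on top of multinomial
sequencing noise, and every planted value is recorded in a :class:`GroundTruth`
object so downstream estimators can be tested for parameter recovery:

* group-specific co-abundance structure — latent log abundances are
  multivariate normal with unit variances and off-diagonal correlations set
  to the planted targets, so groups differ in network connectivity;
* oral-to-gut translocation — each subject's fecal composition is a
  ``(1 - f) * gut + f * saliva`` mixture of that subject's own latent
  salivary composition, with ``f`` fixed per group;
* differentially abundant taxa — per-group multiplicative fold changes on
  the latent means.

Observed counts are a single multinomial draw of the sequencing depth from
the latent composition; zeros arise only from sampling, which keeps
prevalence controllable through depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import GROUPS, AsvTable, SampleMetadata, expand_lineages

# Group-wise saliva-derived fractions of the fecal community. The defaults
# encode the oral-to-gut translocation gradient this pipeline is built to
# detect: ~1.7% in healthy controls rising to ~14.9% in metastatic disease.
DEFAULT_TRANSLOCATION = {"NC": 0.017, "NM": 0.032, "M": 0.149}


MODULE_SIZES = {
    "feces": {"NC": (14, 10, 8), "NM": (10, 8), "M": (6,)},
    "saliva": {"NC": (6,), "NM": (10, 8), "M": (14, 10, 8)},
}


def default_planted_edges(
    n_asvs_feces: int, n_asvs_saliva: int, target_r: float = 0.7
) -> dict:
    """Planted co-abundance modules realizing opposite connectivity gradients.

    Each module is a block of taxa with pairwise correlation ``target_r``
    (an equicorrelated block — the covariance stays positive-definite and the
    binarized module is spectrally strong, like the dense co-abundance
    clusters seen in real microbial networks). Fecal networks lose modules
    along NC -> NM -> M while salivary networks gain them: the
    destabilizing-gut / stabilizing-oral pattern the robustness stage must
    recover.
    """
    edges: dict = {}
    for site, n_asvs, prefix in (
        ("feces", n_asvs_feces, "F"),
        ("saliva", n_asvs_saliva, "S"),
    ):
        for group, sizes in MODULE_SIZES[site].items():
            pairs = []
            start = 0
            for size in sizes:
                size = min(size, max(0, n_asvs - start))
                members = [f"ASV_{prefix}{start + k:04d}" for k in range(size)]
                pairs.extend(
                    (members[a], members[b], target_r)
                    for a in range(size) for b in range(a + 1, size)
                )
                start += size
            edges[(group, site)] = pairs
    return edges


def default_differential_taxa(n_asvs_feces: int) -> list:
    """Six fecal taxa with monotone +/-2 log2 fold changes along NC -> NM -> M.

    Uses the last six fecal taxa so the defaults stay clear of the planted
    edge pairs (which occupy the low indices) at the default table size.
    """
    idx = range(max(0, n_asvs_feces - 6), n_asvs_feces)
    out = []
    for pos, k in enumerate(idx):
        direction = 1.0 if pos < 3 else -1.0
        out.append(
            (f"ASV_F{k:04d}", {"NC": 0.0, "NM": direction, "M": 2.0 * direction})
        )
    return out


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_group: int = 30
    n_asvs_feces: int = 120
    n_asvs_saliva: int = 160
    depth: int = 10_000
    planted_edges: dict | None = None  # (group, site) -> [(asv_i, asv_j, r)]
    translocation_fraction: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSLOCATION)
    )
    differential_taxa: list | None = None  # [(asv, {group: log2fc})]
    cross_site_baseline: float = 1e-4  # off-site taxa floor in latent composition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        for g, f in self.translocation_fraction.items():
            if not 0 <= f < 1:
                raise ValueError(f"translocation_fraction[{g}] must be in [0, 1)")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges(
                self.n_asvs_feces, self.n_asvs_saliva
            )
        if self.differential_taxa is None:
            self.differential_taxa = default_differential_taxa(self.n_asvs_feces)
        for pairs in self.planted_edges.values():
            for i, j, r in pairs:
                if abs(r) > 0.95:
                    raise ValueError(f"planted |r| > 0.95 for edge ({i}, {j})")


@dataclass
class GroundTruth:
    """Planted parameters, recorded before observation noise is applied."""

    saliva_fraction: dict  # fecal sample_id -> true f
    edges: dict  # "group|site" -> [(asv_i, asv_j, r)]
    log2_fold_changes: dict  # asv -> {group: lfc}
    seed: int

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "saliva_fraction": self.saliva_fraction,
            "edges": {k: [list(e) for e in v] for k, v in self.edges.items()},
            "log2_fold_changes": self.log2_fold_changes,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _planted_covariance(asv_ids: list, pairs: list) -> np.ndarray:
    p = len(asv_ids)
    idx = {a: k for k, a in enumerate(asv_ids)}
    cov = np.eye(p)
    for i, j, r in pairs:
        if i not in idx or j not in idx:
            raise ValueError(f"planted edge references unknown ASV ({i}, {j})")
        cov[idx[i], idx[j]] = cov[idx[j], idx[i]] = r
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"planted covariance not positive-definite; offending edges: {pairs}"
        ) from None
    return cov


def _site_mean_logabund(rng, own_ids, other_ids, baseline):
    """Latent mean log abundances: own-site taxa spread over ~4 nats, off-site
    taxa at a small floor so the two body sites share a vocabulary but have
    clearly distinct compositions."""
    mu_own = rng.normal(loc=0.0, scale=1.5, size=len(own_ids))
    mu = pd.Series(np.log(baseline), index=list(own_ids) + list(other_ids))
    mu.loc[list(own_ids)] = mu_own
    return mu


def generate_cohort(config: CohortConfig):
    """Draw one cohort.

    Returns ``(feces: AsvTable, saliva: AsvTable, metadata: SampleMetadata,
    truth: GroundTruth)``. Identical config (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    fecal_ids = [f"ASV_F{k:04d}" for k in range(config.n_asvs_feces)]
    saliva_ids = [f"ASV_S{k:04d}" for k in range(config.n_asvs_saliva)]
    vocab = fecal_ids + saliva_ids

    mu_gut = _site_mean_logabund(rng, fecal_ids, saliva_ids, config.cross_site_baseline)
    mu_oral = _site_mean_logabund(rng, saliva_ids, fecal_ids, config.cross_site_baseline)
    mu_gut = mu_gut.reindex(vocab)
    mu_oral = mu_oral.reindex(vocab)

    lfc = {asv: dict(vec) for asv, vec in config.differential_taxa}

    rows_f, rows_s, meta_rows = [], [], []
    truth_fraction = {}
    for group in GROUPS:
        cov_f = _planted_covariance(vocab, config.planted_edges.get((group, "feces"), []))
        cov_s = _planted_covariance(vocab, config.planted_edges.get((group, "saliva"), []))
        chol_f = np.linalg.cholesky(cov_f)
        chol_s = np.linalg.cholesky(cov_s)
        mu_g = mu_gut.to_numpy().copy()
        mu_o = mu_oral.to_numpy().copy()
        for asv, vec in lfc.items():
            k = vocab.index(asv)
            shift = vec.get(group, 0.0) * np.log(2.0)
            mu_g[k] += shift
            mu_o[k] += shift
        f = config.translocation_fraction.get(group, 0.0)
        for s in range(config.n_per_group):
            subject = f"{group}_{s:03d}"
            z_gut = mu_g + chol_f @ rng.standard_normal(len(vocab))
            z_oral = mu_o + chol_s @ rng.standard_normal(len(vocab))
            comp_oral = np.exp(z_oral)
            comp_oral /= comp_oral.sum()
            comp_gut = np.exp(z_gut)
            comp_gut /= comp_gut.sum()
            comp_fecal = (1.0 - f) * comp_gut + f * comp_oral

            fec_id, sal_id = f"{subject}_F", f"{subject}_S"
            rows_f.append(pd.Series(
                rng.multinomial(config.depth, comp_fecal), index=vocab, name=fec_id))
            rows_s.append(pd.Series(
                rng.multinomial(config.depth, comp_oral), index=vocab, name=sal_id))
            truth_fraction[fec_id] = f
            meta_rows.append((fec_id, subject, group, "feces"))
            meta_rows.append((sal_id, subject, group, "saliva"))

    feces = AsvTable(pd.DataFrame(rows_f), site="feces")
    saliva = AsvTable(pd.DataFrame(rows_s), site="saliva")
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "group", "site"]))
    truth = GroundTruth(
        saliva_fraction=truth_fraction,
        edges={f"{g}|{site}": list(v) for (g, site), v in config.planted_edges.items()},
        log2_fold_changes=lfc,
        seed=config.seed,
    )
    return feces, saliva, meta, truth


def synthetic_taxonomy(asv_ids, n_genera: int = 24, n_phyla: int = 4, seed: int = 0) -> pd.DataFrame:
    """Assign plausible fake lineages (synthetic stand-in for a real
    classifier's output) so rank-level aggregation can be exercised."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for asv in asv_ids:
        g = rng.integers(n_genera)
        p = g % n_phyla
        lineages[asv] = (
            f"Bacteria;Phylum_{p};Class_{p};Order_{g % 8};Family_{g % 12};"
            f"Genus_{g};{asv}_sp"
        )
    return expand_lineages(pd.Series(lineages))


def permute_labels(metadata: SampleMetadata, seed: int) -> SampleMetadata:
    """Permute group labels within each body site; all other fields unchanged.

    Produces a null cohort: any group signal is destroyed while per-site group
    sizes and the sample/subject bookkeeping are preserved.
    """
    rng = np.random.default_rng(seed)
    frame = metadata.frame.copy()
    for site in frame["site"].unique():
        mask = (frame["site"] == site).to_numpy()
        labels = frame.loc[mask, "group"].to_numpy()
        frame.loc[mask, "group"] = rng.permutation(labels)
    return SampleMetadata(frame)
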