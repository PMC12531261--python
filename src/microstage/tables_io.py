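"""Reading, validation, filtering and taxonomic aggregation of ASV count tables.

Count tables are samples x ASVs integer matrices carried as pandas DataFrames
(index = sample identifiers, columns = ASV identifiers). Files are plain TSV:
one header row, first column holds identifiers; both orientations (samples in
rows or ASVs in rows) are accepted behind an explicit ``orientation`` flag —
square tables make silent auto-detection unsafe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

GROUPS = ("NC", "NM", "M")
SITES = ("feces", "saliva")


class TableValidationError(ValueError):
    """Raised when a count table violates its invariants."""


@dataclass
class AsvTable:
    """Integer ASV count matrix (samples x ASVs) for one body site.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer matrix; index = sample ids, columns = ASV ids.
    site : str
        One of ``feces``, ``saliva`` or ``mixed``.
    """

    counts: pd.DataFrame
    site: str = "mixed"
    require_positive_totals: bool = True

    def __post_init__(self) -> None:
        if self.site not in SITES + ("mixed",):
            raise TableValidationError(f"unknown site {self.site!r}")
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate ASV identifiers: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("non-numeric entries in count table")
        if (arr < 0).any():
            raise TableValidationError("negative entries in count table")
        if not np.allclose(arr, np.round(arr)):
            raise TableValidationError("non-integer entries in count table")
        self.counts = c.astype(np.int64)
        if self.require_positive_totals:
            totals = self.counts.sum(axis=1)
            if (totals == 0).any():
                empty = totals.index[totals == 0].tolist()
                raise TableValidationError(f"samples with zero total count: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)], site=self.site)


@dataclass
class SampleMetadata:
    """Per-sample annotations: subject, disease group and body site."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "subject_id", "group", "site")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        if f["sample_id"].duplicated().any():
            raise TableValidationError("duplicate sample_id in metadata")
        bad_g = set(f["group"]) - set(GROUPS)
        if bad_g:
            raise TableValidationError(f"unknown groups: {sorted(bad_g)}")
        bad_s = set(f["site"]) - set(SITES)
        if bad_s:
            raise TableValidationError(f"unknown sites: {sorted(bad_s)}")
        if f[list(self.REQUIRED)].isna().any().any():
            raise TableValidationError("missing values in required metadata columns")
        self.frame = f.reset_index(drop=True)

    def groups_for(self, sample_ids) -> pd.Series:
        lookup = self.frame.set_index("sample_id")["group"]
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise TableValidationError(f"samples without metadata: {missing}")
        return lookup.loc[list(sample_ids)]

    def samples_of(self, group: str | None = None, site: str | None = None) -> list[str]:
        f = self.frame
        if group is not None:
            f = f[f["group"] == group]
        if site is not None:
            f = f[f["site"] == site]
        return f["sample_id"].tolist()


def read_asv_table(path, orientation: str = "sample_rows", site: str = "mixed") -> AsvTable:
    """Read a TSV count table.

    ``orientation`` declares the layout: ``sample_rows`` (samples in rows) or
    ``asv_rows`` (ASVs in rows; the table is transposed on read). A trailing
    ``taxonomy`` column, common in BIOM-style TSV exports, is dropped.
    """
    if orientation not in ("sample_rows", "asv_rows"):
        raise ValueError(f"orientation must be sample_rows or asv_rows, got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "taxonomy" in df.columns:
        df = df.drop(columns=["taxonomy"])
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r} in {path}"
            )
    if orientation == "asv_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return AsvTable(df, site=site)


def write_asv_table(table: AsvTable, path) -> None:
    """Write counts as TSV (samples in rows, deterministic column order)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV (asv_id, semicolon-delimited lineage) into ranked columns.

    Missing ranks propagate as ``unclassified_<parent>`` rather than being
    dropped, so every ASV keeps a label at every rank.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if not {"asv_id", "lineage"}.issubset(raw.columns):
        raise TableValidationError("taxonomy TSV needs columns asv_id, lineage")
    return expand_lineages(raw.set_index("asv_id")["lineage"])


def expand_lineages(lineage: pd.Series) -> pd.DataFrame:
    rows = {}
    for asv, lin in lineage.items():
        parts = [p.strip() for p in str(lin).split(";")]
        labels = []
        parent = "root"
        for i, rank in enumerate(RANKS):
            lab = parts[i] if i < len(parts) and parts[i] not in ("", "unclassified", "nan") else ""
            if not lab:
                lab = f"unclassified_{parent}"
            labels.append(lab)
            parent = lab
        rows[asv] = labels
    out = pd.DataFrame.from_dict(rows, orient="index", columns=RANKS)
    out.index.name = "asv_id"
    return out


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample proportions; each row sums to one."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise TableValidationError(
            f"zero-total samples: {totals.index[totals == 0].tolist()}"
        )
    return table.counts.div(totals, axis=0)


def prevalence_filter(
    table: AsvTable,
    min_fraction: float,
    metadata: SampleMetadata | None = None,
    mode: str = "pooled",
) -> AsvTable:
    """Retain ASVs present (nonzero) in at least ceil(min_fraction * n) samples.

    ``mode='pooled'`` (default) computes prevalence over all samples of the
    table; ``mode='per_group'`` retains an ASV if it clears the threshold
    within at least one group (requires ``metadata``). Pooled prevalence gives
    a single shared node set per body site so per-group networks are
    comparable node-for-node.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    present = table.counts > 0
    if mode == "pooled":
        need = int(np.ceil(min_fraction * table.n_samples))
        keep = present.sum(axis=0) >= need
    elif mode == "per_group":
        if metadata is None:
            raise ValueError("per_group mode requires metadata")
        groups = metadata.groups_for(table.sample_ids)
        keep = pd.Series(False, index=table.counts.columns)
        for g, idx in groups.groupby(groups).groups.items():
            sub = present.loc[list(idx)]
            need = int(np.ceil(min_fraction * len(idx)))
            keep |= sub.sum(axis=0) >= need
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = table.counts.loc[:, keep.to_numpy()]
    # an empty ASV set is legal downstream (0-node networks)
    return AsvTable(kept, site=table.site, require_positive_totals=False)


def aggregate_taxa(
    table: AsvTable, taxonomy: pd.DataFrame, rank: str, top_k: int
) -> pd.DataFrame:
    """Sum per-sample proportions within taxa of ``rank``; merge all but the
    ``top_k`` most abundant (by grand mean proportion) into an ``Others`` bucket.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    props = relative_abundance(table)
    labels = taxonomy[rank].reindex(props.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise TableValidationError(f"ASVs without taxonomy: {missing}")
    agg = props.T.groupby(labels.to_numpy()).sum().T
    order = agg.mean(axis=0).sort_values(ascending=False, kind="stable")
    top = list(order.index[:top_k])
    out = agg[top].copy()
    rest = [t for t in order.index if t not in top]
    if rest:
        out["Others"] = agg[rest].sum(axis=1)
    return out
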