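"""Tabular I/O for expression matrices, gene sets, and pooled-screen count tables.

All matrix-like inputs are plain TSV (gzip transparently supported through
pandas). Gene and sample identifiers are opaque, case-sensitive strings; no
symbol/ID mapping is attempted. Expression matrices carry TPM values
(transcripts per million) and must be complete — missing values are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ScreenCountTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_screen_counts",
    "write_screen_counts",
]

#: float format used by every writer; round-trips are exact to 6 significant digits
FLOAT_FMT = "%.6g"


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with a cohort label per sample.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``cohort_of`` is a Series mapping sample id -> cohort label, aligned to the
    matrix columns.
    """

    values: pd.DataFrame
    cohort_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        arr0 = self.values.to_numpy()
        if not np.issubdtype(arr0.dtype, np.number):
            raise ValueError("expression values must be numeric TPM")
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)].tolist()
            raise ValueError(f"negative TPM values for genes: {bad}")
        missing = [s for s in self.values.columns if s not in self.cohort_of.index]
        if missing:
            raise ValueError(f"samples missing a cohort label: {missing}")
        # align cohort labels to matrix column order, dropping metadata-only samples
        extra = [s for s in self.cohort_of.index if s not in set(self.values.columns)]
        if extra:
            logger.warning(
                "ignoring %d metadata-only samples absent from the matrix", len(extra)
            )
        self.cohort_of = self.cohort_of.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.cohort_of.unique())

    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_cohort(self, cohort: str) -> "ExpressionMatrix":
        """Restrict to the samples of one cohort."""
        keep = self.cohort_of.index[self.cohort_of == cohort]
        if len(keep) == 0:
            raise KeyError(f"no samples in cohort {cohort!r}")
        return ExpressionMatrix(self.values[keep], self.cohort_of.loc[keep])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.cohort_of.equals(other.cohort_of)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), each with an optional description."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe, dropping sets that empty out."""
        kept: dict[str, set[str]] = {}
        dropped = 0
        for name, members in self.sets.items():
            inter = members & universe
            if inter:
                kept[name] = inter
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d gene sets empty after universe intersection", dropped)
        return GeneSetCollection(kept, {k: self.descriptions.get(k, "") for k in kept})


@dataclass
class ScreenCountTable:
    """Pooled-screen gRNA counts: guides x conditions, with a guide -> gene map."""

    counts: pd.DataFrame
    gene_of: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide identifiers: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
                raise ValueError("screen counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = self.counts.index[(arr < 0).any(axis=1)].tolist()
            raise ValueError(f"negative counts for guides: {bad}")
        unmapped = [g for g in self.counts.index if g not in self.gene_of.index]
        if unmapped:
            raise ValueError(f"guides without a gene mapping: {unmapped}")
        self.gene_of = self.gene_of.reindex(self.counts.index)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a TPM matrix TSV (first column gene id) plus a `sample<TAB>cohort` table.

    Samples present in the matrix but absent from the metadata are an error;
    metadata-only samples are ignored with a logged warning.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample", "cohort"}.issubset(meta.columns):
        raise ValueError("metadata must have columns 'sample' and 'cohort'")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in metadata: {dups}")
    cohort_of = meta.set_index("sample")["cohort"]
    return ExpressionMatrix(values, cohort_of)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format=FLOAT_FMT)
    meta = pd.DataFrame({"sample": matrix.sample_ids, "cohort": matrix.cohort_of.to_numpy()})
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: per line `name<TAB>description<TAB>member...`.

    Duplicate members inside a set are deduplicated with a warning; duplicate
    set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{gmt_path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{gmt_path}:{lineno}: duplicate gene set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                logger.warning("gene set %r: %d duplicate members removed", name, len(members) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_screen_counts(counts_path, mapping_path) -> ScreenCountTable:
    """Read a guide x condition count TSV plus a `guide<TAB>gene` mapping."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    if not {"guide", "gene"}.issubset(mapping.columns):
        raise ValueError("mapping must have columns 'guide' and 'gene'")
    if mapping["guide"].duplicated().any():
        dups = mapping.loc[mapping["guide"].duplicated(), "guide"].tolist()
        raise ValueError(f"guides mapped more than once: {dups}")
    gene_of = mapping.set_index("guide")["gene"]
    return ScreenCountTable(counts, gene_of)


def write_screen_counts(table: ScreenCountTable, counts_path, mapping_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="guide")
    pd.DataFrame({"guide": table.guide_ids, "gene": table.gene_of.to_numpy()}).to_csv(
        mapping_path, sep="\t", index=False
    )
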