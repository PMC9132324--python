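"""Readers and writers for the tab-separated interchange formats.

All on-disk formats are plain TSV:

``counts.tsv``
    header ``isoform_id  gene_id  <sample> ...``; one row per isoform,
    TPM-scale non-negative abundances.
``metadata.tsv``
    one row per sample, columns ``sample_id  sample_type  batch  purity
    bias_score  subtype  region``; purity / bias_score may be empty.
``annotation.tsv``
    columns ``gene_id  kinase_group``.
``*.gmt``
    standard gene-set format: set name, description, then member genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("primary", "metastatic")

#: the ten kinome phylogenetic groups, with the tyrosine kinases split into
#: receptor and non-receptor families.
KINASE_GROUPS = (
    "TK-RTK", "TK-nRTK", "STE", "CAMK", "CMGC", "AGC",
    "TKL", "CK1", "RGC", "Other", "aPK",
)

SUBTYPES = ("BRAF", "RAS", "NF1", "tripleWT", "unknown")

METADATA_COLUMNS = (
    "sample_type", "batch", "purity", "bias_score", "subtype", "region",
)


@dataclass
class IsoformCountMatrix:
    """Isoform x sample abundance matrix with its gene mapping.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative, finite abundances (TPM scale); index = isoform ids,
        columns = sample ids, both unique.
    gene_of : pandas.Series
        Maps every isoform id in ``values.index`` to exactly one gene id.
    """

    values: pd.DataFrame
    gene_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate isoform id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing = self.values.index.difference(self.gene_of.index)
        if len(missing) > 0:
            raise ValueError(f"isoform {missing[0]!r} has no gene mapping")
        self.gene_of = self.gene_of.reindex(self.values.index)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("abundance values must be finite")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at isoform {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def isoform_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gene_of:
            seen.setdefault(g, None)
        return list(seen)

    def isoforms_of(self, gene: str) -> list[str]:
        return list(self.gene_of.index[self.gene_of == gene])

    def gene_values(self, gene: str) -> pd.DataFrame:
        """Rows of ``values`` belonging to one gene (file order preserved)."""
        return self.values.loc[self.isoforms_of(gene)]

    def subset_samples(self, sample_ids) -> "IsoformCountMatrix":
        return IsoformCountMatrix(self.values[list(sample_ids)], self.gene_of)


def read_isoform_counts(path) -> IsoformCountMatrix:
    """Read a ``counts.tsv`` file into an :class:`IsoformCountMatrix`.

    Raises ``ValueError`` naming the offending row/column for duplicate
    isoform ids, negative or non-numeric values, and isoforms listed under
    two genes.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["isoform_id", "gene_id"]:
        raise ValueError(
            "counts file must start with columns 'isoform_id', 'gene_id'"
        )
    dup = df["isoform_id"][df["isoform_id"].duplicated()]
    if len(dup) > 0:
        raise ValueError(f"duplicate isoform id: {dup.iloc[0]!r}")
    values = df.set_index("isoform_id").drop(columns="gene_id")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = values.index[numeric.isna()]
        if len(bad) > 0:
            raise ValueError(
                f"non-numeric value at isoform {bad[0]!r}, sample {col!r}"
            )
        neg = values.index[numeric < 0]
        if len(neg) > 0:
            raise ValueError(
                f"negative abundance at isoform {neg[0]!r}, sample {col!r}"
            )
        values[col] = numeric.astype(float)
    gene_of = df.set_index("isoform_id")["gene_id"]
    return IsoformCountMatrix(values, gene_of)


def write_isoform_counts(matrix: IsoformCountMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_id", matrix.gene_of)
    out.index.name = "isoform_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read ``metadata.tsv``; returns a frame indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata file must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    df = df.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad_type = df["sample_type"][~df["sample_type"].isin(SAMPLE_TYPES)]
    if len(bad_type) > 0:
        raise ValueError(
            f"sample {bad_type.index[0]!r} has sample_type "
            f"{bad_type.iloc[0]!r}; expected one of {SAMPLE_TYPES}"
        )
    for col in ("purity", "bias_score"):
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.dropna()
        if ((present < 0) | (present > 1)).any():
            raise ValueError(f"{col} values must lie in [0, 1]")
        df[col] = vals
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_kinome_annotation(path) -> pd.Series:
    """Read ``annotation.tsv`` (gene_id, kinase_group) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "kinase_group"]:
        raise ValueError(
            "annotation file must have columns 'gene_id', 'kinase_group'"
        )
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} annotated more than once")
    bad = df["kinase_group"][~df["kinase_group"].isin(KINASE_GROUPS)]
    if len(bad) > 0:
        raise ValueError(f"unknown kinase group {bad.iloc[0]!r}")
    return df.set_index("gene_id")["kinase_group"]


def write_kinome_annotation(groups: pd.Series, path) -> None:
    out = groups.rename("kinase_group").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into ``{set name: member genes}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
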