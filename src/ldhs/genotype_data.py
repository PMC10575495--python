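"""Containers and readers/writers for case-control genotype matrices and SNP annotations.

Genotypes are biallelic SNP codes: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous variant. Each sample carries a binary phenotype label
(1 = case, 0 = control). The on-disk dialect mirrors GAMETES output:
tab-separated, one header row of SNP names followed by a ``Class`` column,
one sample per row.

Annotations map SNP identifiers to a genomic region (gene or similar) and a
functional category; they stand in for what one would retrieve from dbSNP.
Coordinates are 1-based. SNPs absent from an annotation table are treated as
intergenic by downstream grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

logger = logging.getLogger(__name__)

#: Closed vocabulary of functional categories.
CATEGORIES = frozenset(
    {"coding", "promoter", "upstream", "downstream", "intron", "intergenic"}
)

_VALID_GENOTYPES = frozenset({0, 1, 2})


@dataclass(eq=False)
class GenotypeDataset:
    """A samples x SNPs genotype matrix with case/control labels.

    Parameters
    ----------
    snp_ids
        Unique SNP identifiers, one per column.
    genotypes
        ``(n_samples, m)`` integer array with entries in {0, 1, 2}.
    labels
        ``(n_samples,)`` integer array, 1 = case, 0 = control.
    """

    snp_ids: list[str]
    genotypes: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        n, m = self.genotypes.shape
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {m} genotype columns")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of samples")
        if n and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be in {0 (control), 1 (case)}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return self.genotypes.shape[1]

    @property
    def n_case(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return int(self.n_samples - self.labels.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and self.genotypes.shape == other.genotypes.shape
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class AnnotationTable:
    """SNP annotation records: (snp_id, chrom, pos, region_id, category).

    ``region_id`` is the gene/region label used for locus grouping; ``None``
    marks SNPs with no region (e.g. intergenic). ``category`` is drawn from
    :data:`CATEGORIES`.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "region_id", "category"]
        )
    )

    def __post_init__(self) -> None:
        df = self.records
        required = ["snp_id", "chrom", "pos", "region_id", "category"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing columns: {missing}")
        self.records = df = df[required].reset_index(drop=True)
        if len(df) == 0:
            return
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise FormatError(f"duplicate snp_id in annotation table: {dups[:5]}")
        bad = set(df["category"]) - CATEGORIES
        if bad:
            raise FormatError(f"unknown annotation categories: {sorted(bad)}")
        if (df["pos"].astype(int) < 1).any():
            raise FormatError("annotation positions must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self) -> dict[str, tuple[str | None, str]]:
        """Map snp_id -> (region_id, category); first row wins on duplicates."""
        out: dict[str, tuple[str | None, str]] = {}
        for row in self.records.itertuples(index=False):
            if row.snp_id in out:  # pragma: no cover - construction forbids it
                logger.warning("ignoring duplicate annotation for %s", row.snp_id)
                continue
            region = None if pd.isna(row.region_id) or row.region_id == "" else str(row.region_id)
            out[str(row.snp_id)] = (region, str(row.category))
        return out


def read_genotypes(
    path,
    dialect: str = "gametes_tsv",
    class_column: str = "Class",
    class_map: dict | None = None,
) -> GenotypeDataset:
    """Read a genotype matrix from a GAMETES-style TSV (or generic CSV).

    The final column (named ``class_column``, default ``Class``) holds the
    phenotype, coded 1 = case / 0 = control unless ``class_map`` overrides it.
    """
    if dialect not in ("gametes_tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "gametes_tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty genotype file") from None
    if class_column not in df.columns:
        raise FormatError(
            f"{path}: missing class column {class_column!r} (columns: {list(df.columns)[:6]}...)"
        )
    snp_ids = [c for c in df.columns if c != class_column]
    if not snp_ids:
        raise FormatError(f"{path}: no SNP columns")

    geno = np.empty((len(df), len(snp_ids)), dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        col = pd.to_numeric(df[snp], errors="coerce")
        bad = col.isna() | ~col.isin([0, 1, 2])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: invalid genotype {df[snp].iloc[row]!r} at sample row "
                f"{row + 1}, SNP column {snp!r} (expected 0/1/2)"
            )
        geno[:, j] = col.to_numpy(dtype=np.int8)

    mapping = {"1": 1, "0": 0} if class_map is None else {str(k): v for k, v in class_map.items()}
    labels = np.empty(len(df), dtype=np.int8)
    for i, raw in enumerate(df[class_column].astype(str)):
        key = raw.strip()
        # accept "1.0"-style floats written by other tools
        if key not in mapping and key.endswith(".0"):
            key = key[:-2]
        if key not in mapping:
            raise ParseError(
                f"{path}: invalid class value {raw!r} at sample row {i + 1}"
            )
        labels[i] = mapping[key]
    return GenotypeDataset(snp_ids=snp_ids, genotypes=geno, labels=labels)


def write_genotypes(dataset: GenotypeDataset, path, class_column: str = "Class") -> None:
    """Write ``dataset`` as a GAMETES-style TSV; round-trips with :func:`read_genotypes`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([*dataset.snp_ids, class_column]) + "\n")
        for i in range(dataset.n_samples):
            row = dataset.genotypes[i]
            fh.write("\t".join(str(int(v)) for v in row))
            fh.write(f"\t{int(dataset.labels[i])}\n")


def read_annotations(path) -> AnnotationTable:
    """Read a 5-column SNP annotation TSV (snp_id, chrom, pos, region_id, category)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"snp_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty annotation file (header required)") from None
    required = ["snp_id", "chrom", "pos", "region_id", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    return AnnotationTable(records=df[required])


def write_annotations(table: AnnotationTable, path) -> None:
    """Write an annotation table as TSV; round-trips with :func:`read_annotations`."""
    df = table.records.copy()
    df.to_csv(path, sep="\t", index=False)
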