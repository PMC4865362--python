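"""Readers and writers for the formats the pipeline consumes.

All coordinates are 0-based half-open internally: BED is native, GFF3 start
positions are decremented on read. Per-cytosine TAB-seq calls travel in an
allc-style 6-column TSV: ``chrom  pos  strand  context  protected  total``,
where *protected* is the number of reads reporting C at the site (the 5hmC
signal in TAB-seq) and *total* the number of reads covering it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "protected", "total"]
CONTEXTS = ("CG", "CHG", "CHH")
SOURCE_KINDS = ("genome", "lambda_5mC", "pUC19_5hmC")


@dataclass
class CallTable:
    """Per-cytosine TAB-seq calls for one sample, sorted by (chrom, pos, strand).

    Parameters
    ----------
    sample_id
        Label for the sequenced nuclear fraction (e.g. ``PPARg2-High``).
    source_kind
        ``genome`` for the nuclear DNA, ``lambda_5mC`` for the fully
        methylated lambda spike-in, ``pUC19_5hmC`` for the fully
        hydroxymethylated pUC19 spike-in.
    calls
        DataFrame with columns ``chrom, pos, strand, context, protected, total``.
    """

    sample_id: str
    source_kind: str
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise ValidationError(
                f"unknown source_kind {self.source_kind!r}; expected one of {SOURCE_KINDS}"
            )
        self.calls = _validate_calls(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.source_kind == other.source_kind
            and self.calls.reset_index(drop=True).equals(other.calls.reset_index(drop=True))
        )

    def subset_context(self, *contexts: str) -> pd.DataFrame:
        """Rows whose context is in *contexts* (e.g. ``table.subset_context("CG")``)."""
        return self.calls[self.calls["context"].isin(contexts)]


def _validate_calls(df: pd.DataFrame, line_offset: int = 0) -> pd.DataFrame:
    """Validate, sort and type-normalise a raw call frame.

    ``line_offset`` maps frame rows back to 1-based file line numbers in
    error messages (0 when the frame was built in memory).
    """
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table is missing columns: {missing}")
    df = df[CALL_COLUMNS].copy()
    for col in ("pos", "protected", "total"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-integer values in column {col!r}: {exc}") from exc
    df["chrom"] = df["chrom"].astype(str)
    df["strand"] = df["strand"].astype(str)
    df["context"] = df["context"].astype(str)

    def _lines(mask: pd.Series) -> list[int]:
        return [int(i) + line_offset + 1 for i in df.index[mask][:10]]

    bad = df["pos"] < 0
    if bad.any():
        raise ValidationError(f"negative positions at lines {_lines(bad)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(f"strand must be '+' or '-' at lines {_lines(bad)}")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValidationError(f"context must be one of {CONTEXTS} at lines {_lines(bad)}")
    bad = (df["protected"] < 0) | (df["total"] < 0)
    if bad.any():
        raise ValidationError(f"negative counts at lines {_lines(bad)}")
    bad = df["protected"] > df["total"]
    if bad.any():
        raise ValidationError(f"protected > total at lines {_lines(bad)}")

    dup = df.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate (chrom, pos, strand) records at lines {_lines(dup)}; "
            "duplicates are an error, never merged"
        )
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return df


def read_calls(
    path, source_kind: str, sample_id: str | None = None, has_header: bool = True
) -> CallTable:
    """Read an allc-style call TSV into a validated, sorted :class:`CallTable`.

    With ``has_header=False`` the six columns are assumed to be in canonical
    order. Rows violating invariants are reported with their file line
    numbers.
    """
    try:
        if has_header:
            df = pd.read_csv(path, sep="\t", dtype=str)
        else:
            df = pd.read_csv(path, sep="\t", header=None, names=CALL_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CALL_COLUMNS)
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    offset = 1 if has_header else 0
    if sample_id is None:
        sample_id = str(path)
    table = CallTable.__new__(CallTable)
    table.sample_id = sample_id
    table.source_kind = source_kind
    if source_kind not in SOURCE_KINDS:
        raise ValidationError(
            f"unknown source_kind {source_kind!r}; expected one of {SOURCE_KINDS}"
        )
    table.calls = _validate_calls(df, line_offset=offset)
    return table


def write_calls(table: CallTable, path) -> str:
    """Write a :class:`CallTable` to TSV (header always included); returns *path*."""
    table.calls.to_csv(path, sep="\t", index=False)
    return str(path)


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open span, strand, and total exonic length.

    TSS and TTS are strand-derived: for ``+`` genes the TSS is ``start``;
    for ``-`` genes it is ``end - 1`` (the last base of the span).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exonic_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.exonic_length < 1:
            raise ValidationError(f"gene {self.gene_id}: exonic_length must be >= 1")
        if self.exonic_length > self.end - self.start:
            raise ValidationError(
                f"gene {self.gene_id}: exonic_length {self.exonic_length} exceeds "
                f"gene span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _genes_from_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise FormatError(f"{path}: BED12 requires 12 columns, found {df.shape[1]}")
    genes = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        gene_id, strand = row[3], row[5]
        sizes = [int(s) for s in str(row[10]).rstrip(",").split(",")]
        starts = [int(s) for s in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != len(starts) or len(sizes) != int(row[9]):
            raise FormatError(f"{path} line {line_no}: blockCount/blockSizes/blockStarts disagree")
        blocks = sorted(zip(starts, sizes))
        for (s1, z1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + z1 > s2:
                raise ValidationError(
                    f"{path} line {line_no}: overlapping exon blocks in gene {gene_id}"
                )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exonic_length=sum(sizes),
            )
        )
    return genes


def _genes_from_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(feat, featuretype="exon")),
        )
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValidationError(f"gene {feat.id}: overlapping exons in GFF3")
        # genes annotated without exon children span their full length
        exonic = sum(e - s for s, e in exons) if exons else feat.end - (feat.start - 1)
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                exonic_length=exonic,
            )
        )
    return genes


def read_gene_models(path, fmt: str = "bed12") -> list[GeneModel]:
    """Parse gene models from BED12 or GFF3 into 0-based half-open coordinates."""
    fmt = fmt.lower()
    if fmt == "bed12":
        return _genes_from_bed12(path)
    if fmt == "gff3":
        return _genes_from_gff3(path)
    raise FormatError(f"unknown annotation format {fmt!r}; expected 'bed12' or 'gff3'")


def read_expression(path) -> pd.DataFrame:
    """Read a gene-expression TSV (gene_id column + >=1 numeric sample column).

    Returns a DataFrame indexed by gene_id. Negative values and duplicate
    gene ids are errors; genes with missing values are kept (as NaN) and
    counted in a log message.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: expression table needs a 'gene_id' column")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression table needs at least one sample column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene_id values: {sorted(set(dup))[:10]}")
    df = df.set_index("gene_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc
    if (df < 0).any().any():
        bad = df.index[(df < 0).any(axis=1)]
        raise ValidationError(f"negative expression for genes: {list(bad[:10])}")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d genes have missing expression values", n_missing)
    return df


def write_gene_models_bed12(genes: list[GeneModel], path, blocks=None) -> str:
    """Write gene models as BED12. ``blocks`` optionally maps gene_id to a
    list of (relative_start, size) exon blocks; absent that, one block spans
    the gene (exonic_length then equals the gene length on re-read)."""
    with open(path, "w") as fh:
        for g in genes:
            if blocks and g.gene_id in blocks:
                blk = sorted(blocks[g.gene_id])
            else:
                blk = [(0, g.length)]
            sizes = ",".join(str(z) for _, z in blk)
            starts = ",".join(str(s) for s, _ in blk)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(blk)}\t{sizes}\t{starts}\n"
            )
    return str(path)
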