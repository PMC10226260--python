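"""Readers and writers for the text formats the pipeline exchanges.

All genomic coordinates are held internally as 0-based half-open intervals.
BED input is native to that convention; GFF3 (1-based inclusive) is converted
at the boundary. Readers validate rather than coerce: malformed records raise
:class:`FormatError` with enough context to locate the offending line.

Formats covered: BED / GFF3 / TSV gene annotation, SEG-like per-sample
copy-number bin tables, rectangular expression matrices, GMT gene sets,
sample metadata with survival columns, and FASTA (via Biopython).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}

EXPRESSION_SCALES = ("log2TPM", "FPKM", "TMM", "log2FPKM")

#: scales whose values are already log-transformed
LOG_SCALES = frozenset({"log2TPM", "log2FPKM"})


class FormatError(ValueError):
    """A file failed validation under the declared dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene records with 0-based half-open coordinates and arm assignment.

    ``df`` columns: gene_id, symbol, chromosome, start, end, strand,
    biotype, arm (one of ``p``, ``q``, ``unknown``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "symbol", "chromosome", "start", "end",
                    "strand", "biotype", "arm"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicated gene_id: {dup!r}")
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            row = self.df[bad].iloc[0]
            raise FormatError(
                f"gene {row.gene_id!r}: end ({row.end}) <= start ({row.start})")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, *, biotype: str | None = None,
               chromosomes: Iterable[str] | None = None) -> "GeneAnnotation":
        df = self.df
        if biotype is not None:
            df = df[df["biotype"] == biotype]
        if chromosomes is not None:
            df = df[df["chromosome"].isin(set(chromosomes))]
        return GeneAnnotation(df.reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise FormatError(
                f"unknown expression scale {self.scale!r}; "
                f"expected one of {EXPRESSION_SCALES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicated sample id: {dup!r}")
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing cells")

    @property
    def is_log_scale(self) -> bool:
        return self.scale in LOG_SCALES

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class CohortMeta:
    """Per-sample clinical metadata with overall-survival columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "os_time", "os_event"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if (self.df["os_time"] < 0).any():
            raise FormatError("negative survival time")
        if not self.df["os_event"].isin([0, 1]).all():
            raise FormatError("os_event must be 0 (censored) or 1 (event)")
        if self.df["sample_id"].duplicated().any():
            raise FormatError("duplicated sample_id in metadata")
        self.df = self.df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def assign_arm(start: int, chromosome: str,
               centromeres: Mapping[str, int] | None) -> str:
    """Chromosome arm from the gene start and a centromere position table."""
    if centromeres is None:
        return "unknown"
    if chromosome not in centromeres:
        logger.warning("no centromere position for %s; arm set to unknown",
                       chromosome)
        return "unknown"
    return "p" if start < centromeres[chromosome] else "q"


def read_gene_annotation(path: str | Path, format: str = "BED",
                         centromeres: Mapping[str, int] | None = None
                         ) -> GeneAnnotation:
    """Read gene records from BED, GFF3 or a column-named TSV.

    BED is taken as 0-based half-open; GFF3 coordinates (1-based inclusive)
    are converted on input. ``centromeres`` maps chromosome name to the
    centromere position (bp); when given, each gene is assigned to the p or
    q arm by its start coordinate.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "BED":
        records = _read_bed(path)
    elif fmt == "GFF3":
        records = _read_gff3(path)
    elif fmt == "TSV":
        records = _read_annotation_tsv(path)
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    df = pd.DataFrame.from_records(
        records, columns=["gene_id", "symbol", "chromosome", "start", "end",
                          "strand", "biotype"])
    df["arm"] = [assign_arm(s, c, centromeres)
                 for s, c in zip(df["start"], df["chromosome"])]
    return GeneAnnotation(df)


def _read_bed(path: Path) -> list[tuple]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED line has "
                                  f"{len(fields)} fields, need >= 4")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            # BED has no biotype column; optional 7th field used when present
            biotype = fields[6] if len(fields) > 6 else "protein_coding"
            records.append((name, name, chrom, start, end, strand, biotype))
    return records


def _read_gff3(path: Path) -> list[tuple]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has "
                                  f"{len(fields)} fields, need 9")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            start, end = int(start1) - 1, int(end1)  # 1-based incl -> 0-based half-open
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks ID")
            symbol = attr.get("Name", gene_id)
            biotype = attr.get("biotype", attr.get("gene_biotype", "protein_coding"))
            if strand not in VALID_STRANDS:
                strand = "."
            records.append((gene_id, symbol, chrom, start, end, strand, biotype))
    return records


def _read_annotation_tsv(path: Path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = ["gene_id", "chromosome", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation TSV missing columns {missing}")
    if "symbol" not in df.columns:
        df["symbol"] = df["gene_id"]
    if "strand" not in df.columns:
        df["strand"] = "."
    if "biotype" not in df.columns:
        df["biotype"] = "protein_coding"
    return list(df[["gene_id", "symbol", "chromosome", "start", "end",
                    "strand", "biotype"]].itertuples(index=False, name=None))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write annotation as a TSV (the dialect ``read_gene_annotation`` reads)."""
    annotation.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number bins (SEG-like TSV)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end"]


def read_cn_bins(path: str | Path):
    """Read a SEG-like TSV into one :class:`~neuro17q.copy_number.CNProfile`
    per sample.

    Required columns: sample, chrom, start, end and at least one of
    log2_ratio / cn. When only integer copy number is present the log2 ratio
    is derived as log2(cn/2) relative to the diploid state.
    """
    from .copy_number import CNProfile  # deferred: avoids import cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_log2 = "log2_ratio" in df.columns
    has_cn = "cn" in df.columns
    if not (has_log2 or has_cn):
        raise FormatError(f"{path}: need a log2_ratio and/or cn column")
    if not has_log2:
        if (df["cn"] <= 0).any():
            raise FormatError(f"{path}: non-positive cn values cannot be "
                              "converted to log2 ratios")
        df["log2_ratio"] = np.log2(df["cn"] / 2.0)
    if not has_cn:
        df["cn"] = np.nan
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        grp = grp.sort_values(["chrom", "start"], kind="stable")
        bins = grp[["chrom", "start", "end", "log2_ratio", "cn"]].rename(
            columns={"chrom": "chromosome"}).reset_index(drop=True)
        profiles.append(CNProfile(sample_id=str(sample), bins=bins))
    return profiles


def write_cn_bins(profiles, path: str | Path) -> None:
    """Write CNProfiles back to the SEG-like TSV dialect."""
    frames = []
    for p in profiles:
        df = p.bins.rename(columns={"chromosome": "chrom"}).copy()
        df.insert(0, "sample", p.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a rectangular genes-x-samples TSV (first column gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for rowno, line in enumerate(fh, 2):
            n = line.rstrip("\n").count("\t") + 1
            if n != width:
                raise FormatError(
                    f"{path}: row {rowno} has {n} fields, header has {width}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(values=df, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered mapping set name -> gene list.

    Duplicate genes within a set are dropped (first occurrence kept, warning
    logged); duplicate set names are an error; empty sets are allowed with a
    warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 2 tab-separated "
                    "fields (name, description, genes...)")
            name, genes = fields[0], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < sum(1 for g in genes if g):
                logger.warning("%s:%d: duplicate genes in set %s deduplicated",
                               path, lineno, name)
            if not deduped:
                logger.warning("%s:%d: empty gene set %s", path, lineno, name)
            sets[name] = deduped
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------


def read_cohort_meta(path: str | Path) -> CohortMeta:
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample_id": str, "inss_stage": str})
    return CohortMeta(df)


def write_cohort_meta(meta: CohortMeta, path: str | Path) -> None:
    meta.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequence name -> uppercase nucleotide string."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
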