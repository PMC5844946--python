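"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* FASTQ (4-line records) for small-RNA reads; sequences are uppercased and
  U is mapped to T on ingest.
* FASTA for the mature-miRNA reference (via Biopython).
* TSV count matrices (features in rows, samples in columns) with a two-column
  sample->group sidecar.
* TSV editing-site pileup tables: one row per site with annotation columns
  followed by per-sample ``edited_<s>`` / ``total_<s>`` count pairs.
* Long-format TSV Ct tables (sample, group, gene, replicate, ct).
* BED (0-based, half-open) site lists; internal coordinates are 1-based
  inclusive, conversion happens only at this boundary.

Missing values are written as ``.`` in TSV output. All validation errors name
the offending row or line.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_TO_DNA = str.maketrans("Uu", "Tt")

SITE_CLASSES = ("alu", "recoding")

#: annotation columns of a site pileup table, in file order
SITE_ANNOTATION_COLUMNS = ["chrom", "pos", "strand", "site_class", "gene", "aa_change"]


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class SmallRNARead:
    """A single small-RNA sequencing read.

    ``sequence`` is over {A,C,G,T,N}; ``qualities`` (per-base Phred scores)
    may be absent, e.g. for FASTA-derived input.
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class FastqParseError(ValueError):
    pass


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream reads from a 4-line-record FASTQ file.

    Sequences are uppercased with U->T. Malformed records (missing '@',
    length mismatch, truncation) raise :class:`FastqParseError` naming the
    line number. This parser is deliberately strict and line-aware; it does
    not support wrapped FASTQ.
    """
    n = 0
    with open(path) as fh:
        while True:
            lineno = 4 * n + 1
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}:{lineno + 2}: expected '+' separator (truncated record?)")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SmallRNARead(
                read_id=header[1:].split()[0],
                sequence=seq.upper().translate(_RNA_TO_DNA),
                qualities=tuple(ord(c) - 33 for c in qual),
            )
            n += 1
    logger.info("read_fastq: %d records from %s", n, path)


def write_fastq(reads: Sequence[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else (40,) * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{''.join(chr(q + 33) for q in quals)}\n")


def read_fasta_reference(path: str | Path) -> dict[str, str]:
    """Load a mature-miRNA reference as ``{name: sequence}``.

    Names are the first whitespace token of the header and must be unique;
    sequences are uppercased with U->T; empty sequences are rejected.
    """
    reference: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        seq = str(record.seq).upper().translate(_RNA_TO_DNA)
        if name in reference:
            raise ValueError(f"duplicate reference name {name!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for {name!r} in {path}")
        reference[name] = seq
    return reference


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n{seq}\n")


def longest_homopolymer_run(sequence: str) -> int:
    """Length of the longest single-base run in ``sequence``."""
    return max((sum(1 for _ in grp) for _, grp in itertools.groupby(sequence)), default=0)


def qc_filter_read(
    read: SmallRNARead,
    min_q: float = 20.0,
    min_len: int = 50,
    max_homopolymer_frac: float = 0.5,
) -> tuple[bool, list[str]]:
    """Long-read QC: keep iff mean Phred > min_q, length > min_len, and the
    longest homopolymer run is < max_homopolymer_frac of the read length.

    Returns ``(keep, reasons)`` where ``reasons`` lists every failed
    criterion. Reads without quality scores skip the quality criterion (a
    warning is logged) so FASTA-only inputs remain usable.
    """
    reasons: list[str] = []
    if read.qualities is None:
        logger.warning("qc_filter_read: %s has no qualities; quality criterion skipped", read.read_id)
    elif float(np.mean(read.qualities)) <= min_q:
        reasons.append("low_quality")
    if len(read) <= min_len:
        reasons.append("short")
    if longest_homopolymer_run(read.sequence) / len(read) >= max_homopolymer_frac:
        reasons.append("homopolymer")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# count matrices and group labels


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "feature"
    numeric = matrix.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = matrix.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: non-numeric count in row {bad!r}")
    if (numeric < 0).any().any():
        bad = numeric.index[(numeric < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count in row {bad!r}")
    return numeric


def write_groups(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").rename_axis("sample").to_csv(path, sep="\t")


def read_groups(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].rename("group")


# ---------------------------------------------------------------------------
# editing-site records and pileup tables


@dataclass(frozen=True)
class SiteRecord:
    """An annotated A-to-I editing site (1-based inclusive coordinate)."""

    chrom: str
    pos: int
    strand: str
    site_class: str
    gene: str | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site {self.chrom}:{self.pos}: pos must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.chrom}:{self.pos}: unknown strand {self.strand!r}")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"site {self.chrom}:{self.pos}: unknown class {self.site_class!r}")
        if self.site_class == "recoding" and (self.gene is None or self.aa_change is None):
            raise ValueError(f"recoding site {self.chrom}:{self.pos} requires gene and aa_change")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def write_site_table(
    sites: pd.DataFrame,
    edited: pd.DataFrame,
    total: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write a pileup table: annotation columns then edited_<s>/total_<s> pairs."""
    out = sites[SITE_ANNOTATION_COLUMNS].copy()
    for s in edited.columns:
        out[f"edited_{s}"] = edited[s].astype(int).values
        out[f"total_{s}"] = total[s].astype(int).values
    out = out.fillna(".")
    out.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a pileup table; returns (sites, edited, total).

    ``sites`` is indexed by "chrom:pos" site ids; ``edited``/``total`` are
    integer site x sample frames on the same index. Rows with edited > total,
    negative counts, or an unknown strand are rejected with the row named.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_ANNOTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites = raw[SITE_ANNOTATION_COLUMNS].replace(".", None).copy()
    sites["pos"] = sites["pos"].astype(int)
    site_ids = sites["chrom"] + ":" + sites["pos"].astype(str)
    sites.index = pd.Index(site_ids, name="site_id")

    samples = [c[len("edited_"):] for c in raw.columns if c.startswith("edited_")]
    edited = pd.DataFrame(index=sites.index)
    total = pd.DataFrame(index=sites.index)
    for s in samples:
        edited[s] = raw[f"edited_{s}"].astype(int).values
        total[s] = raw[f"total_{s}"].astype(int).values

    for i, sid in enumerate(sites.index):
        # validate through the SiteRecord invariants
        row = sites.iloc[i]
        SiteRecord(
            chrom=row["chrom"], pos=int(row["pos"]), strand=row["strand"],
            site_class=row["site_class"], gene=row["gene"], aa_change=row["aa_change"],
        )
    if (edited.values < 0).any() or (total.values < 0).any():
        bad = edited.index[((edited < 0) | (total < 0)).any(axis=1)][0]
        raise ValueError(f"{path}: negative count at site {bad}")
    over = (edited.values > total.values)
    if over.any():
        bad = edited.index[over.any(axis=1)][0]
        raise ValueError(f"{path}: edited > total at site {bad}")
    return sites, edited, total


# ---------------------------------------------------------------------------
# Ct tables

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct[CT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct table (sample, group, gene, replicate, ct)."""
    ct = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ct["ct"] = ct["ct"].astype(float)
    if (ct["ct"] <= 0).any():
        bad = ct.index[ct["ct"] <= 0][0]
        raise ValueError(f"{path}: nonpositive Ct at row {bad}")
    return ct[CT_COLUMNS]


# ---------------------------------------------------------------------------
# BED

@dataclass
class BedInterval:
    """One BED line (0-based half-open on disk, 1-based inclusive in memory)."""

    chrom: str
    pos_start: int  # 1-based inclusive
    pos_end: int    # 1-based inclusive
    extra: tuple[str, ...] = field(default_factory=tuple)


def read_bed(path: str | Path) -> list[BedInterval]:
    """Ingest a BED file, converting to 1-based inclusive coordinates.

    ``chr4 158257874 158257875`` becomes pos_start == pos_end == 158257875.
    Extra columns (name, score, strand, ...) are preserved verbatim so that
    :func:`write_bed` round-trips byte-for-byte.
    """
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append(
                BedInterval(chrom=parts[0], pos_start=start + 1, pos_end=end, extra=tuple(parts[3:]))
            )
    return intervals


def write_bed(intervals: Sequence[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.pos_start - 1), str(iv.pos_end), *iv.extra]
            fh.write("\t".join(fields) + "\n")


def bed_to_site_records(
    intervals: Sequence[BedInterval],
    site_class: str,
    strand_column: int = 2,
) -> list[SiteRecord]:
    """Interpret single-base BED intervals as editing sites.

    ``strand_column`` indexes into the extra columns (default BED6 layout:
    name, score, strand). Intervals without a strand default to '+'.
    """
    records = []
    for iv in intervals:
        if iv.pos_start != iv.pos_end:
            raise ValueError(f"site interval {iv.chrom}:{iv.pos_start}-{iv.pos_end} is not single-base")
        strand = iv.extra[strand_column] if len(iv.extra) > strand_column else "+"
        gene = iv.extra[0] if iv.extra else None
        records.append(
            SiteRecord(chrom=iv.chrom, pos=iv.pos_start, strand=strand,
                       site_class=site_class, gene=gene,
                       aa_change=None if site_class == "alu" else "?/?")
        )
    return records
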