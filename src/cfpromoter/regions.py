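"""Promoter (pTSS) window construction and blacklist filtering.

A pTSS region is the 2-kb window spanning -1 kb to +1 kb around a
transcript's transcription start site, oriented by strand.  All
coordinates are 0-based half-open (UCSC refFlat/BED convention): the TSS
of a + strand transcript is ``txStart``; for a - strand transcript it is
``txEnd - 1``, so the window is ``[tss - flank, tss + flank)`` in both
cases and every emitted region has length exactly ``2 * flank``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger("cfpromoter")

DEFAULT_FLANK = 1000


@dataclass(frozen=True)
class PTSSRegion:
    """A strand-oriented promoter window around one transcript's TSS."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    transcript_id: str
    gene_symbol: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotation row: gene symbol, transcript id, chrom, strand, tx span."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int  # 0-based inclusive
    tx_end: int    # 0-based exclusive


def read_refflat(path) -> list[TranscriptRecord]:
    """Parse a refFlat-style tab table.

    Expected leading columns: geneName, name, chrom, strand, txStart,
    txEnd (any further columns such as cdsStart/exon blocks are ignored).
    Lines starting with '#' are skipped.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 tab fields, got {len(parts)}")
            records.append(TranscriptRecord(
                gene_symbol=parts[0], transcript_id=parts[1], chrom=parts[2],
                strand=parts[3], tx_start=int(parts[4]), tx_end=int(parts[5]),
            ))
    return records


def read_bed12(path) -> list[TranscriptRecord]:
    """Parse BED12 (or BED6) into transcript records; name doubles as both ids."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED needs >=6 fields for strand, got {len(parts)}")
            records.append(TranscriptRecord(
                gene_symbol=parts[3], transcript_id=parts[3], chrom=parts[0],
                strand=parts[5], tx_start=int(parts[1]), tx_end=int(parts[2]),
            ))
    return records


def build_ptss(annotation: Iterable[TranscriptRecord], flank: int = DEFAULT_FLANK) -> list[PTSSRegion]:
    """Build one pTSS window per transcript.

    TSS = txStart on + strand, txEnd - 1 on - strand; window =
    [tss - flank, tss + flank).  Windows that would extend below
    coordinate 0 are dropped.  Records with an unknown strand symbol are
    rejected with a logged warning.  Duplicate windows (same
    chrom/start/end/strand) are collapsed to one region whose ids are the
    comma-joined ids of the members.

    Parameters
    ----------
    annotation : iterable of TranscriptRecord
    flank : upstream/downstream extent in bp (default 1000, i.e. a 2-kb window)
    """
    by_key: dict[tuple, list[TranscriptRecord]] = {}
    order: list[tuple] = []
    for rec in annotation:
        if rec.strand not in ("+", "-"):
            logger.warning("rejecting %s: unknown strand %r", rec.transcript_id, rec.strand)
            continue
        tss = rec.tx_start if rec.strand == "+" else rec.tx_end - 1
        start, end = tss - flank, tss + flank
        if start < 0:
            continue
        key = (rec.chrom, start, end, rec.strand)
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(rec)

    out = []
    for key in order:
        chrom, start, end, strand = key
        members = by_key[key]
        out.append(PTSSRegion(
            chrom=chrom, start=start, end=end, strand=strand,
            transcript_id=",".join(m.transcript_id for m in members),
            gene_symbol=",".join(dict.fromkeys(m.gene_symbol for m in members)),
            tss=start + flank,
        ))
    return out


def read_bed3(path) -> list[tuple[str, int, int]]:
    """Parse a BED3+ file into (chrom, start, end) tuples.

    Malformed lines raise a parse error naming the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has {len(parts)} fields, need >=3")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            intervals.append((parts[0], start, end))
    return intervals


def filter_blacklist(regions: Sequence[PTSSRegion],
                     blacklist: Iterable[tuple[str, int, int]]) -> list[PTSSRegion]:
    """Remove every region sharing >=1 bp with any blacklist interval.

    Intervals are 0-based half-open, so a blacklist interval that merely
    touches a region end-to-start does not remove it.  Input order is
    preserved.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in blacklist:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return [r for r in regions
            if r.chrom not in trees or not trees[r.chrom].overlap(r.start, r.end)]


def write_bed6(regions: Sequence[PTSSRegion], path) -> None:
    """Write regions as BED6 with name=transcript_id, score=0."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\t0\t{r.strand}\n")


def regions_to_annotation(regions: Sequence[PTSSRegion]) -> list[TranscriptRecord]:
    """Re-express pTSS regions as annotation rows (the TSS as a 1-bp tx).

    Useful for round-trip checks: ``build_ptss`` applied to this output
    reproduces the regions.
    """
    out = []
    for r in regions:
        # a 1-bp transcript at the TSS has txStart = tss and txEnd - 1 = tss,
        # so the convention maps it back to the same TSS on either strand
        tx_start, tx_end = r.tss, r.tss + 1
        out.append(TranscriptRecord(
            gene_symbol=r.gene_symbol, transcript_id=r.transcript_id,
            chrom=r.chrom, strand=r.strand, tx_start=tx_start, tx_end=tx_end,
        ))
    return out
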