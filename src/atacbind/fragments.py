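"""Paired-end ATAC-seq fragment ingestion, Tn5 offsetting and size partitioning.

A sequenced fragment is modelled as a genomic interval whose two termini are
the Tn5 cut sites: the left cut at ``start`` and the right cut at ``end - 1``
(intervals are 0-based, half-open throughout).  Fragments are split into two
size classes at one nucleosome length ("short": size <= nucleosome_bp,
"long": size > nucleosome_bp).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "FragmentRecord",
    "SizePartitionConfig",
    "ReadFilterStats",
    "read_fragments",
    "size_class",
    "downsample_fragments",
    "FragmentParseError",
]

SHORT = "short"
LONG = "long"


class FragmentParseError(ValueError):
    """Raised for malformed fragment interval lines; carries the line number."""

    def __init__(self, path: str, lineno: int, line: str):
        self.path = path
        self.lineno = lineno
        self.line = line
        super().__init__(f"{path}: malformed fragment line {lineno}: {line!r}")


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment contributing two Tn5 cut events."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def left_cut(self) -> int:
        """Forward-strand Tn5 cut position."""
        return self.start

    @property
    def right_cut(self) -> int:
        """Reverse-strand Tn5 cut position (last base inside the interval)."""
        return self.end - 1


@dataclass(frozen=True)
class SizePartitionConfig:
    """Tn5 shift offsets and the one-nucleosome size cutoff.

    ``nucleosome_bp`` defaults to 147 (canonical nucleosomal DNA length);
    shifts default to the standard ATAC-seq +4/-5 convention.
    """

    nucleosome_bp: int = 147
    shift_forward: int = 4
    shift_reverse: int = -5

    def __post_init__(self):
        if self.nucleosome_bp <= 0:
            raise ValueError("nucleosome_bp must be positive")


@dataclass
class ReadFilterStats:
    """Counters for records skipped while reading an alignment file."""

    emitted: int = 0
    skipped_unpaired: int = 0
    skipped_secondary: int = 0
    skipped_duplicate: int = 0
    skipped_low_mapq: int = 0
    skipped_other: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_unpaired
            + self.skipped_secondary
            + self.skipped_duplicate
            + self.skipped_low_mapq
            + self.skipped_other
        )


def _iter_bed_fragments(path: str) -> Iterator[FragmentRecord]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FragmentParseError(path, lineno, line)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FragmentParseError(path, lineno, line) from None
            if end <= start:
                raise FragmentParseError(path, lineno, line)
            yield FragmentRecord(fields[0], start, end)


def _iter_bam_fragments(
    path: str,
    config: SizePartitionConfig,
    min_mapq: int,
    stats: ReadFilterStats,
    exclude_chroms: frozenset,
) -> Iterator[FragmentRecord]:
    import pysam

    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.mate_is_unmapped or not read.is_proper_pair:
                stats.skipped_unpaired += 1
                continue
            if read.is_secondary or read.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if read.is_duplicate:
                stats.skipped_duplicate += 1
                continue
            if read.mapping_quality < min_mapq:
                stats.skipped_low_mapq += 1
                continue
            tlen = read.template_length
            # one record per fragment: emit from the leftmost mate only
            if tlen <= 0:
                continue
            chrom = read.reference_name
            if chrom in exclude_chroms:
                stats.skipped_other += 1
                continue
            fwd5 = read.reference_start
            rev5 = fwd5 + tlen - 1  # 5' base of the reverse mate
            left_cut = fwd5 + config.shift_forward
            right_cut = rev5 + config.shift_reverse
            if right_cut < left_cut:
                stats.skipped_other += 1
                continue
            stats.emitted += 1
            yield FragmentRecord(chrom, left_cut, right_cut + 1)


def read_fragments(
    path: str,
    config: SizePartitionConfig | None = None,
    *,
    min_mapq: int = 30,
    exclude_chroms: Iterable[str] = (),
    stats: ReadFilterStats | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a BAM/SAM alignment or a BED3 fragment file.

    BAM/SAM input: properly-paired primary non-duplicate reads with
    MAPQ >= ``min_mapq``; each fragment is emitted once, from its leftmost
    mate, with the forward cut shifted by ``shift_forward`` and the reverse
    cut by ``shift_reverse`` before interval construction.

    BED input: intervals are taken verbatim and assumed pre-shifted.
    """
    config = config or SizePartitionConfig()
    if stats is None:
        stats = ReadFilterStats()
    exclude = frozenset(exclude_chroms)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".bam", ".sam", ".cram"):
        yield from _iter_bam_fragments(path, config, min_mapq, stats, exclude)
    else:
        for frag in _iter_bed_fragments(path):
            if frag.chrom in exclude:
                stats.skipped_other += 1
                continue
            stats.emitted += 1
            yield frag


def size_class(frag: FragmentRecord, config: SizePartitionConfig | None = None) -> str:
    """Partition a fragment at one nucleosome length (inclusive on 'short')."""
    config = config or SizePartitionConfig()
    return SHORT if frag.size <= config.nucleosome_bp else LONG


def downsample_fragments(
    fragments: Iterable[FragmentRecord], target_n: int, seed: int
) -> list[FragmentRecord]:
    """Uniform subsample without replacement, deterministic for a fixed seed.

    Returns all fragments (input order preserved) if ``target_n`` is not
    smaller than the input size.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    frags = list(fragments)
    if target_n >= len(frags):
        return frags
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frags), size=target_n, replace=False)
    idx.sort()
    return [frags[i] for i in idx]
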