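"""Readers/writers for the plain-text genomic formats used by the pipeline:
FASTA, BED, narrowPeak (BED6+4), JASPAR-style PFM and bedGraph."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Peak",
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "write_bedgraph",
    "write_bed3",
]


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record; ``summit_offset`` is relative to ``start``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    summit_offset: int = -1

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (peak midpoint if no summit given)."""
        if self.summit_offset < 0:
            return (self.start + self.end) // 2
        return self.start + self.summit_offset

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory; keys are record ids."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before FASTA header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path: str, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_narrowpeak(path: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            signal = float(f[6]) if len(f) > 6 else 0.0
            summit = int(f[9]) if len(f) > 9 else -1
            peaks.append(Peak(chrom, start, end, name, score, signal, summit))
    return peaks


def write_narrowpeak(path: str, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{int(p.score)}\t.\t"
                f"{p.signal:g}\t-1\t-1\t{p.summit_offset}\n"
            )


def read_jaspar_pfm(path: str) -> tuple[str, np.ndarray]:
    """Parse a JASPAR PFM: a ``>`` header then 4 rows (A, C, G, T) of counts.

    Accepts both the bracketed layout (``A [ 1 2 3 ]``) and bare rows of
    numbers.  Returns (name, 4 x L count matrix).
    """
    name = "motif"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            parts = cleaned.split()
            if parts and parts[0].upper() in "ACGT":
                parts = parts[1:]
            if parts:
                rows.append([float(p) for p in parts])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 PFM rows, found {len(rows)}")
    mat = np.asarray(rows, dtype=np.float64)
    if mat.shape[1] < 1 or len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: ragged PFM rows")
    return name, mat


def write_jaspar_pfm(path: str, name: str, matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix)
    if matrix.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", matrix):
            vals = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {vals} ]\n")


def write_bedgraph(
    path: str, chrom: str, start: int, values: Sequence[float], name: str | None = None
) -> None:
    """Write a per-base track as bedGraph, merging runs of equal value."""
    values = np.asarray(values, dtype=np.float64)
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        if values.size == 0:
            return
        breaks = np.flatnonzero(np.diff(values)) + 1
        edges = np.concatenate([[0], breaks, [values.size]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            fh.write(f"{chrom}\t{start + lo}\t{start + hi}\t{values[lo]:g}\n")


def write_bed3(path: str, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
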