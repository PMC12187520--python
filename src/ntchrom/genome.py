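"""Genome coordinate system, gene models, and intervals.

All coordinates are 0-based half-open, the BED convention. The genome is
viewed as a concatenation of fixed-size bins (200 bp by default, the
resolution at which chromatin states are called); per-bin arrays across
the whole genome are indexed by a single global bin index, chromosome by
chromosome in declaration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["GenomeSpec", "GeneModel", "Interval"]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus the bin size used for state calling.

    Each chromosome contributes ``ceil(length / bin_size)`` bins; the last
    bin of a chromosome may be shorter than ``bin_size``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def n_bins_per_chrom(self) -> tuple[int, ...]:
        b = self.bin_size
        return tuple(-(-l // b) for l in self.chrom_lengths)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins_per_chrom)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    @property
    def bin_offsets(self) -> dict[str, int]:
        """Global index of each chromosome's first bin."""
        out: dict[str, int] = {}
        acc = 0
        for name, n in zip(self.chrom_names, self.n_bins_per_chrom):
            out[name] = acc
            acc += n
        return out

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_slice(self, chrom: str) -> slice:
        """Slice of a genome-wide per-bin array belonging to one chromosome."""
        start = self.bin_offsets[chrom]
        return slice(start, start + self.n_bins_per_chrom[self.chrom_index(chrom)])

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index containing base-pair position ``pos``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chrom_lengths[ci]})")
        return self.bin_offsets[chrom] + pos // self.bin_size

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index; end clipped to the chromosome."""
        if not 0 <= index < self.total_bins:
            raise IndexError(f"bin index {index} out of range")
        for name, length, n in zip(self.chrom_names, self.chrom_lengths, self.n_bins_per_chrom):
            off = self.bin_offsets[name]
            if index < off + n:
                local = index - off
                start = local * self.bin_size
                return name, start, min(start + self.bin_size, length)
        raise AssertionError("unreachable")

    def bin_widths(self) -> np.ndarray:
        """Width in bp of every bin (only the last bin per chromosome may be short)."""
        w = np.full(self.total_bins, self.bin_size, dtype=np.int64)
        for name, length, n in zip(self.chrom_names, self.chrom_lengths, self.n_bins_per_chrom):
            tail = length - (n - 1) * self.bin_size
            w[self.bin_offsets[name] + n - 1] = tail
        return w


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open body coordinates plus strand.

    The TSS is the first transcribed base: ``start`` on the plus strand and
    ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, halfwidth: int = 2000) -> tuple[int, int]:
        """Promoter window [tss - halfwidth, tss + halfwidth), clipped at 0."""
        return max(0, self.tss - halfwidth), self.tss + halfwidth


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_bp(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def sort_intervals(intervals: list[Interval]) -> list[Interval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def iter_by_chrom(intervals: list[Interval]) -> Iterator[tuple[str, list[Interval]]]:
    by: dict[str, list[Interval]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by):
        yield chrom, sorted(by[chrom], key=lambda iv: (iv.start, iv.end))
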