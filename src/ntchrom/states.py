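"""Per-bin chromatin-state calling and interval/domain construction.

A bin is "marked" by a histone modification when its input-normalized fold
enrichment exceeds a mark-specific threshold (strictly greater than 4 for
H3K4me3, 2 for H3K27me3 and H3K36me3). Combining the two promoter marks
gives the four-state partition: bins carrying both H3K4me3 and H3K27me3 are
Bivalent, one mark only gives K4only/K27only, neither gives Unmarked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec, Interval

STATE_NAMES = ("Unmarked", "K4only", "K27only", "Bivalent")
STATE_CODES = {name: i for i, name in enumerate(STATE_NAMES)}

UNMARKED, K4ONLY, K27ONLY, BIVALENT = range(4)

DEFAULT_FE_THRESHOLDS = {"H3K4me3": 4.0, "H3K27me3": 2.0, "H3K36me3": 2.0}


@dataclass(frozen=True)
class StateSegmentation:
    """A four-state partition of the genome at bin resolution.

    Stored as one state code per bin; the interval view (maximal same-state
    runs, which never cross a chromosome boundary) is derived on demand and
    is canonical: adjacent segments always differ in state, and segments
    tile each chromosome exactly.
    """

    genome: GenomeSpec
    states: np.ndarray
    stage: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        if states.shape != (self.genome.total_bins,):
            raise ValueError("state vector length does not match genome bin count")
        if states.max(initial=0) > 3:
            raise ValueError("state codes must be in 0..3")
        object.__setattr__(self, "states", states)

    def segments(self) -> list[Interval]:
        out: list[Interval] = []
        for chrom, length in zip(self.genome.chrom_names, self.genome.chrom_lengths):
            vals = self.states[self.genome.bin_slice(chrom)]
            n = len(vals)
            starts = np.flatnonzero(np.r_[True, vals[1:] != vals[:-1]])
            ends = np.r_[starts[1:], n]
            for i0, i1 in zip(starts, ends):
                out.append(
                    Interval(
                        chrom,
                        int(i0) * self.genome.bin_size,
                        min(int(i1) * self.genome.bin_size, length),
                        STATE_NAMES[vals[i0]],
                    )
                )
        return out

    def mark_bins(self, mark: str) -> np.ndarray:
        """Boolean bin vector for bins carrying a promoter mark.

        H3K4me3-bearing bins are K4only or Bivalent; H3K27me3-bearing bins
        are K27only or Bivalent.
        """
        if mark == "H3K4me3":
            return (self.states == K4ONLY) | (self.states == BIVALENT)
        if mark == "H3K27me3":
            return (self.states == K27ONLY) | (self.states == BIVALENT)
        raise ValueError(f"segmentation carries no mark {mark!r}")

    def mark_segments(self, mark: str) -> list[Interval]:
        """Maximal runs of mark-bearing bins as intervals (K4only and
        Bivalent runs coalesce for H3K4me3, and symmetrically)."""
        return bins_to_intervals(self.mark_bins(mark), self.genome)


def binarize_mark(enrichment: np.ndarray, threshold: float) -> np.ndarray:
    """Mark a bin iff fold enrichment is strictly greater than the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(enrichment) > threshold


def combine_states(k4: np.ndarray, k27: np.ndarray) -> np.ndarray:
    """Four-state code per bin from the two per-mark boolean calls."""
    k4 = np.asarray(k4, dtype=bool)
    k27 = np.asarray(k27, dtype=bool)
    if k4.shape != k27.shape:
        raise ValueError("mark vectors differ in length")
    # encodes the truth table: (0,0)=Unmarked, (1,0)=K4only, (0,1)=K27only, (1,1)=Bivalent
    return (k4.astype(np.uint8) + 2 * k27.astype(np.uint8)).astype(np.uint8)


def segments_from_bins(
    states: np.ndarray,
    genome: GenomeSpec,
    stage: str | None = None,
    condition: str | None = None,
) -> StateSegmentation:
    """Wrap per-bin state codes as a canonical segmentation."""
    return StateSegmentation(genome=genome, states=np.asarray(states, dtype=np.uint8), stage=stage, condition=condition)


def bins_to_intervals(marked: np.ndarray, genome: GenomeSpec) -> list[Interval]:
    """Maximal runs of True bins as bp intervals, per chromosome."""
    marked = np.asarray(marked, dtype=bool)
    if marked.shape != (genome.total_bins,):
        raise ValueError("bin vector length does not match genome bin count")
    out: list[Interval] = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        vals = marked[genome.bin_slice(chrom)]
        padded = np.r_[False, vals, False].astype(np.int8)
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for i0, i1 in zip(starts, ends):
            out.append(Interval(chrom, int(i0) * genome.bin_size, min(int(i1) * genome.bin_size, length)))
    return out


def merge_domains(peaks: list[Interval], max_gap: int = 5000) -> list[Interval]:
    """Merge peaks transitively when the gap between them is < max_gap (strict).

    The gap is next.start - prev.end; overlapping peaks (negative gap) always
    merge. Output is sorted and disjoint. Idempotent for any max_gap >= 0.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    from .genome import iter_by_chrom

    out: list[Interval] = []
    for chrom, ivs in iter_by_chrom(peaks):
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e < max_gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def call_mark_domains(binarized: np.ndarray, genome: GenomeSpec, max_gap: int = 5000) -> list[Interval]:
    """Domains from a binarized track: marked-bin runs become peaks, then
    peaks closer than max_gap are merged."""
    return merge_domains(bins_to_intervals(binarized, genome), max_gap=max_gap)
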