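"""Binned ChIP/input tracks and enrichment computations.

Enrichment is always input-normalized: per-bin fold enrichment (the bin
classifier's input) and regional log2 RPKM enrichment (the browser-view and
promoter/gene-body score). Both add a pseudocount to raw counts before rate
normalization, because zero-coverage input bins are routine at low depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import GenomeSpec, Interval

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3")


@dataclass(frozen=True)
class BinnedTrack:
    """Per-bin ChIP and matched input counts for one mark/stage/condition."""

    genome: GenomeSpec
    mark: str
    stage: str
    condition: str
    chip_counts: np.ndarray
    input_counts: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        chip = np.asarray(self.chip_counts)
        inp = np.asarray(self.input_counts)
        n = self.genome.total_bins
        if chip.shape != (n,) or inp.shape != (n,):
            raise ValueError("count vector length does not match genome bin count")
        if (chip < 0).any() or (inp < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "chip_counts", chip)
        object.__setattr__(self, "input_counts", inp)

    @property
    def chip_library_size(self) -> float:
        return float(self.chip_counts.sum())

    @property
    def input_library_size(self) -> float:
        return float(self.input_counts.sum())

    def _region_counts(self, region: Interval) -> tuple[float, float, int]:
        """(chip, input) counts over a region, bins weighted by overlap fraction."""
        g = self.genome
        if region.chrom not in g.chrom_names:
            raise ValueError(f"region chromosome {region.chrom!r} not in genome")
        length = g.chrom_sizes[region.chrom]
        if region.start < 0 or region.end > length:
            raise ValueError(f"region {region.start}-{region.end} outside {region.chrom} (length {length})")
        b = g.bin_size
        off = g.bin_offsets[region.chrom]
        first, last = region.start // b, -(-region.end // b)
        idx = np.arange(first, last)
        bin_starts = idx * b
        bin_ends = np.minimum(bin_starts + b, length)
        ov = np.minimum(bin_ends, region.end) - np.maximum(bin_starts, region.start)
        frac = ov / (bin_ends - bin_starts)
        sl = slice(off + first, off + last)
        chip = float(np.sum(self.chip_counts[sl] * frac))
        inp = float(np.sum(self.input_counts[sl] * frac))
        return chip, inp, region.end - region.start


def fold_enrichment(track: BinnedTrack, pseudocount: float = 1.0) -> np.ndarray:
    """Per-bin fold enrichment: library-normalized (chip + pc) over (input + pc).

    FE_i = ((chip_i + pc) / chip_total) / ((input_i + pc) / input_total).
    Invariant to uniform scaling of either library.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ct, it = track.chip_library_size, track.input_library_size
    if ct == 0 or it == 0:
        raise ValueError("zero library size")
    return ((track.chip_counts + pseudocount) / ct) / ((track.input_counts + pseudocount) / it)


def log2_rpkm_enrichment(track: BinnedTrack, region: Interval, pseudocount: float = 1.0) -> float:
    """log2(chip RPKM + pc) - log2(input RPKM + pc) over one region.

    RPKM = counts * 1e9 / (region bp * library size).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    chip, inp, width = track._region_counts(region)
    ct, it = track.chip_library_size, track.input_library_size
    if ct == 0 or it == 0:
        raise ValueError("zero library size")
    chip_rpkm = chip * 1e9 / (width * ct)
    input_rpkm = inp * 1e9 / (width * it)
    return float(np.log2((chip_rpkm + pseudocount) / (input_rpkm + pseudocount)))


def replicate_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    promoters: list[Interval],
    pseudocount: float = 1.0,
) -> float:
    """Pearson r of per-promoter log2 RPKM enrichment between two replicates.

    Returns NaN when either vector has zero variance (correlation undefined).
    """
    if len(promoters) < 3:
        raise ValueError("need at least 3 promoters")
    a = np.array([log2_rpkm_enrichment(track_a, p, pseudocount) for p in promoters])
    b = np.array([log2_rpkm_enrichment(track_b, p, pseudocount) for p in promoters])
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pool_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Sum counts of highly correlated replicates into one pooled track."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.genome, t.mark, t.stage, t.condition) != (first.genome, first.mark, first.stage, first.condition):
            raise ValueError("cannot pool tracks with mismatched genome/mark/stage/condition")
    chip = np.sum([t.chip_counts for t in tracks], axis=0)
    inp = np.sum([t.input_counts for t in tracks], axis=0)
    return replace(first, chip_counts=chip, input_counts=inp, replicate=None)
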