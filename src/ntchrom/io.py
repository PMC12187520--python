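"""Readers and writers for the flat-file dialects the pipeline consumes.

Supported: gene models (BED12 or a minimal TSV), bedGraph coverage binned
onto the genome grid, four-state segmentation BED, and gene x sample count
matrices as TSV. Everything is 0-based half-open.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeSpec, Interval

GENE_TSV_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def read_gene_models(path: str | Path, format: str = "infer") -> list[GeneModel]:
    """Read gene models from BED12 (first 6 columns used) or the minimal TSV.

    The file must be pre-collapsed to one record per gene_id; duplicates are
    an error. Output is sorted by (chrom, start).
    """
    path = Path(path)
    if format == "infer":
        format = "bed12" if path.suffix in (".bed", ".bed12") else "tsv"
    genes: list[GeneModel] = []
    if format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
                chrom, start, end, name, _score, strand = fields[:6]
                try:
                    genes.append(GeneModel(name, chrom, int(start), int(end), strand))
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: {e}") from None
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in GENE_TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            try:
                genes.append(GeneModel(str(row.gene_id), str(row.chrom), int(row.start), int(row.end), str(row.strand)))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    else:
        raise ValueError(f"unknown gene-model format {format!r}")

    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate gene_ids {dupes[:5]}")
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand, g.gene_id) for g in genes],
        columns=GENE_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_bedgraph_to_bins(path: str | Path, genome: GenomeSpec) -> np.ndarray:
    """Bin a bedGraph onto the genome grid by length-weighted mean.

    Each bin receives sum(value x overlap bp) / bin width; base pairs not
    covered by any record contribute 0. Records beyond chromosome bounds are
    an error; unsorted input is accepted with a warning (order is irrelevant
    to the accumulation).
    """
    path = Path(path)
    acc = np.zeros(genome.total_bins, dtype=float)
    b = genome.bin_size
    offsets = genome.bin_offsets
    sizes = genome.chrom_sizes
    last_seen: dict[str, int] = {}
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s < 0 or e > sizes[chrom] or s >= e:
                raise ValueError(f"{path}:{lineno}: interval {s}-{e} outside {chrom} (length {sizes[chrom]})")
            if not warned and last_seen.get(chrom, -1) > s:
                warnings.warn(f"{path}: bedGraph not sorted; binning is order-independent", stacklevel=2)
                warned = True
            last_seen[chrom] = s
            first, last = s // b, (e - 1) // b
            off = offsets[chrom]
            if first == last:
                acc[off + first] += v * (e - s)
            else:
                acc[off + first] += v * ((first + 1) * b - s)
                acc[off + last] += v * (e - last * b)
                if last - first > 1:
                    acc[off + first + 1 : off + last] += v * b
    return acc / genome.bin_widths()


def write_bedgraph(values: np.ndarray, genome: GenomeSpec, path: str | Path) -> None:
    """Write per-bin values as bedGraph, merging adjacent equal-valued bins
    and omitting zero runs."""
    values = np.asarray(values)
    if values.shape != (genome.total_bins,):
        raise ValueError("values length does not match genome bin count")
    with open(path, "w") as fh:
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            sl = genome.bin_slice(chrom)
            vals = values[sl]
            n = len(vals)
            starts = np.flatnonzero(np.r_[True, vals[1:] != vals[:-1]])
            ends = np.r_[starts[1:], n]
            for i0, i1 in zip(starts, ends):
                v = vals[i0]
                if v == 0:
                    continue
                s = i0 * genome.bin_size
                e = min(i1 * genome.bin_size, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_segmentation(seg, path: str | Path) -> None:
    """Write a StateSegmentation as 4-column BED (chrom, start, end, state).

    Adjacent same-state segments are merged first (canonical form);
    overlapping segments are an error by construction of the segmentation.
    """
    with open(path, "w") as fh:
        for iv in seg.segments():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_segmentation(path: str | Path, genome: GenomeSpec, stage: str | None = None, condition: str | None = None):
    """Read a segmentation BED back into a StateSegmentation.

    Segments must tile each chromosome exactly and align to the bin grid.
    """
    from .states import STATE_CODES, StateSegmentation

    path = Path(path)
    codes = np.full(genome.total_bins, -1, dtype=np.int8)
    sizes = genome.chrom_sizes
    b = genome.bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, state = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chrom not in sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if state not in STATE_CODES:
                raise ValueError(f"{path}:{lineno}: unknown state {state!r}")
            if s % b != 0 or (e % b != 0 and e != sizes[chrom]):
                raise ValueError(f"{path}:{lineno}: segment not aligned to {b} bp grid")
            off = genome.bin_offsets[chrom]
            first, last = s // b, -(-e // b)
            target = codes[off + first : off + last]
            if (target != -1).any():
                raise ValueError(f"{path}:{lineno}: overlapping segments")
            target[:] = STATE_CODES[state]
    if (codes == -1).any():
        raise ValueError(f"{path}: segments do not cover the genome")
    return StateSegmentation(genome=genome, states=codes.astype(np.uint8), stage=stage, condition=condition)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample count matrix: header row, gene_id first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene_ids in count matrix")
    return df


def write_intervals_bed(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_intervals_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            label = fields[3] if len(fields) > 3 else None
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), label))
    return out
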