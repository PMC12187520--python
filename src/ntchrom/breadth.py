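"""Promoter-anchored H3K4me3 domain breadth: width measurement, the
broad/medium/narrow/control taxonomy, and stage-to-stage class dynamics.

Broad H3K4me3 domains (wider than 5 kb) mark highly transcribed, identity
genes; the taxonomy boundaries are: broad > 5000 bp, medium in (1000, 5000],
narrow in (200, 1000], control <= 200 bp (control promoters are considered
not marked by H3K4me3 at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, Interval

BREADTH_CLASSES = ("broad", "medium", "narrow", "control")


@dataclass(frozen=True)
class BreadthRecord:
    gene_id: str
    stage: str
    condition: str
    width: int
    klass: str

    def __post_init__(self) -> None:
        if self.klass != classify_breadth(self.width):
            raise ValueError(f"{self.gene_id}: class {self.klass!r} inconsistent with width {self.width}")


def classify_breadth(width: int) -> str:
    if width < 0:
        raise ValueError("width must be nonnegative")
    if width > 5000:
        return "broad"
    if width > 1000:
        return "medium"
    if width > 200:
        return "narrow"
    return "control"


def promoter_domain_width(gene: GeneModel, k4_segments: list[Interval], halfwidth: int = 2000) -> int:
    """Full (unclipped) width of the widest H3K4me3-bearing segment
    overlapping the promoter [tss - halfwidth, tss + halfwidth); 0 if none.

    Ties in width break toward the segment whose midpoint is nearer the TSS.
    The segments passed in should be H3K4me3-bearing runs (K4only and
    Bivalent coalesced), e.g. ``StateSegmentation.mark_segments("H3K4me3")``.
    """
    p_start, p_end = gene.promoter(halfwidth)
    best: tuple[int, int] | None = None  # (width, -distance) maximized
    for seg in k4_segments:
        if seg.chrom != gene.chrom or seg.overlap_bp(p_start, p_end) <= 0:
            continue
        dist = abs((seg.start + seg.end) // 2 - gene.tss)
        key = (seg.width, -dist)
        if best is None or key > best:
            best = key
    return best[0] if best is not None else 0


def breadth_table(
    genes: list[GeneModel],
    seg,
    stage: str,
    condition: str,
    halfwidth: int = 2000,
    bridge_gap: int = 0,
) -> pd.DataFrame:
    """Per-gene width and class against one segmentation.

    ``bridge_gap`` > 0 closes gaps shorter than that many bp between
    H3K4me3-bearing runs before measuring widths — a morphological stand-in
    for the run persistence an HMM segmentation would provide, guarding
    domain widths against single-bin dropouts. Returns a DataFrame indexed
    by gene_id with columns width, klass.
    """
    from .states import call_mark_domains

    if bridge_gap > 0:
        k4_segments = call_mark_domains(seg.mark_bins("H3K4me3"), seg.genome, max_gap=bridge_gap)
    else:
        k4_segments = seg.mark_segments("H3K4me3")
    by_chrom: dict[str, list[Interval]] = {}
    for iv in k4_segments:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    rows = []
    for g in genes:
        w = promoter_domain_width(g, by_chrom.get(g.chrom, []), halfwidth)
        rows.append((g.gene_id, stage, condition, w, classify_breadth(w)))
    df = pd.DataFrame(rows, columns=["gene_id", "stage", "condition", "width", "klass"])
    return df.set_index("gene_id")


def breadth_transitions(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """4x4 row-stochastic matrix of class membership flow from stage A to B.

    Entry (i, j) is the fraction of genes in class i at A found in class j
    at B. Rows for classes with no genes at A are NaN. The two tables must
    cover the same gene universe.
    """
    if set(records_a.index) != set(records_b.index):
        raise ValueError("gene universes differ between stages")
    a = records_a["klass"]
    b = records_b["klass"].reindex(a.index)
    counts = pd.crosstab(a, b).reindex(index=BREADTH_CLASSES, columns=BREADTH_CLASSES, fill_value=0)
    totals = counts.sum(axis=1)
    frac = counts.div(totals.replace(0, np.nan), axis=0)
    return frac


def mean_log_breadth(records: pd.DataFrame) -> float:
    """Mean over genes of log10(domain width + 1), the stage-level breadth summary."""
    if len(records) == 0:
        raise ValueError("no breadth records")
    return float(np.mean(np.log10(records["width"].to_numpy() + 1.0)))
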