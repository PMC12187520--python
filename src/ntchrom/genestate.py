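"""Gene-level chromatin states, 0/1 stage matrices, bin-level transition
accounting across stages, and condition-specific marking fractions.

A gene inherits marks from its promoter (TSS +/- 2 kb): it is H3K4me3-marked
when the promoter's total overlap with H3K4me3-only or Bivalent segments
exceeds 200 bp (strictly), H3K27me3-marked symmetrically, and Bivalent when
the Bivalent-segment overlap itself exceeds 200 bp or when both exclusive
single-mark overlaps do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel
from .states import BIVALENT, K4ONLY, K27ONLY, STATE_NAMES, StateSegmentation

GENE_STATES = ("Unmarked", "K4marked-only", "K27marked-only", "Bivalent")


def _promoter_state_overlaps(gene: GeneModel, seg: StateSegmentation, halfwidth: int) -> np.ndarray:
    """bp of promoter overlap with each of the four bin states."""
    g = seg.genome
    if gene.chrom not in g.chrom_names:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    length = g.chrom_sizes[gene.chrom]
    p_start, p_end = gene.promoter(halfwidth)
    if p_end > length:
        warnings.warn(f"{gene.gene_id}: promoter clipped to chromosome end", stacklevel=3)
        p_end = length
    if p_start >= p_end:
        return np.zeros(4)
    b = g.bin_size
    off = g.bin_offsets[gene.chrom]
    first, last = p_start // b, -(-p_end // b)
    idx = np.arange(first, last)
    bin_starts = idx * b
    bin_ends = np.minimum(bin_starts + b, length)
    ov = np.minimum(bin_ends, p_end) - np.maximum(bin_starts, p_start)
    codes = seg.states[off + first : off + last]
    out = np.zeros(4)
    np.add.at(out, codes, ov)
    return out


def assign_gene_state(
    gene: GeneModel,
    seg: StateSegmentation,
    min_overlap: int = 200,
    halfwidth: int = 2000,
    inclusive: bool = False,
) -> tuple[str, bool, bool]:
    """(state, k4_marked, k27_marked) for one gene against one segmentation.

    Overlap evidence is summed across all promoter segments of the relevant
    classes before the threshold test, which is strict (> min_overlap) by
    default; ``inclusive=True`` switches to >=. A gene that is both
    H3K4me3- and H3K27me3-marked but satisfies neither bivalent clause is
    still labeled Bivalent, so the label never contradicts the mark booleans.
    """
    ov = _promoter_state_overlaps(gene, seg, halfwidth)
    passes = (lambda x: x >= min_overlap) if inclusive else (lambda x: x > min_overlap)
    k4 = passes(ov[K4ONLY] + ov[BIVALENT])
    k27 = passes(ov[K27ONLY] + ov[BIVALENT])
    bivalent = passes(ov[BIVALENT]) or (passes(ov[K4ONLY]) and passes(ov[K27ONLY]))
    if bivalent or (k4 and k27):
        state = "Bivalent"
    elif k4:
        state = "K4marked-only"
    elif k27:
        state = "K27marked-only"
    else:
        state = "Unmarked"
    return state, bool(k4), bool(k27)


def gene_state_table(
    genes: list[GeneModel],
    segs: dict[str, StateSegmentation],
    min_overlap: int = 200,
    halfwidth: int = 2000,
) -> dict[str, pd.DataFrame]:
    """Genes x stages state and mark matrices.

    ``segs`` maps stage name -> segmentation (one condition). Returns dict
    with 'state' (labels), 'k4_marked' and 'k27_marked' (booleans), each a
    DataFrame indexed by gene_id with stages as columns in input order.
    """
    ids = [g.gene_id for g in genes]
    state = pd.DataFrame(index=ids, columns=list(segs), dtype=object)
    k4 = pd.DataFrame(index=ids, columns=list(segs), dtype=bool)
    k27 = pd.DataFrame(index=ids, columns=list(segs), dtype=bool)
    for stage, seg in segs.items():
        for g in genes:
            s, a, b = assign_gene_state(g, seg, min_overlap, halfwidth)
            state.at[g.gene_id, stage] = s
            k4.at[g.gene_id, stage] = a
            k27.at[g.gene_id, stage] = b
    return {"state": state, "k4_marked": k4, "k27_marked": k27}


def binary_matrix(marked: pd.DataFrame) -> pd.DataFrame:
    """0/1 genes x stages matrix ranked for heat-map display.

    Rows are sorted descending by the integer whose binary digits are the
    stage-ordered row (earliest stage = most significant digit); ties break
    by gene_id ascending. Input is a boolean genes x stages frame.
    """
    mat = marked.astype(int)
    weights = 2 ** np.arange(mat.shape[1] - 1, -1, -1)
    score = mat.to_numpy() @ weights
    order = sorted(range(len(mat)), key=lambda i: (-score[i], mat.index[i]))
    return mat.iloc[order]


@dataclass(frozen=True)
class TransitionTable:
    """Per-bin state trajectories across an ordered stage list, plus the
    4x4 transition count matrix for each adjacent stage pair."""

    stages: tuple[str, ...]
    trajectories: np.ndarray  # bins x stages, state codes
    pair_counts: tuple[np.ndarray, ...]  # one 4x4 per adjacent pair

    @property
    def n_bins(self) -> int:
        return self.trajectories.shape[0]


def bin_state_transitions(segs: list[StateSegmentation], stages: list[str] | None = None) -> TransitionTable:
    """Tally 200-bp-bin state transitions between consecutive stages."""
    if not segs:
        raise ValueError("need at least one segmentation")
    genome = segs[0].genome
    for s in segs[1:]:
        if s.genome != genome:
            raise ValueError("segmentations are on different genomes")
    if stages is None:
        stages = [s.stage or f"stage{i}" for i, s in enumerate(segs)]
    traj = np.stack([s.states for s in segs], axis=1)
    pairs = []
    for j in range(len(segs) - 1):
        m = np.zeros((4, 4), dtype=np.int64)
        np.add.at(m, (traj[:, j], traj[:, j + 1]), 1)
        pairs.append(m)
    return TransitionTable(stages=tuple(stages), trajectories=traj, pair_counts=tuple(pairs))


def persistent_state_bins(table: TransitionTable, state: int | str) -> tuple[np.ndarray, np.ndarray]:
    """Bins holding one state at every stage, plus the per-stage trend.

    Returns (bin indices persistent in ``state``, per-stage fraction of all
    bins carrying ``state``) — the trend line drawn alongside alluvial
    plots.
    """
    code = STATE_NAMES.index(state) if isinstance(state, str) else int(state)
    is_state = table.trajectories == code
    persistent = np.flatnonzero(is_state.all(axis=1))
    per_stage_fraction = is_state.mean(axis=0)
    return persistent, per_stage_fraction


def condition_specific_fraction(marked_a: set, marked_b: set) -> tuple[float, float]:
    """(specific, overlapped) fractions of condition A's marked genes.

    specific = |A \\ B| / |A|; overlapped = |A n B| / |A|; they sum to 1.
    """
    if not marked_a:
        raise ValueError("condition A has no marked genes")
    n_a = len(marked_a)
    n_int = len(marked_a & marked_b)
    return (n_a - n_int) / n_a, n_int / n_a


def gain_loss_percentages(prev_marked: pd.Series, curr_marked: pd.Series) -> tuple[float, float]:
    """Percent of all genes gaining / losing a mark relative to the previous stage."""
    if not prev_marked.index.equals(curr_marked.index):
        curr_marked = curr_marked.reindex(prev_marked.index)
        if curr_marked.isna().any():
            raise ValueError("gene universes differ between stages")
    prev = prev_marked.astype(bool).to_numpy()
    curr = curr_marked.astype(bool).to_numpy()
    gain = 100.0 * np.mean(curr & ~prev)
    loss = 100.0 * np.mean(prev & ~curr)
    return float(gain), float(loss)
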