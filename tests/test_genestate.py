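"""Gene-level state assignment, 0/1 matrices, bin transition tallies, and
marking-change summaries."""

import numpy as np
import pandas as pd
import pytest

from ntchrom.genestate import (
    assign_gene_state,
    bin_state_transitions,
    binary_matrix,
    condition_specific_fraction,
    gain_loss_percentages,
    persistent_state_bins,
)
from ntchrom.genome import GeneModel, GenomeSpec
from ntchrom.states import STATE_CODES, segments_from_bins

from conftest import random_states


def _seg(genome, spans):
    """Segmentation from (state, n_bins) run spec covering the genome."""
    states = np.zeros(genome.total_bins, np.uint8)
    pos = 0
    for state, nbins in spans:
        states[pos : pos + nbins] = STATE_CODES[state]
        pos += nbins
    return segments_from_bins(states, genome)


@pytest.fixture
def genome():
    return GenomeSpec(("chrA",), (20_000,), 200)  # 100 bins


# promoter of this gene is [2000, 6000) = bins 10..19
GENE = GeneModel("g", "chrA", 4000, 9000, "+")


class TestAssignGeneState:
    def test_promoter_inside_bivalent_segment(self, genome):
        seg = _seg(genome, [("Bivalent", 100)])
        state, k4, k27 = assign_gene_state(GENE, seg)
        assert (state, k4, k27) == ("Bivalent", True, True)

    def test_exact_200bp_overlap_is_not_marked(self, genome):
        # exactly one K4only bin (200 bp) inside the promoter: strict > fails
        seg = _seg(genome, [("Unmarked", 10), ("K4only", 1), ("Unmarked", 89)])
        state, k4, k27 = assign_gene_state(GENE, seg)
        assert (state, k4, k27) == ("Unmarked", False, False)
        # the inclusive variant flips it
        state_inc, k4_inc, _ = assign_gene_state(GENE, seg, inclusive=True)
        assert k4_inc and state_inc == "K4marked-only"

    def test_two_bins_of_one_mark_is_marked(self, genome):
        seg = _seg(genome, [("Unmarked", 10), ("K4only", 2), ("Unmarked", 88)])
        state, k4, k27 = assign_gene_state(GENE, seg)
        assert (state, k4, k27) == ("K4marked-only", True, False)

    def test_separate_k4_and_k27_overlaps_make_bivalent(self, genome):
        # 400 bp K4only plus 400 bp K27only inside the promoter, no Bivalent bins
        seg = _seg(genome, [("Unmarked", 10), ("K4only", 2), ("Unmarked", 3), ("K27only", 2), ("Unmarked", 83)])
        state, k4, k27 = assign_gene_state(GENE, seg)
        assert (state, k4, k27) == ("Bivalent", True, True)

    def test_summed_overlap_evidence_across_fragments(self, genome):
        # two separate single K4only bins sum to 400 bp > 200
        seg = _seg(genome, [("Unmarked", 11), ("K4only", 1), ("Unmarked", 3), ("K4only", 1), ("Unmarked", 84)])
        state, k4, _ = assign_gene_state(GENE, seg)
        assert k4 and state == "K4marked-only"

    @pytest.mark.parametrize("seed", range(50))
    def test_label_never_contradicts_mark_booleans(self, genome, seed):
        rng = np.random.default_rng(seed)
        seg = segments_from_bins(random_states(rng, genome), genome)
        tss = int(rng.integers(2000, 18_000))
        gene = GeneModel("g", "chrA", tss, tss + 1000, "+")
        state, k4, k27 = assign_gene_state(gene, seg)
        if state == "Bivalent":
            assert k4 and k27
        elif state == "K4marked-only":
            assert k4 and not k27
        elif state == "K27marked-only":
            assert k27 and not k4
        else:
            assert not k4 and not k27


class TestBinaryMatrix:
    def test_fully_marked_gene_ranks_first(self):
        marked = pd.DataFrame(
            {"s1": [False, True, False], "s2": [True, True, False], "s3": [False, True, True]},
            index=["a", "b", "c"],
        )
        out = binary_matrix(marked)
        assert list(out.index) == ["b", "a", "c"]  # scores 7, 2, 1

    def test_all_zero_falls_back_to_gene_id_order(self):
        marked = pd.DataFrame(False, index=["z", "m", "a"], columns=["s1", "s2"])
        assert list(binary_matrix(marked).index) == ["a", "m", "z"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_base_two_score_oracle(self, seed):
        rng = np.random.default_rng(seed)
        marked = pd.DataFrame(
            rng.random((8, 4)) < 0.5, index=[f"g{i}" for i in range(8)], columns=list("wxyz")
        )
        out = binary_matrix(marked)
        score = {g: int("".join(str(int(v)) for v in marked.loc[g]), 2) for g in marked.index}
        expected = sorted(marked.index, key=lambda g: (-score[g], g))
        assert list(out.index) == expected


class TestBinStateTransitions:
    def test_identical_segmentations_give_diagonal_counts(self, genome):
        rng = np.random.default_rng(0)
        seg = segments_from_bins(random_states(rng, genome), genome)
        table = bin_state_transitions([seg, seg], ["a", "b"])
        m = table.pair_counts[0]
        assert m.sum() == genome.total_bins
        assert (m - np.diag(np.diag(m)) == 0).all()

    def test_single_bin_genome_trajectory_length(self):
        g = GenomeSpec(("c",), (200,), 200)
        segs = [segments_from_bins(np.array([s], np.uint8), g) for s in (0, 3, 1)]
        table = bin_state_transitions(segs, ["a", "b", "c"])
        assert table.trajectories.shape == (1, 3)
        assert table.trajectories[0].tolist() == [0, 3, 1]

    @pytest.mark.parametrize("seed", range(100))
    def test_counts_match_per_bin_tally(self, genome, seed):
        rng = np.random.default_rng(seed)
        segs = [segments_from_bins(random_states(rng, genome), genome) for _ in range(3)]
        table = bin_state_transitions(segs)
        for j in range(2):
            tally = np.zeros((4, 4), dtype=int)
            for i in range(genome.total_bins):
                tally[segs[j].states[i], segs[j + 1].states[i]] += 1
            assert (table.pair_counts[j] == tally).all()
            # marginals equal per-stage state totals
            assert (table.pair_counts[j].sum(axis=1) == np.bincount(segs[j].states, minlength=4)).all()

    def test_mismatched_genomes_rejected(self, genome):
        other = GenomeSpec(("c",), (400,), 200)
        a = segments_from_bins(np.zeros(genome.total_bins, np.uint8), genome)
        b = segments_from_bins(np.zeros(other.total_bins, np.uint8), other)
        with pytest.raises(ValueError, match="genome"):
            bin_state_transitions([a, b])


class TestPersistentStateBins:
    def test_state_absent_at_one_stage_gives_empty(self, genome):
        a = segments_from_bins(np.full(genome.total_bins, 1, np.uint8), genome)
        b = segments_from_bins(np.zeros(genome.total_bins, np.uint8), genome)
        bins, _ = persistent_state_bins(bin_state_transitions([a, b]), "K4only")
        assert len(bins) == 0

    def test_identical_stages_return_that_stages_bins(self, genome):
        rng = np.random.default_rng(1)
        seg = segments_from_bins(random_states(rng, genome), genome)
        bins, frac = persistent_state_bins(bin_state_transitions([seg, seg, seg]), "Bivalent")
        expected = np.flatnonzero(seg.states == 3)
        assert (bins == expected).all()
        assert frac.tolist() == [len(expected) / genome.total_bins] * 3

    def test_matches_set_intersection_oracle(self, genome):
        rng = np.random.default_rng(2)
        segs = [segments_from_bins(random_states(rng, genome), genome) for _ in range(4)]
        bins, _ = persistent_state_bins(bin_state_transitions(segs), "K27only")
        oracle = set(range(genome.total_bins))
        for s in segs:
            oracle &= set(np.flatnonzero(s.states == 2))
        assert set(bins.tolist()) == oracle


class TestMarkingFractions:
    def test_equal_sets_fully_overlap(self):
        assert condition_specific_fraction({"a", "b"}, {"a", "b"}) == (0.0, 1.0)

    def test_disjoint_sets_fully_specific(self):
        assert condition_specific_fraction({"a"}, {"b"}) == (1.0, 0.0)

    def test_set_arithmetic_example(self):
        a = set(range(10))
        b = set(range(6, 20))  # intersect = {6..9}, 4 genes
        spec, over = condition_specific_fraction(a, b)
        assert (spec, over) == (0.6, 0.4)
        assert spec + over == 1.0

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            condition_specific_fraction(set(), {"a"})

    def test_gain_loss_identical_stages(self):
        s = pd.Series([True, False, True], index=list("abc"))
        assert gain_loss_percentages(s, s) == (0.0, 0.0)

    def test_gain_loss_all_newly_marked(self):
        prev = pd.Series([False] * 4, index=list("abcd"))
        curr = pd.Series([True] * 4, index=list("abcd"))
        assert gain_loss_percentages(prev, curr) == (100.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_gain_loss_matches_boolean_diff_oracle(self, seed):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(40)]
        prev = pd.Series(rng.random(40) < 0.5, index=idx)
        curr = pd.Series(rng.random(40) < 0.5, index=idx)
        gain, loss = gain_loss_percentages(prev, curr)
        o_gain = 100 * sum((not p) and c for p, c in zip(prev, curr)) / 40
        o_loss = 100 * sum(p and (not c) for p, c in zip(prev, curr)) / 40
        assert (gain, loss) == (pytest.approx(o_gain), pytest.approx(o_loss))
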