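"""Synthetic genomes, ChIP tracks, and expression counts with planted
chromatin-state structure.

The generator emulates the two-condition, multi-stage design of nuclear
transfer (NT) versus naturally fertilized (NF) embryos, plus a Setd2-
overexpression rescue: at one focal stage (the 2-cell-like stage) the NT
condition carries aberrantly broadened promoter H3K4me3 domains, excess
promoter H3K27me3, and depleted gene-body H3K36me3, while the rescue
condition restores all three to the NF configuration. Expression counts are
negative binomial with planted log2 fold changes that track the planted
promoter defects, defining ground-truth ob/us/ue/od gene categories.

Randomness is split into named streams — genome/truth, track noise, and
expression noise — so recovery tests can vary sampling noise while holding
the planted truth fixed.

ChIP counts are Poisson at bin level: background mean ``background`` per
bin everywhere, multiplied by a mark-specific enrichment inside planted
domains (well above the downstream binarization thresholds of 4 and 2).
H3K36me3 is excluded structurally from bins planted as H3K4me3- or
H3K27me3-marked, the mutual-exclusion structure the exclusivity index is
meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breadth import classify_breadth
from .genome import GeneModel, GenomeSpec, Interval
from .signal import BinnedTrack
from .states import combine_states

CATEGORY_NAMES = ("obH3K4me3", "usH3K4me3", "ueH3K27me3", "odH3K27me3")

# planted width ranges per breadth class, in bins of 200 bp, inclusive;
# chosen one bin inside the class boundaries so +/-1 bin of calling noise
# cannot flip the class (except narrow's low edge, which is rare)
_CLASS_BIN_RANGES = {"broad": (27, 40), "medium": (7, 20), "narrow": (2, 4), "control": (0, 0)}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    bin_size: int = 200
    n_genes: int = 800
    promoter_halfwidth: int = 2000
    stages: tuple[str, ...] = ("CC", "2C", "4C", "morula")
    focal_stage: str = "2C"
    conditions: tuple[str, ...] = ("NF", "NT", "Setd2OE")
    # baseline breadth-class mix and its stage-to-stage persistence
    class_fractions: dict = field(
        default_factory=lambda: {"broad": 0.10, "medium": 0.30, "narrow": 0.20, "control": 0.40}
    )
    class_persistence: float = 0.8
    # promoter H3K27me3
    k27_fraction: float = 0.15
    k27_block_bp: int = 2000
    # gene-body H3K36me3
    expressed_fraction: float = 0.5
    nt_k36_loss: float = 0.7
    # planted NT defects at the focal stage
    category_fraction: float = 0.05  # each of ob/us/ue/od
    extra_broadened_fraction: float = 0.05
    extra_nt_k27_fraction: float = 0.10
    planted_log2fc: float = 3.0
    # ChIP counts
    background: float = 100.0
    enrichment: dict = field(
        default_factory=lambda: {"H3K4me3": 40.0, "H3K27me3": 8.0, "H3K36me3": 8.0}
    )
    # expression counts
    base_mean: float = 1000.0
    low_expr_mean: float = 10.0
    dispersion: float = 0.005
    n_replicates: int = 3

    def __post_init__(self) -> None:
        planted = 4 * self.category_fraction + self.extra_broadened_fraction + self.extra_nt_k27_fraction
        if planted > 1:
            raise ValueError("planted gene fractions exceed 1")
        if abs(sum(self.class_fractions.values()) - 1) > 1e-9:
            raise ValueError("breadth class fractions must sum to 1")
        if self.focal_stage not in self.stages:
            raise ValueError("focal_stage must be one of stages")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.chrom_names, self.chrom_lengths, self.bin_size)

    def rng(self, stream: int, rep: int = 0) -> np.random.Generator:
        """Named RNG substream (0 = genome/truth, 1 = tracks, 2 = expression)."""
        return np.random.default_rng([self.seed, stream, rep])


@dataclass
class TruthSet:
    """Planted per-gene state of the simulation, for recovery testing.

    ``marks[(condition, stage)]`` is a frame indexed by gene_id with columns
    k4_width (bp of planted promoter H3K4me3 domain, 0 = none), k27
    (planted promoter H3K27me3 block) and k36 (planted gene-body H3K36me3).
    ``expression`` holds the planted NT-over-NF log2FC at the focal stage
    and the planted category.
    """

    config: SimulationConfig
    genome: GenomeSpec
    genes: list[GeneModel]
    marks: dict[tuple[str, str], pd.DataFrame]
    expression: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def _k4_bins_of(self, gene: GeneModel, width: int) -> tuple[int, int]:
        b = self.genome.bin_size
        nb = int(width) // b
        off = self.genome.bin_offsets[gene.chrom]
        tss_bin = gene.tss // b
        n_chrom = self.genome.n_bins_per_chrom[self.genome.chrom_index(gene.chrom)]
        lo = max(0, tss_bin - nb // 2)
        hi = min(n_chrom, lo + nb)
        return off + lo, off + hi

    def mark_bin_sets(self, condition: str, stage: str) -> dict[str, np.ndarray]:
        """Planted marked-bin boolean vectors for one condition/stage."""
        n = self.genome.total_bins
        k4 = np.zeros(n, dtype=bool)
        k27 = np.zeros(n, dtype=bool)
        k36 = np.zeros(n, dtype=bool)
        marks = self.marks[(condition, stage)]
        b = self.genome.bin_size
        for g in self.genes:
            row = marks.loc[g.gene_id]
            if row["k4_width"] > 0:
                lo, hi = self._k4_bins_of(g, int(row["k4_width"]))
                k4[lo:hi] = True
            if row["k27"]:
                lo, hi = self._k4_bins_of(g, self.config.k27_block_bp)
                k27[lo:hi] = True
            if row["k36"]:
                off = self.genome.bin_offsets[g.chrom]
                k36[off + g.start // b : off + -(-g.end // b)] = True
        k36 &= ~(k4 | k27)  # structural mutual exclusion
        return {"H3K4me3": k4, "H3K27me3": k27, "H3K36me3": k36}

    def truth_states(self, condition: str, stage: str) -> np.ndarray:
        """Planted four-state code per bin."""
        bins = self.mark_bin_sets(condition, stage)
        return combine_states(bins["H3K4me3"], bins["H3K27me3"])

    def truth_breadth(self, condition: str, stage: str) -> pd.Series:
        """Planted breadth class per gene."""
        widths = self.marks[(condition, stage)]["k4_width"]
        return widths.map(classify_breadth).rename("klass")

    def k4_domains(self, condition: str, stage: str) -> list[Interval]:
        out = []
        for g in self.genes:
            w = int(self.marks[(condition, stage)].loc[g.gene_id, "k4_width"])
            if w > 0:
                lo, hi = self._k4_bins_of(g, w)
                off = self.genome.bin_offsets[g.chrom]
                out.append(Interval(g.chrom, (lo - off) * self.genome.bin_size, (hi - off) * self.genome.bin_size))
        return sorted(out, key=lambda iv: (iv.chrom, iv.start))

    def gene_bodies(self) -> list[Interval]:
        return [Interval(g.chrom, g.start, g.end, g.gene_id) for g in self.genes]


def _draw_class(rng: np.random.Generator, fractions: dict) -> str:
    names = list(fractions)
    return names[rng.choice(len(names), p=[fractions[n] for n in names])]


def _draw_width(rng: np.random.Generator, klass: str, bin_size: int, lo_bins: int | None = None, hi_bins: int | None = None) -> int:
    lo, hi = _CLASS_BIN_RANGES[klass]
    if lo_bins is not None:
        lo, hi = lo_bins, hi_bins
    if hi == 0:
        return 0
    return int(rng.integers(lo, hi + 1)) * bin_size


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSpec, list[GeneModel], TruthSet]:
    """Place genes and plant the full per-gene truth.

    Genes sit at a fixed pitch (>= 12 kb) with the TSS at the slot center
    and alternating strands, so promoters and planted domains of neighboring
    genes never collide. Deterministic given the config seed.
    """
    genome = config.genome
    rng = config.rng(0)
    total = genome.total_length
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        per_chrom = [round(config.n_genes * l / total) for l in genome.chrom_lengths]
        # fix rounding drift on the last chromosome
        per_chrom[-1] = config.n_genes - sum(per_chrom[:-1])
        gi = 0
        for chrom, length, n_c in zip(genome.chrom_names, genome.chrom_lengths, per_chrom):
            if n_c <= 0:
                continue
            pitch = length // n_c
            if pitch < 12_000:
                raise ValueError(f"genome too small: gene pitch {pitch} bp < 12 kb on {chrom}")
            for j in range(n_c):
                center = j * pitch + pitch // 2
                tss = (center // config.bin_size) * config.bin_size
                glen = int(rng.integers(10, 31)) * config.bin_size  # 2-6 kb bodies
                strand = "+" if gi % 2 == 0 else "-"
                if strand == "+":
                    start, end = tss, tss + glen
                else:
                    start, end = tss + 1 - glen, tss + 1
                genes.append(GeneModel(f"g{gi:04d}", chrom, start, end, strand))
                gi += 1
    ids = [g.gene_id for g in genes]
    n = len(ids)

    # --- per-gene baseline truth (NF), then NT/rescue deviations at the focal stage
    stages = list(config.stages)
    klass = pd.DataFrame(index=ids, columns=stages, dtype=object)
    width = pd.DataFrame(0, index=ids, columns=stages, dtype=int)
    for i, gid in enumerate(ids):
        prev_k, prev_w = None, 0
        for s in stages:
            if prev_k is None or rng.random() > config.class_persistence:
                k = _draw_class(rng, config.class_fractions)
                w = _draw_width(rng, k, config.bin_size)
            else:
                k, w = prev_k, prev_w
            klass.at[gid, s], width.at[gid, s] = k, w
            prev_k, prev_w = k, w
    k27 = pd.DataFrame(False, index=ids, columns=stages, dtype=bool)
    for s in stages:
        k27[s] = rng.random(n) < config.k27_fraction
    expressed = pd.Series(rng.random(n) < config.expressed_fraction, index=ids)

    # --- planted NT defect gene sets (disjoint)
    perm = rng.permutation(n)
    n_cat = int(round(config.category_fraction * n))
    n_extra_b = int(round(config.extra_broadened_fraction * n))
    n_extra_k = int(round(config.extra_nt_k27_fraction * n))
    cursor = 0
    sets: dict[str, list[str]] = {}
    for name, count in [
        ("obH3K4me3", n_cat),
        ("usH3K4me3", n_cat),
        ("ueH3K27me3", n_cat),
        ("odH3K27me3", n_cat),
        ("extra_broad", n_extra_b),
        ("extra_k27", n_extra_k),
    ]:
        sets[name] = [ids[j] for j in perm[cursor : cursor + count]]
        cursor += count
    for name in CATEGORY_NAMES:
        for gid in sets[name]:
            expressed[gid] = True  # category genes are expressed in the NF baseline

    focal = config.focal_stage
    nf_width = width.copy()
    nf_k27 = k27.copy()
    nt_width = width.copy()
    nt_k27 = k27.copy()
    for gid in sets["obH3K4me3"]:
        nf_width.at[gid, focal] = _draw_width(rng, "medium", config.bin_size, 7, 14)  # 1.4-2.8 kb
        nt_width.at[gid, focal] = _draw_width(rng, "broad", config.bin_size, 30, 40)  # 6-8 kb
    for gid in sets["usH3K4me3"]:
        nf_width.at[gid, focal] = _draw_width(rng, "medium", config.bin_size, 7, 14)
        nt_width.at[gid, focal] = _draw_width(rng, "narrow", config.bin_size, 2, 4)
    for gid in sets["extra_broad"]:
        nf_width.at[gid, focal] = _draw_width(rng, "medium", config.bin_size, 7, 14)
        nt_width.at[gid, focal] = _draw_width(rng, "broad", config.bin_size, 30, 40)
    for gid in sets["ueH3K27me3"]:
        nf_k27.at[gid, focal] = False
        nt_k27.at[gid, focal] = True
    for gid in sets["odH3K27me3"]:
        nf_k27.at[gid, focal] = True
        nt_k27.at[gid, focal] = False
    for gid in sets["extra_k27"]:
        nf_k27.at[gid, focal] = False
        nt_k27.at[gid, focal] = True

    nf_k36 = pd.DataFrame({s: expressed for s in stages})
    nt_k36 = nf_k36.copy()
    lost = expressed & (rng.random(n) < config.nt_k36_loss)
    nt_k36[focal] = expressed & ~lost

    marks: dict[tuple[str, str], pd.DataFrame] = {}
    for s in stages:
        marks[("NF", s)] = pd.DataFrame({"k4_width": nf_width[s], "k27": nf_k27[s], "k36": nf_k36[s]})
        marks[("NT", s)] = pd.DataFrame({"k4_width": nt_width[s], "k27": nt_k27[s], "k36": nt_k36[s]})
        # the rescue condition is NT-like except at the focal stage, where all
        # three marks revert to the NF configuration
        src = "NF" if s == focal else "NT"
        marks[("Setd2OE", s)] = marks[(src, s)].copy()

    log2fc = pd.Series(0.0, index=ids)
    category = pd.Series("none", index=ids, dtype=object)
    for name in CATEGORY_NAMES:
        for gid in sets[name]:
            category[gid] = name
            log2fc[gid] = config.planted_log2fc if name in ("obH3K4me3", "odH3K27me3") else -config.planted_log2fc
    expression = pd.DataFrame({"category": category, "log2fc": log2fc, "expressed": expressed})
    expression["extra_broadened"] = expression.index.isin(sets["extra_broad"])
    expression["extra_nt_k27"] = expression.index.isin(sets["extra_k27"])

    truth = TruthSet(config=config, genome=genome, genes=genes, marks=marks, expression=expression)
    return genome, genes, truth


def simulate_tracks(
    config: SimulationConfig,
    truth: TruthSet,
    conditions: tuple[str, ...] | None = None,
    stages: tuple[str, ...] | None = None,
    marks: tuple[str, ...] = ("H3K4me3", "H3K27me3", "H3K36me3"),
    noise_rep: int = 0,
) -> dict[tuple[str, str, str], BinnedTrack]:
    """Poisson ChIP/input count tracks for every (mark, stage, condition).

    chip ~ Poisson(background * enrichment) inside planted domains and
    Poisson(background) outside; input ~ Poisson(background) everywhere.
    ``noise_rep`` selects an independent noise stream with identical truth.
    """
    rng = config.rng(1, noise_rep)
    genome = truth.genome
    n = genome.total_bins
    out: dict[tuple[str, str, str], BinnedTrack] = {}
    for condition in conditions or config.conditions:
        for stage in stages or config.stages:
            bins = truth.mark_bin_sets(condition, stage)
            for mark in marks:
                enr = config.enrichment[mark]
                lam = np.where(bins[mark], config.background * enr, config.background)
                out[(mark, stage, condition)] = BinnedTrack(
                    genome=genome,
                    mark=mark,
                    stage=stage,
                    condition=condition,
                    chip_counts=rng.poisson(lam, size=n),
                    input_counts=rng.poisson(config.background, size=n),
                )
    return out


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson as dispersion -> 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_null_expression(
    config: SimulationConfig,
    n_genes: int = 2000,
    noise_rep: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two same-mean NB count matrices (planted fold change 1 everywhere),
    for type-I-error calibration of the differential-expression test."""
    rng = config.rng(3, noise_rep)
    ids = pd.Index([f"null{i:05d}" for i in range(n_genes)], name="gene_id")
    mu = np.full(n_genes, config.base_mean)
    mats = []
    for label in ("A", "B"):
        cols = {f"{label}_rep{r}": _nb_sample(rng, mu, config.dispersion) for r in range(1, config.n_replicates + 1)}
        mats.append(pd.DataFrame(cols, index=ids))
    return mats[0], mats[1]


def planted_cluster_profiles(
    n_genes: int = 300,
    n_samples: int = 6,
    k: int = 3,
    seed: int = 0,
    separation: float = 3.0,
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Well-separated gene-profile matrix with known cluster labels.

    Each cluster's archetype profile is a distinct +/- separation pattern
    over samples; genes get the archetype plus N(0, noise_sd) noise. Used to
    verify that profile clustering recovers a clean planted partition.
    """
    rng = np.random.default_rng(seed)
    archetypes = np.zeros((k, n_samples))
    for c in range(k):
        archetypes[c] = separation * np.cos(np.pi * (np.arange(n_samples) + 1) * (c + 1) / n_samples)
    labels = np.repeat(np.arange(k), -(-n_genes // k))[:n_genes]
    mat = archetypes[labels] + rng.normal(0, noise_sd, size=(n_genes, n_samples))
    idx = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    df = pd.DataFrame(mat, index=idx, columns=[f"s{j}" for j in range(n_samples)])
    return df, pd.Series(labels, index=idx, name="cluster")


def simulate_expression(config: SimulationConfig, truth: TruthSet, noise_rep: int = 0) -> pd.DataFrame:
    """Replicated NB counts at the focal stage for NF, NT, and the rescue.

    NT means are base_mean * 2**planted_log2FC; the rescue condition reverts
    to NF means. Columns are '<condition>_rep<i>'.
    """
    rng = config.rng(2, noise_rep)
    ids = truth.gene_ids
    expressed = truth.expression["expressed"].to_numpy(dtype=bool)
    base = np.where(expressed, config.base_mean, config.low_expr_mean)
    fc = truth.expression["log2fc"].to_numpy()
    means = {"NF": base, "NT": base * 2.0**fc, "Setd2OE": base}
    cols: dict[str, np.ndarray] = {}
    for condition in config.conditions:
        mu = means.get(condition, base)
        for r in range(1, config.n_replicates + 1):
            cols[f"{condition}_rep{r}"] = _nb_sample(rng, mu, config.dispersion)
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
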