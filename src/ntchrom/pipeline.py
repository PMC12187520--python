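"""End-to-end pipeline: simulate (or ingest) -> enrichment -> four-state
segmentation -> domain breadth -> gene states -> expression integration ->
exclusivity -> summary, with every threshold echoed into the output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import breadth as breadth_mod
from . import expression as expr_mod
from . import genestate, io, recovery
from .exclusivity import compute_exclusivity
from .genome import Interval
from .signal import fold_enrichment, log2_rpkm_enrichment
from .simulate import SimulationConfig, TruthSet, simulate_expression, simulate_genome, simulate_tracks
from .states import STATE_NAMES, binarize_mark, bins_to_intervals, call_mark_domains, combine_states, segments_from_bins

log = logging.getLogger("ntchrom")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds in one place, serialized into every run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fe_thresholds: dict = field(
        default_factory=lambda: {"H3K4me3": 4.0, "H3K27me3": 2.0, "H3K36me3": 2.0}
    )
    pseudocount: float = 1.0
    min_overlap: int = 200
    promoter_halfwidth: int = 2000
    merge_gap: int = 5000
    k4_bridge_gap: int = 400  # close sub-bin dropouts inside H3K4me3 domains
    fc_cut: float = 2.0
    padj_cut: float = 0.01
    enrich_delta: float = 1.0
    kmeans_k: int = 3
    kmeans_restarts: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    truth: TruthSet
    segmentations: dict  # (condition, stage) -> StateSegmentation
    breadth: dict  # (condition, stage) -> DataFrame
    de: pd.DataFrame
    categories: pd.DataFrame  # per-gene combined call + arms
    exclusivity: dict  # mark -> ExclusivityResult
    summary: dict


def _segmentations(cfg: RunConfig, truth: TruthSet, tracks: dict) -> dict:
    segs = {}
    binarized = {}
    for (mark, stage, condition), track in tracks.items():
        fe = fold_enrichment(track, cfg.pseudocount)
        binarized[(mark, stage, condition)] = binarize_mark(fe, cfg.fe_thresholds[mark])
    for condition in cfg.sim.conditions:
        for stage in cfg.sim.stages:
            k4 = binarized[("H3K4me3", stage, condition)]
            k27 = binarized[("H3K27me3", stage, condition)]
            segs[(condition, stage)] = segments_from_bins(
                combine_states(k4, k27), truth.genome, stage=stage, condition=condition
            )
    return segs, binarized


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    sim = cfg.sim
    log.info("simulating genome: %d genes on %s", sim.n_genes, dict(zip(sim.chrom_names, sim.chrom_lengths)))
    genome, genes, truth = simulate_genome(sim)
    tracks = simulate_tracks(sim, truth)
    log.info("binarizing %d tracks at FE thresholds %s", len(tracks), cfg.fe_thresholds)
    segs, binarized = _segmentations(cfg, truth, tracks)

    focal = sim.focal_stage
    # --- domain breadth per condition/stage and NT stage-to-stage dynamics
    breadth = {
        (condition, stage): breadth_mod.breadth_table(
            genes, segs[(condition, stage)], stage, condition, cfg.promoter_halfwidth, cfg.k4_bridge_gap
        )
        for condition in sim.conditions
        for stage in sim.stages
    }

    # --- gene-level chromatin states (NF and NT across stages)
    tables = {
        condition: genestate.gene_state_table(
            genes, {s: segs[(condition, s)] for s in sim.stages}, cfg.min_overlap, cfg.promoter_halfwidth
        )
        for condition in ("NF", "NT")
    }
    transitions = genestate.bin_state_transitions([segs[("NT", s)] for s in sim.stages], list(sim.stages))

    # --- expression integration at the focal stage
    counts = simulate_expression(sim, truth)
    nt_cols = [c for c in counts.columns if c.startswith("NT_")]
    nf_cols = [c for c in counts.columns if c.startswith("NF_")]
    de = expr_mod.differential_expression(counts[nt_cols], counts[nf_cols])

    k4_calls = expr_mod.call_h3k4me3_categories(
        de,
        breadth[("NT", focal)]["width"],
        breadth[("NF", focal)]["width"],
        cfg.fc_cut,
        cfg.padj_cut,
    )
    promoters = {g.gene_id: Interval(g.chrom, *g.promoter(cfg.promoter_halfwidth)) for g in genes}
    k27_enrich = {}
    for condition in ("NT", "NF"):
        track = tracks[("H3K27me3", focal, condition)]
        k27_enrich[condition] = pd.Series(
            {gid: log2_rpkm_enrichment(track, p, cfg.pseudocount) for gid, p in promoters.items()}
        )
    k27_calls = expr_mod.call_h3k27me3_categories(
        de, k27_enrich["NT"], k27_enrich["NF"], cfg.fc_cut, cfg.padj_cut, cfg.enrich_delta
    )
    combined = recovery.combine_category_calls(k4_calls, k27_calls)
    categories = pd.DataFrame(
        {
            "category": combined,
            "log2fc": de["log2fc"],
            "p_adj": de["p_adj"],
            "width_delta": k4_calls["width_delta"],
            "k27_delta": k27_calls["k27_delta"],
        }
    )

    # --- H3K36me3: coverage, expression correlation, clustering, exclusivity
    bodies = truth.gene_bodies()
    k36_domains = {
        condition: call_mark_domains(binarized[("H3K36me3", focal, condition)], genome, cfg.merge_gap)
        for condition in sim.conditions
    }
    coverage = {
        condition: expr_mod.genebody_coverage_fraction(doms, bodies) for condition, doms in k36_domains.items()
    }
    k36_enrich = pd.DataFrame(
        {
            condition: [
                log2_rpkm_enrichment(tracks[("H3K36me3", focal, condition)], Interval(g.chrom, g.start, g.end), cfg.pseudocount)
                for g in genes
            ]
            for condition in sim.conditions
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    _, norm = expr_mod.normalize_counts(counts)
    expr_nf = np.log2(norm[nf_cols].mean(axis=1) + 1.0)
    k36_expr_r = expr_mod.genebody_expression_correlation(k36_enrich["NF"], expr_nf)
    clusters = expr_mod.kmeans_genebody_clusters(k36_enrich, cfg.kmeans_k, sim.seed, cfg.kmeans_restarts)

    excl = {}
    for mark in ("H3K4me3", "H3K27me3"):
        mark_domains = bins_to_intervals(binarized[(mark, focal, "NT")], genome)
        excl[mark] = compute_exclusivity(mark_domains, k36_domains["NT"])

    # --- gain/loss and condition-specific H3K27me3 marking
    k27_marked = tables["NT"]["k27_marked"]
    gain_loss = {}
    for prev, curr in zip(sim.stages[:-1], sim.stages[1:]):
        gain_loss[f"{prev}->{curr}"] = genestate.gain_loss_percentages(k27_marked[prev], k27_marked[curr])
    nt_set = set(k27_marked.index[k27_marked[focal]])
    nf_set = set(tables["NF"]["k27_marked"].index[tables["NF"]["k27_marked"][focal]])
    nt_specific, nt_overlap = genestate.condition_specific_fraction(nt_set, nf_set)

    # --- recovery against the planted truth
    rec = {
        "bin_state_accuracy": recovery.bin_state_accuracy(
            segs[("NT", focal)].states, truth.truth_states("NT", focal)
        ),
        "breadth_accuracy": recovery.breadth_accuracy(
            breadth[("NT", focal)]["klass"], truth.truth_breadth("NT", focal)
        ),
        **recovery.category_performance(combined, truth.expression["category"]),
    }

    state_counts = {
        f"{condition}_{stage}": {
            STATE_NAMES[i]: int(c)
            for i, c in enumerate(np.bincount(segs[(condition, stage)].states, minlength=4))
        }
        for condition in sim.conditions
        for stage in sim.stages
    }
    summary = {
        "config": cfg.to_dict(),
        "n_genes": len(genes),
        "state_bin_counts": state_counts,
        "category_counts": combined.value_counts().to_dict(),
        "mean_log10_breadth": {
            f"{c}_{s}": breadth_mod.mean_log_breadth(breadth[(c, s)]) for c in sim.conditions for s in sim.stages
        },
        "k27_gain_loss_pct": {k: {"gain": g, "loss": l} for k, (g, l) in gain_loss.items()},
        "nt_specific_k27_fraction": nt_specific,
        "nt_k27_overlap_nf_fraction": nt_overlap,
        "k36_genebody_coverage": coverage,
        "k36_expression_pearson_r": k36_expr_r,
        "k36_cluster_sizes": clusters.value_counts().sort_index().to_dict(),
        "mutually_exclusive_index": {
            mark: {"n_a": r.n_a, "n_b": r.n_b, "n_total": r.n_total, "n_bi": r.n_bi, "b_r": r.b_r, "m_s": r.m_s}
            for mark, r in excl.items()
        },
        "recovery": rec,
    }

    result = PipelineResult(
        config=cfg,
        truth=truth,
        segmentations=segs,
        breadth=breadth,
        de=de,
        categories=categories,
        exclusivity=excl,
        summary=summary,
    )
    if outdir is not None:
        _write_outputs(result, genes, counts, transitions, Path(outdir))
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, float) and not np.isfinite(o):
        return str(o)
    if isinstance(o, (tuple, set)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def dump_summary(summary: dict, path: str | Path) -> None:
    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, float) and not np.isfinite(x):
            return "inf" if x > 0 else ("-inf" if x < 0 else "nan")
        return x

    with open(path, "w") as fh:
        json.dump(clean(summary), fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _write_outputs(result: PipelineResult, genes, counts, transitions, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.config.sim
    dump_summary(result.summary["config"], outdir / "config.json")
    io.write_gene_models(genes, outdir / "gene_models.tsv")
    counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
    result.truth.expression.to_csv(outdir / "truth_genes.tsv", sep="\t")
    for (condition, stage), seg in result.segmentations.items():
        io.write_segmentation(seg, outdir / f"segmentation_{condition}_{stage}.bed")
    breadth_all = pd.concat(result.breadth.values())
    breadth_all.to_csv(outdir / "breadth.tsv", sep="\t")
    result.de.to_csv(outdir / "differential_expression.tsv", sep="\t")
    result.categories.to_csv(outdir / "categories.tsv", sep="\t")
    for j, pair in enumerate(transitions.pair_counts):
        pd.DataFrame(pair, index=STATE_NAMES, columns=STATE_NAMES).to_csv(
            outdir / f"bin_transitions_{transitions.stages[j]}_to_{transitions.stages[j + 1]}.tsv", sep="\t"
        )
    dump_summary(result.summary, outdir / "summary.json")
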