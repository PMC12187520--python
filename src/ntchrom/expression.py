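"""Expression-side analysis: count normalization, a differential-expression
test, joint expression x epigenome gene categories, coverage/correlation
summaries, and k-means clustering of gene-body enrichment.

The DE test is a deliberately simple, documented procedure — median-of-ratios
size factors, Welch's t on log2(normalized + 1), Benjamini–Hochberg
adjustment — supplying the (log2FC, adjusted p) pair that the category
definitions consume. Categories pair an expression change in the
nuclear-transfer (NT) condition against the fertilized (NF) control with the
matching promoter-epigenome change:

* obH3K4me3 — over-expressed with broadened promoter H3K4me3 domain;
* usH3K4me3 — under-expressed with shortened promoter H3K4me3 domain;
* ueH3K27me3 — under-expressed with enriched promoter H3K27me3;
* odH3K27me3 — over-expressed with deficient promoter H3K27me3.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-exported for callers)
from statsmodels.stats.multitest import multipletests

from .genome import Interval

CATEGORIES = ("obH3K4me3", "usH3K4me3", "ueH3K27me3", "odH3K27me3", "none")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The size factor of a sample is the median, over genes with nonzero
    counts in every sample, of that sample's count divided by the gene's
    geometric mean across samples. Falls back to total-count scaling (with a
    warning) when no gene is nonzero everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        log_geo = np.mean(np.log(mat[all_nonzero]), axis=1, keepdims=True)
        ratios = mat[all_nonzero] / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn("no gene with nonzero counts in all samples; using total-count scaling", stacklevel=2)
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return sf, counts / factors


def differential_expression(counts_a: pd.DataFrame, counts_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene DE of condition A over condition B.

    Joint median-of-ratios normalization, log2FC of normalized means with a
    pseudocount of 1, Welch's t-test on log2(normalized + 1), and BH
    adjustment across genes. Returns base_mean, log2fc, p_value, p_adj.
    Genes with identical values in both groups get p = 1.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices index different genes")
    joint = pd.concat([counts_a, counts_b], axis=1)
    _, norm = normalize_counts(joint)
    na = counts_a.shape[1]
    norm_a, norm_b = norm.iloc[:, :na], norm.iloc[:, na:]
    mean_a, mean_b = norm_a.mean(axis=1), norm_b.mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    la, lb = np.log2(norm_a + 1.0), np.log2(norm_b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p_value": p,
            "p_adj": p_adj,
        },
        index=counts_a.index,
    )


def _width_series(widths: pd.Series, index: pd.Index, label: str) -> pd.Series:
    out = widths.reindex(index)
    if out.isna().any():
        warnings.warn(f"{int(out.isna().sum())} genes missing {label}; treated as 0", stacklevel=3)
        out = out.fillna(0.0)
    return out


def call_h3k4me3_categories(
    de: pd.DataFrame,
    width_nt: pd.Series,
    width_nf: pd.Series,
    fc_cut: float = 2.0,
    padj_cut: float = 0.01,
) -> pd.DataFrame:
    """obH3K4me3 / usH3K4me3 calls from DE (NT over NF) plus promoter
    H3K4me3 domain widths in each condition.

    ob: log2FC > fc_cut, p_adj < padj_cut, width_NT > width_NF;
    us: log2FC < -fc_cut, p_adj < padj_cut, width_NT < width_NF.
    All inequalities strict; ob and us are mutually exclusive by sign.
    """
    wnt = _width_series(width_nt, de.index, "NT width")
    wnf = _width_series(width_nf, de.index, "NF width")
    sig = de["p_adj"] < padj_cut
    ob = (de["log2fc"] > fc_cut) & sig & (wnt > wnf)
    us = (de["log2fc"] < -fc_cut) & sig & (wnt < wnf)
    category = pd.Series("none", index=de.index, dtype=object)
    category[ob] = "obH3K4me3"
    category[us] = "usH3K4me3"
    return pd.DataFrame(
        {"category": category, "log2fc": de["log2fc"], "p_adj": de["p_adj"], "width_delta": wnt - wnf}
    )


def call_h3k27me3_categories(
    de: pd.DataFrame,
    k27_nt: pd.Series,
    k27_nf: pd.Series,
    fc_cut: float = 2.0,
    padj_cut: float = 0.01,
    enrich_delta: float = 1.0,
) -> pd.DataFrame:
    """ueH3K27me3 / odH3K27me3 calls from DE (NT over NF) plus promoter
    H3K27me3 log2 RPKM enrichment in each condition.

    ue: log2FC < -fc_cut, p_adj < padj_cut, (k27_NT - k27_NF) > enrich_delta;
    od: log2FC > fc_cut, p_adj < padj_cut, (k27_NF - k27_NT) > enrich_delta.
    """
    knt = _width_series(k27_nt, de.index, "NT H3K27me3 enrichment")
    knf = _width_series(k27_nf, de.index, "NF H3K27me3 enrichment")
    sig = de["p_adj"] < padj_cut
    delta = knt - knf
    ue = (de["log2fc"] < -fc_cut) & sig & (delta > enrich_delta)
    od = (de["log2fc"] > fc_cut) & sig & (-delta > enrich_delta)
    category = pd.Series("none", index=de.index, dtype=object)
    category[ue] = "ueH3K27me3"
    category[od] = "odH3K27me3"
    return pd.DataFrame(
        {"category": category, "log2fc": de["log2fc"], "p_adj": de["p_adj"], "k27_delta": delta}
    )


def gene_set_overlap(set_a: set, set_b: set) -> tuple[int, int, int, float]:
    """(|A|, |B|, |A n B|, percent of A in B rounded to 2 decimals)."""
    if not set_a:
        raise ValueError("set A is empty")
    n_int = len(set_a & set_b)
    pct = round(100.0 * n_int / len(set_a), 2)
    return len(set_a), len(set_b), n_int, pct


def _union_bp_masks(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    from .genome import iter_by_chrom

    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in iter_by_chrom(intervals):
        merged: list[tuple[int, int]] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
            else:
                merged.append((iv.start, iv.end))
        out[chrom] = merged
    return out


def genebody_coverage_fraction(domains: list[Interval], gene_bodies: list[Interval]) -> float:
    """Fraction of the gene-body union covered by the domain union."""
    if not gene_bodies:
        raise ValueError("no gene bodies")
    dom = _union_bp_masks(domains)
    bodies = _union_bp_masks(gene_bodies)
    total = 0
    covered = 0
    for chrom, ivs in bodies.items():
        dlist = dom.get(chrom, [])
        for s, e in ivs:
            total += e - s
            for ds, de_ in dlist:
                covered += max(0, min(e, de_) - max(s, ds))
    return covered / total


def genebody_expression_correlation(k36_signal: pd.Series, expression: pd.Series) -> float:
    """Pearson r between gene-body H3K36me3 enrichment and expression.

    NaN when either vector has zero variance.
    """
    if len(k36_signal) < 3:
        raise ValueError("need >= 3 genes")
    x = k36_signal.to_numpy(dtype=float)
    y = expression.reindex(k36_signal.index).to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def kmeans_genebody_clusters(
    enrichment: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
) -> pd.Series:
    """k-means cluster labels for genes by gene-body enrichment profile.

    Rows are z-scored per gene before Lloyd's algorithm (Euclidean, best of
    ``restarts`` seeded initializations by within-cluster sum of squares).
    Labels are relabeled by descending cluster mean in the first sample
    column so identical inputs always yield identical labels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(enrichment):
        raise ValueError("k exceeds number of genes")
    mat = enrichment.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(z)
    order = np.argsort(-np.array([z[raw == c, 0].mean() if (raw == c).any() else -np.inf for c in range(k)]))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return pd.Series(relabel[raw], index=enrichment.index, name="cluster")


def group_expression_test(gene_set: set, expr_a: pd.Series, expr_b: pd.Series) -> tuple[float, float, float]:
    """(mean A, mean B, p) for a gene set's expression in two conditions.

    Two-tailed unpaired Student's t-test on the per-gene expression
    summaries (log2 of normalized expression). Identical vectors give p = 1.
    """
    genes = sorted(gene_set & set(expr_a.index) & set(expr_b.index))
    if len(genes) < 2:
        raise ValueError("gene set too small for a t-test")
    a = expr_a.loc[genes].to_numpy(dtype=float)
    b = expr_b.loc[genes].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):
        p = 1.0
    return float(a.mean()), float(b.mean()), float(p)
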