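"""Recovery metrics: how well the pipeline's calls match a planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd


def bin_state_accuracy(called: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of bins whose called four-state code equals the planted one."""
    called = np.asarray(called)
    truth = np.asarray(truth)
    if called.shape != truth.shape:
        raise ValueError("state vectors differ in length")
    return float(np.mean(called == truth))


def breadth_accuracy(called: pd.Series, truth: pd.Series) -> float:
    """Fraction of genes whose called breadth class equals the planted one."""
    if set(called.index) != set(truth.index):
        raise ValueError("gene universes differ")
    return float((called == truth.reindex(called.index)).mean())


def combine_category_calls(k4_calls: pd.DataFrame, k27_calls: pd.DataFrame) -> pd.Series:
    """One category per gene from the H3K4me3 and H3K27me3 call tables.

    The two rule families are disjoint for any one gene in practice (their
    expression arms have opposite signs between ob/ue and us/od, and the
    epigenome arms require opposite-sign deltas between ob/od and us/ue);
    when both fire, the H3K4me3 call wins.
    """
    out = k4_calls["category"].copy()
    k27 = k27_calls["category"].reindex(out.index)
    out[out == "none"] = k27[out == "none"]
    return out


def category_performance(called: pd.Series, truth: pd.Series) -> dict[str, float]:
    """Sensitivity and FDR of planted-category recovery.

    A planted gene counts as recovered only when the called category matches
    exactly; a call is false when the gene's planted category differs
    (including planted 'none').
    """
    truth = truth.reindex(called.index)
    planted = truth != "none"
    called_pos = called != "none"
    tp = int(((called == truth) & planted).sum())
    sens = tp / int(planted.sum()) if planted.any() else float("nan")
    n_called = int(called_pos.sum())
    fdr = float(((called != truth) & called_pos).sum()) / n_called if n_called else 0.0
    return {
        "sensitivity": float(sens),
        "fdr": float(fdr),
        "n_planted": int(planted.sum()),
        "n_called": n_called,
        "n_true_positive": tp,
    }
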