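"""Reduction-in-variance (RV) gene scoring.

For each gene the between-class variance of class-mean log2 expression is
computed independently at mid-véraison (V) and post-véraison (PostV); the
ratio var_V / var_PostV is the RV fold.  A gene with high RV had distinct
class expression at V that converged by PostV — the signature of ripening
synchronization.  Significance is assessed with a one-sided F test on the
variance ratio (BH FDR, default threshold 0.2).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr


def between_class_variance(
    matrix: pd.DataFrame, meta: pd.DataFrame, stage: str, tissue: str
) -> pd.Series:
    """Per-gene sample variance (ddof=1) of the k class-mean expressions."""
    sel = meta[(meta["stage"] == stage) & (meta["tissue"] == tissue)]
    classes = sorted(sel["class"].unique())
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes in {tissue}/{stage}")
    class_means = []
    for cls in classes:
        cols = sel.loc[sel["class"] == cls, "sample_id"].to_list()
        if not cols:
            raise ValueError(f"class {cls} has no samples in {tissue}/{stage}")
        class_means.append(matrix[cols].to_numpy().mean(axis=1))
    cm = np.stack(class_means)  # k x genes
    return pd.Series(cm.var(axis=0, ddof=1), index=matrix.index, name="var")


def rv_score(var_v, var_postv):
    """RV fold = var_V / var_PostV, with degenerate cases flagged.

    Returns a frame with ``rv_fold`` (inf when var_PostV == 0 < var_V, NaN
    for 0/0) and a boolean ``flagged`` column.
    """
    var_v = np.asarray(var_v, dtype=float)
    var_postv = np.asarray(var_postv, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = var_v / var_postv
    fold = np.where((var_postv == 0) & (var_v > 0), np.inf, fold)
    fold = np.where((var_postv == 0) & (var_v == 0), np.nan, fold)
    flagged = ~np.isfinite(fold)
    return pd.DataFrame({"rv_fold": fold, "flagged": flagged})


def rv_records(
    matrix: pd.DataFrame, meta: pd.DataFrame, tissue: str,
    gene_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble per-gene RV records for one tissue."""
    var_v = between_class_variance(matrix, meta, "V", tissue)
    var_postv = between_class_variance(matrix, meta, "PostV", tissue)
    if gene_universe is not None:
        var_v = var_v.loc[list(gene_universe)]
        var_postv = var_postv.loc[list(gene_universe)]
    score = rv_score(var_v.to_numpy(), var_postv.to_numpy())
    return pd.DataFrame(
        {
            "gene": var_v.index,
            "tissue": tissue,
            "var_v": var_v.to_numpy(),
            "var_postv": var_postv.to_numpy(),
            "rv_fold": score["rv_fold"].to_numpy(),
            "flagged": score["flagged"].to_numpy(),
        }
    ).reset_index(drop=True)


def rv_ftest(
    records: pd.DataFrame, df1: int = 2, df2: int = 2, alpha: float = 0.2
) -> pd.DataFrame:
    """One-sided F test of variance reduction per gene.

    ``p = P(F(df1, df2) > rv_fold)``; BH adjustment across finite-fold
    genes; significant if q < alpha.  Default df (2, 2) follow from the
    three-class-mean variance definition.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    out = records.copy()
    finite = np.isfinite(out["rv_fold"].to_numpy())
    p = np.full(len(out), np.nan)
    p[finite] = stats.f.sf(out.loc[finite, "rv_fold"].to_numpy(), df1, df2)
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite] = bh_fdr(p[finite])
    out["p"] = p
    out["q"] = q
    out["significant"] = (q < alpha) & finite
    return out


def rv_distribution_summary(records: pd.DataFrame) -> dict:
    """Summary of the RV fold distribution.

    Mean/median/quantiles over finite folds; fractions in the fold bins
    <=10, 10-20, >20 and <=100; infinite/undefined folds counted apart.
    """
    fold = records["rv_fold"].to_numpy()
    finite = fold[np.isfinite(fold)]
    n = finite.size
    if n == 0:
        # fully degenerate (e.g. exact synchronization): every fold infinite
        return {
            "n_finite": 0,
            "n_infinite": int(np.sum(np.isinf(fold))),
            "n_undefined": int(np.sum(np.isnan(fold))),
            "mean": float("nan"), "median": float("nan"),
            "q25": float("nan"), "q75": float("nan"),
            "frac_le_10": float("nan"), "frac_10_20": float("nan"),
            "frac_gt_20": float("nan"), "frac_le_100": float("nan"),
        }
    return {
        "n_finite": int(n),
        "n_infinite": int(np.sum(np.isinf(fold))),
        "n_undefined": int(np.sum(np.isnan(fold))),
        "mean": float(np.mean(finite)),
        "median": float(np.median(finite)),
        "q25": float(np.quantile(finite, 0.25)),
        "q75": float(np.quantile(finite, 0.75)),
        "frac_le_10": float(np.mean(finite <= 10)),
        "frac_10_20": float(np.mean((finite > 10) & (finite <= 20))),
        "frac_gt_20": float(np.mean(finite > 20)),
        "frac_le_100": float(np.mean(finite <= 100)),
    }


def rank_overlap(
    score_a: pd.Series, score_b: pd.Series, n: int
) -> float:
    """Fraction of shared genes among the top-n of two rankings.

    Scores are ranked descending; ties broken by gene id for stability.
    """
    if not score_a.index.equals(score_b.index):
        score_b = score_b.reindex(score_a.index)
        if score_b.isna().any():
            raise ValueError("scores must cover the same gene universe")
    if n > len(score_a):
        raise ValueError("n exceeds the gene universe size")

    def top(s: pd.Series) -> set:
        order = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
        return {g for g, _ in order[:n]}

    return len(top(score_a) & top(score_b)) / n
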