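"""Moderated paired differential expression between berry classes.

Per gene, paired (by replicate plant) log2 differences between two classes
within one tissue-stage block are tested with an empirical-Bayes moderated
t statistic: per-gene sample variances are shrunk towards a pooled prior
(s0^2 with d0 prior degrees of freedom, both estimated across genes by
method of moments on log variances), and the moderated t is referred to a
t distribution with d0 + d degrees of freedom.  With d0 = 0 the statistic
reduces exactly to the ordinary paired t.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


class ShrinkageEstimate(NamedTuple):
    prior_df: float      # d0; may be inf (complete shrinkage)
    prior_var: float     # s0^2


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log-stable start)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_shrinkage(s2: np.ndarray, df: int) -> ShrinkageEstimate:
    """Method-of-moments fit of the scaled-F variance prior on log s^2.

    Matches mean and variance of ``log(s2)`` to the model
    ``s2 ~ s0^2 * F(df, d0)``; genes with zero variance are excluded from
    the moment fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need >= 2 genes with positive variance to fit prior")
    z = np.log(pos)
    e_known = special.digamma(df / 2.0) - np.log(df / 2.0)
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        log_s0 = float(np.mean(z)) - e_known
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            float(np.mean(z))
            - e_known
            + float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return ShrinkageEstimate(prior_df=float(d0), prior_var=float(np.exp(log_s0)))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _paired_differences(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pair: tuple[str, str],
    tissue: str,
    stage: str,
) -> np.ndarray:
    """genes x replicates array of within-pair differences (first - second)."""
    cols = {}
    for cls in pair:
        sel = meta[
            (meta["class"] == cls)
            & (meta["tissue"] == tissue)
            & (meta["stage"] == stage)
        ]
        if sel.empty:
            raise ValueError(f"no samples for class {cls} in {tissue}/{stage}")
        cols[cls] = sel.set_index("replicate")["sample_id"]
    reps = sorted(set(cols[pair[0]].index) & set(cols[pair[1]].index))
    if len(reps) < 2:
        raise ValueError("need >= 2 complete replicate pairs")
    d = (
        matrix[cols[pair[0]].loc[reps].to_list()].to_numpy()
        - matrix[cols[pair[1]].loc[reps].to_list()].to_numpy()
    )
    return d


def moderated_paired_ttest(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pair: tuple[str, str],
    tissue: str,
    stage: str,
    moderate: bool = True,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated paired t-test per gene for one class pair in a block.

    Returns columns ``gene, pair, tissue, stage, log2fc, t_mod, df_total,
    p, q`` with BH adjustment within this (tissue, stage, pair) family.
    ``prior_df=0`` (or ``moderate=False``) gives the ordinary paired t.
    """
    d = _paired_differences(matrix, meta, pair, tissue, stage)
    n = d.shape[1]
    df = n - 1
    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)

    if not moderate:
        prior_df = 0.0
    if prior_df is None and np.count_nonzero(s2 > 0) < 2:
        # fully degenerate block (no variance anywhere): nothing to fit
        est = ShrinkageEstimate(np.inf, 0.0)
    elif prior_df is None:
        est = estimate_shrinkage(s2, df)
    else:
        if prior_df == 0:
            est = ShrinkageEstimate(0.0, 0.0)
        else:
            est = ShrinkageEstimate(float(prior_df),
                                    estimate_shrinkage(s2, df).prior_var)

    d0, s0 = est.prior_df, est.prior_var
    if np.isinf(d0):
        var_post = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        var_post = s2.copy()
        df_total = float(df)
    else:
        var_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    # zero-variance genes: fall back to the pooled prior rather than an
    # infinite statistic
    zero = var_post <= 0
    if np.any(zero):
        fallback = s0 if s0 > 0 else float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
        var_post = np.where(zero, fallback, var_post)

    se = np.sqrt(var_post / n)
    t_mod = np.where(mean_d == 0, 0.0, mean_d / se)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "pair": f"{pair[0]}-{pair[1]}",
            "tissue": tissue,
            "stage": stage,
            "log2fc": mean_d,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": bh_fdr(p),
        }
    )


CLASS_PAIRS = (("GS", "PS"), ("PS", "RS"), ("GS", "RS"))


def degenes_union(
    results: Sequence[pd.DataFrame], alpha: float = 0.05
) -> list[str]:
    """Union of genes significant (q < alpha) in any class-pair result."""
    genes: set[str] = set()
    for res in results:
        genes.update(res.loc[res["q"] < alpha, "gene"])
    return sorted(genes)


def dge_block(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    stage: str,
    alpha: float = 0.05,
    moderate: bool = True,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """All three class-pair tests for one tissue-stage block + DE union."""
    results = {
        f"{a}-{b}": moderated_paired_ttest(
            matrix, meta, (a, b), tissue, stage, moderate=moderate
        )
        for a, b in CLASS_PAIRS
    }
    union = degenes_union(list(results.values()), alpha=alpha)
    return results, union
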