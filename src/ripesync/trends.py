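"""V -> PostV expression-trend classification.

Each gene is classified relative to the véraison RS state: "up" or "down"
if the mean PostV expression (pooled across classes by default) differs
significantly from the véraison RS mean (pooled-variance two-sided t, BH
FDR), "plateau" otherwise.  A plateau gene completed its ripening-related
expression change by the RS stage, placing its synchronization in the
early post-véraison window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

TREND_LABELS = ("up", "down", "plateau")


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pooled-variance two-sample t per gene (rows)."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    s1 = x.var(axis=1, ddof=1)
    s2 = y.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    est = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    t = np.where(est == 0, 0.0, t)
    inf_signed = np.where(est > 0, np.inf, np.where(est < 0, -np.inf, 0.0))
    t = np.where(np.isfinite(t), t, inf_signed)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where(est == 0, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    return est, t, p


def trend_call(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    alpha: float = 0.05,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene trend label for one tissue.

    ``mode="pooled"`` contrasts the mean of all PostV samples against the
    véraison RS samples; ``mode="per_class"`` returns one call set per
    PostV class contrasted against véraison RS (frames concatenated with a
    ``postv_class`` column).
    """
    sel = meta[meta["tissue"] == tissue]
    rs_v_cols = sel[(sel["stage"] == "V") & (sel["class"] == "RS")][
        "sample_id"
    ].to_list()
    if not rs_v_cols:
        raise ValueError(f"no véraison RS samples in tissue {tissue}")
    y = matrix[rs_v_cols].to_numpy()

    def build(cols: list[str], extra: dict) -> pd.DataFrame:
        if not cols:
            raise ValueError(f"missing PostV block in tissue {tissue}")
        x = matrix[cols].to_numpy()
        est, t, p = _pooled_t(x, y)
        q = bh_fdr(p)
        label = np.where(
            q < alpha, np.where(est > 0, "up", "down"), "plateau"
        )
        return pd.DataFrame(
            {
                "gene": matrix.index,
                "tissue": tissue,
                **extra,
                "contrast_estimate": est,
                "t": t,
                "p": p,
                "q": q,
                "label": label,
            }
        ).reset_index(drop=True)

    postv = sel[sel["stage"] == "PostV"]
    if mode == "pooled":
        return build(postv["sample_id"].to_list(), {})
    if mode == "per_class":
        frames = [
            build(sub["sample_id"].to_list(), {"postv_class": cls})
            for cls, sub in postv.groupby("class")
        ]
        return pd.concat(frames, ignore_index=True)
    raise ValueError(f"unknown mode {mode!r}")


def trend_by_rv_crosstab(
    trends: pd.DataFrame,
    rv: pd.DataFrame,
    hi_threshold: float = 20.0,
    lo_threshold: float = 10.0,
) -> pd.DataFrame:
    """Trend-label proportions within high-RV and low-RV gene strata.

    Rows ``high`` (rv_fold > hi) and ``low`` (rv_fold < lo); columns are
    up/down/plateau proportions plus the stratum size.  An empty stratum
    yields NaN proportions and is flagged via ``n == 0``.
    """
    merged = trends.merge(rv[["gene", "rv_fold"]], on="gene")
    strata = {
        "high": merged[merged["rv_fold"] > hi_threshold],
        "low": merged[merged["rv_fold"] < lo_threshold],
    }
    rows = []
    for name, sub in strata.items():
        n = len(sub)
        row = {"stratum": name, "n": n}
        for lab in TREND_LABELS:
            row[lab] = float((sub["label"] == lab).mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
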