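"""Transcriptional-distance decomposition.

Treats ripening as movement along a common transcriptional trajectory.
Per gene, the véraison gaps between classes are

    a = mean(PS@V) - mean(GS@V),   b = mean(RS@V) - mean(PS@V)

and the V -> PostV changes within each class are X (GS), Y (PS), Z (RS).
If all classes traverse the same programme and end synchronized, then the
distance still ahead of a GS berry at véraison is the gap to RS plus the
distance RS itself still travels:

    X_calc = a + b + Z,   Y_calc = b + Z.

The identity ``X_calc - X_obs = mean(RS@PostV) - mean(GS@PostV)`` holds
algebraically for any input, so the observed-vs-calculated regression R^2
approaches 1 exactly as the PostV class means converge — this is the
model's testable core.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _class_stage_means(
    matrix: pd.DataFrame, meta: pd.DataFrame, tissue: str
) -> dict[tuple[str, str], np.ndarray]:
    means = {}
    for (cls, stage), sel in meta[meta["tissue"] == tissue].groupby(
        ["class", "stage"]
    ):
        means[(cls, stage)] = matrix[sel["sample_id"].to_list()].to_numpy().mean(
            axis=1
        )
    for cls in ("GS", "PS", "RS"):
        for stage in ("V", "PostV"):
            if (cls, stage) not in means:
                raise ValueError(f"missing class-stage block {cls}/{stage}")
    return means


def compute_distances(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    gene_universe: Sequence[str] | None = None,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-gene distance record (a, b, X/Y observed and calculated, Z).

    ``scale="log2"`` (default) returns log2 differences; ``scale="fold"``
    exponentiates every distance to a fold change (2**value).
    """
    if gene_universe is not None:
        matrix = matrix.loc[list(gene_universe)]
    m = _class_stage_means(matrix, meta, tissue)
    a = m[("PS", "V")] - m[("GS", "V")]
    b = m[("RS", "V")] - m[("PS", "V")]
    x_obs = m[("GS", "PostV")] - m[("GS", "V")]
    y_obs = m[("PS", "PostV")] - m[("PS", "V")]
    z = m[("RS", "PostV")] - m[("RS", "V")]
    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "tissue": tissue,
            "a": a,
            "b": b,
            "x_obs": x_obs,
            "y_obs": y_obs,
            "z": z,
            "x_calc": a + b + z,
            "y_calc": b + z,
        }
    ).reset_index(drop=True)
    if scale == "fold":
        for col in ("a", "b", "x_obs", "y_obs", "z", "x_calc", "y_calc"):
            out[col] = np.exp2(out[col])
    elif scale != "log2":
        raise ValueError(f"unknown scale {scale!r}")
    return out


def linearity(records: pd.DataFrame, which: str = "X") -> dict:
    """OLS of calculated on observed distance across genes.

    Returns slope, intercept and R^2 for the X (GS) or Y (PS) distances.
    """
    which = which.upper()
    if which not in ("X", "Y"):
        raise ValueError("which must be 'X' or 'Y'")
    obs = records[f"{which.lower()}_obs"].to_numpy()
    calc = records[f"{which.lower()}_calc"].to_numpy()
    if len(obs) < 3:
        raise ValueError("need >= 3 records for a regression")
    if np.ptp(obs) == 0:
        raise ValueError("degenerate observed distances (all equal)")
    if np.array_equal(obs, calc):
        # exact synchronization: calculated == observed identically
        return {"slope": 1.0, "intercept": 0.0, "r_squared": 1.0, "n": len(obs)}
    fit = stats.linregress(obs, calc)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "n": len(obs),
    }
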