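"""Synthetic-data generator for the ripening-synchronization design.

Two generators emulate the study layout:

``simulate_physiology``
    Per-berry weekly °Brix / colour / elasticity trajectories for the four
    ripening classes.  Every class follows one common saturating (logistic)
    curve, shifted in time by a class-specific lag, so that under-ripe
    classes traverse the same physiological states later and converge on
    the RS class towards maturity.

``simulate_expression``
    A genes x samples log2 expression matrix for GS/PS/RS at mid-véraison
    (V) and five weeks post-véraison (PostV), paired by replicate plant.
    At V the class means per gene are (mu, mu + a, mu + a + b); at PostV
    all classes share a common target (the V RS mean shifted by the gene's
    up/down/plateau trend effect) plus small per-class residuals calibrated
    so the measured between-class variance shrinks by ``rv_fold_target``.

Ground truth (per-gene a, b, Z, trend label, residual variance) is returned
alongside for parameter-recovery testing.
"""

from __future__ import annotations

import zlib
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimConfig, TREND_LABELS


class ExpressionData(NamedTuple):
    """Simulated expression bundle: matrix (genes x samples), sample
    metadata, and per-(gene, tissue) ground truth."""

    matrix: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame


def _rng(config: SimConfig, *key: str) -> np.random.Generator:
    """Deterministic named substream of the run's seed (process-independent)."""
    hashed = [zlib.crc32(k.encode()) & 0x7FFFFFFF for k in key]
    return np.random.default_rng(np.random.SeedSequence([config.seed, *hashed]))


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def simulate_physiology(config: SimConfig) -> pd.DataFrame:
    """Generate the per-berry physiology table.

    One row per berry per sampling day with columns
    ``berry_id, plant, cluster, class, day, brix, L, h, C, elasticity``.
    L, h, C are emitted such that ``colour_index(L, h, C) == 180*h/(L+C)``
    reproduces the intended (noisy) colour-index value exactly: L and C are
    held near constants and the hue angle h carries the colour signal.
    """
    curves = {"brix": config.brix_curve, "colour": config.colour_curve}
    for name, curve in curves.items():
        days = np.asarray(config.weeks, dtype=float)
        vals = curve.value(days)
        if np.any(np.diff(vals) < 0):
            raise ValueError(f"{name} curve is non-monotone over the sampled days")

    # Colour noise is scaled to keep the relative noise level comparable to
    # the Brix channel (the two curves span different ranges).
    ci_scale = (config.colour_curve.asymptote - config.colour_curve.floor) / (
        config.brix_curve.asymptote - config.brix_curve.floor
    )
    ci_noise_sd = config.phys_noise_sd * ci_scale

    rng = _rng(config, "physiology")
    n_b = config.berries_per_class_per_week
    clusters_per_plant = max(1, int(np.ceil(n_b / config.n_plants_phys)))

    rows = []
    for cls in config.classes_phys:
        lag = float(config.class_lags_days.get(cls, 0.0))
        for day in config.weeks:
            t = float(day) - lag
            brix_true = float(config.brix_curve.value(t))
            ci_true = float(config.colour_curve.value(t))
            brix = brix_true + rng.normal(0.0, config.phys_noise_sd, n_b)
            ci = ci_true + rng.normal(0.0, ci_noise_sd, n_b)
            ci = np.maximum(ci, 1e-6)
            L = 32.0 + rng.normal(0.0, 0.5, n_b)
            C = 8.0 + rng.normal(0.0, 0.5, n_b)
            h = ci * (L + C) / 180.0
            # softening: elasticity decays along the same shifted clock
            elast_true = 0.2 + 1.0 / (1.0 + np.exp(0.25 * (t - 3.0)))
            elast = np.maximum(
                elast_true + rng.normal(0.0, 0.05, n_b), 0.01
            )
            for i in range(n_b):
                plant = i % config.n_plants_phys + 1
                cluster = i // config.n_plants_phys % clusters_per_plant + 1
                rows.append(
                    {
                        "berry_id": f"{cls}_d{day:g}_b{i + 1}",
                        "plant": f"P{plant}",
                        "cluster": f"P{plant}c{cluster}",
                        "class": cls,
                        "day": float(day),
                        "brix": brix[i],
                        "L": L[i],
                        "h": h[i],
                        "C": C[i],
                        "elasticity": elast[i],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _sample_id(tissue: str, stage: str, cls: str, rep: int) -> str:
    return f"{tissue}_{stage}_{cls}_r{rep}"


def simulate_expression(config: SimConfig) -> ExpressionData:
    """Generate a paired two-stage, three-class log2 expression matrix.

    The PostV per-class residual SD is calibrated so that the *measured*
    between-class variance of empirical class means (which includes the
    replicate sampling noise ``residual_sd**2 / n_replicates``) shrinks by
    ``rv_fold_target`` relative to V in expectation.  Genes whose V variance
    is too small for the target to clear the sampling-noise floor receive a
    zero residual (exact synchronization for that gene).
    """
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (paired tests undefined)")
    classes = list(config.classes_expr)
    if len(classes) != 3:
        raise ValueError("expression design expects exactly 3 classes (GS, PS, RS)")

    n = config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]
    nu = config.residual_sd**2 / config.n_replicates  # class-mean noise floor

    mats, truths, meta_rows = [], [], []
    for tissue in config.tissues:
        rng = _rng(config, "expression", tissue)
        mu = rng.normal(config.baseline_mean, config.baseline_sd, n)
        a = rng.normal(0.0, config.effect_sd_v, n)
        b = rng.normal(0.0, config.effect_sd_v, n)
        probs = [config.trend_mix[k] for k in TREND_LABELS]
        trend = rng.choice(np.array(TREND_LABELS), size=n, p=probs)
        delta = np.where(trend == "up", config.trend_effect, 0.0) - np.where(
            trend == "down", config.trend_effect, 0.0
        )

        means_v = np.stack([mu, mu + a, mu + a + b])  # GS, PS, RS
        var_v_true = (a * a + a * b + b * b) / 3.0  # sample variance of the 3 means

        if config.exact_sync:
            s2 = np.zeros(n)
        else:
            target = np.full(n, config.rv_fold_target)
            if config.rv_fold_sdlog > 0:
                target = target * rng.lognormal(0.0, config.rv_fold_sdlog, n)
            if config.up_rv_multiplier != 1.0:
                target = np.where(trend == "up", target * config.up_rv_multiplier,
                                  target)
            s2 = np.maximum(0.0, (var_v_true + nu) / target - nu)
        resid = rng.normal(0.0, 1.0, (3, n)) * np.sqrt(s2)
        common = mu + a + b + delta
        means_postv = common[None, :] + resid

        cols, data = [], []
        for stage, means in (("V", means_v), ("PostV", means_postv)):
            for ci, cls in enumerate(classes):
                noise = rng.normal(0.0, config.residual_sd,
                                   (config.n_replicates, n))
                for rep in range(1, config.n_replicates + 1):
                    cols.append(_sample_id(tissue, stage, cls, rep))
                    data.append(means[ci] + noise[rep - 1])
                    meta_rows.append(
                        {
                            "sample_id": cols[-1],
                            "class": cls,
                            "tissue": tissue,
                            "stage": stage,
                            "replicate": f"plant{rep}",
                        }
                    )
        mats.append(pd.DataFrame(np.column_stack(data), index=genes, columns=cols))
        truths.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "tissue": tissue,
                    "a": a,
                    "b": b,
                    "z": delta + resid[2],
                    "trend": trend,
                    "var_v_true": var_v_true,
                    "var_postv_true": s2,
                }
            )
        )

    matrix = pd.concat(mats, axis=1)
    matrix.index.name = "gene"
    meta = pd.DataFrame(meta_rows)
    truth = pd.concat(truths, ignore_index=True)
    return ExpressionData(matrix=matrix, meta=meta, truth=truth)
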