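"""Configuration objects for the simulator and the pipeline.

The defaults encode the study design this package emulates: a Pinot noir
cluster at mid-véraison (V) containing berry ripening classes GH (green
hard), GS (green soft), PS (pink soft) and RS (red soft); expression
profiled in three tissues for GS/PS/RS at V and five weeks post-véraison
(PostV) with three replicate plants; physiology (°Brix, colour, elasticity)
tracked weekly on all four classes for six weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
import yaml

EXPR_CLASSES = ("GS", "PS", "RS")
PHYS_CLASSES = ("GH", "GS", "PS", "RS")
TISSUES = ("pulp", "skin", "seed")
STAGES = ("V", "PostV")
TREND_LABELS = ("up", "down", "plateau")


@dataclass(frozen=True)
class LogisticCurve:
    """Monotone saturating trajectory ``f(t) = floor + (asymptote - floor) *
    sigmoid(rate * (t - m))`` with the midpoint ``m`` chosen so that
    ``f(0) == start`` exactly.

    ``start`` is the value of the reference (RS) class at mid-véraison;
    lagged classes evaluate the same curve at ``t - lag`` and therefore sit
    below ``start`` at day 0, bounded below by ``floor``.
    """

    floor: float
    start: float
    asymptote: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.floor < self.start < self.asymptote):
            raise ValueError(
                "curve requires floor < start < asymptote "
                f"(got {self.floor}, {self.start}, {self.asymptote})"
            )
        if self.rate <= 0:
            raise ValueError("curve rate must be positive (monotone increasing)")

    @property
    def midpoint(self) -> float:
        p0 = (self.start - self.floor) / (self.asymptote - self.floor)
        return -float(logit(p0)) / self.rate

    def value(self, t):
        """Evaluate the curve at time ``t`` (days; scalar or array)."""
        t = np.asarray(t, dtype=float)
        y = self.floor + (self.asymptote - self.floor) * expit(
            self.rate * (t - self.midpoint)
        )
        # The logistic is bounded below by floor already; clip guards against
        # round-off on extreme negative times.
        return np.maximum(y, self.floor)


# Default curves: RS °Brix is 12.6 at mid-véraison (the R1 reference) and
# ~19.8 at 42 d; the curve is concave over the sampled window so that a
# class lagging by 13 d sits ~5 °Brix behind at day 0 yet only ~1.2 °Brix
# behind by day 35 — between-class spread shrinks monotonically as all
# classes saturate.  The colour curve is the same shape rescaled (colour
# index 3.4 at day 0, the R1 colour reference), so sugar and pigment
# progress concomitantly.
DEFAULT_BRIX_CURVE = LogisticCurve(floor=0.5, start=12.6, asymptote=20.2, rate=0.08)
DEFAULT_COLOUR_CURVE = LogisticCurve(floor=-0.26, start=3.4, asymptote=5.7, rate=0.08)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generator.

    Expression parameters are on the log2 scale throughout.
    """

    seed: int = 0
    n_genes: int = 2000
    classes_expr: Sequence[str] = EXPR_CLASSES
    classes_phys: Sequence[str] = PHYS_CLASSES
    tissues: Sequence[str] = ("pulp",)
    n_replicates: int = 3
    class_lags_days: Mapping[str, float] = field(
        default_factory=lambda: {"GH": 13.0, "GS": 10.0, "PS": 7.0, "RS": 0.0}
    )
    weeks: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 35.0, 42.0)
    berries_per_class_per_week: int = 30
    n_plants_phys: int = 6
    brix_curve: LogisticCurve = DEFAULT_BRIX_CURVE
    colour_curve: LogisticCurve = DEFAULT_COLOUR_CURVE
    phys_noise_sd: float = 0.15
    effect_sd_v: float = 1.0
    rv_fold_target: float = 24.0
    exact_sync: bool = False
    trend_mix: Mapping[str, float] = field(
        default_factory=lambda: {"up": 1 / 3, "down": 1 / 3, "plateau": 1 / 3}
    )
    trend_effect: float = 1.0
    residual_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    # Optional heterogeneity/coupling knobs (off by default): per-gene
    # lognormal spread of the RV fold target (median-preserving) and a fold
    # multiplier applied to up-trend genes.
    rv_fold_sdlog: float = 0.0
    up_rv_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates", "berries_per_class_per_week",
                     "n_plants_phys"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.rv_fold_target <= 0:
            raise ValueError("rv_fold_target must be > 0")
        mix = self.trend_mix
        if set(mix) != set(TREND_LABELS):
            raise ValueError(f"trend_mix must have keys {TREND_LABELS}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("trend_mix proportions must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("trend_mix proportions must be non-negative")
        lags = self.class_lags_days
        if "RS" in lags and lags["RS"] != 0:
            raise ValueError("class_lags_days['RS'] must be 0 (RS is the reference)")
        if self.residual_sd < 0 or self.phys_noise_sd < 0 or self.effect_sd_v < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings: either an input directory with matrix /
    metadata / physiology files, or a SimConfig block to generate them."""

    sim: SimConfig | None = None
    expression_tsv: str | None = None
    metadata_tsv: str | None = None
    physiology_csv: str | None = None
    alpha_dge: float = 0.05
    alpha_rv: float = 0.2
    alpha_trend: float = 0.05
    rv_hi: float = 20.0
    rv_lo: float = 10.0
    top_n: int = 100
    outdir: str = "ripesync_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_dge", "alpha_rv", "alpha_trend"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.sim is None and self.expression_tsv is None:
            raise ValueError("need either a sim block or input file paths")


def _curve_from_dict(d: Mapping) -> LogisticCurve:
    return LogisticCurve(**{k: float(v) for k, v in d.items()})


def sim_config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    for key in ("brix_curve", "colour_curve"):
        if key in d and isinstance(d[key], Mapping):
            d[key] = _curve_from_dict(d[key])
    for key in ("classes_expr", "classes_phys", "tissues", "weeks"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def pipeline_config_from_dict(d: Mapping) -> PipelineConfig:
    d = dict(d)
    if "sim" in d and isinstance(d["sim"], Mapping):
        d["sim"] = sim_config_from_dict(d["sim"])
    return PipelineConfig(**d)


def load_config(path: str) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
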