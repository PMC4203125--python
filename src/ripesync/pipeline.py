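"""End-to-end orchestration: simulate -> dge -> rv -> distances -> trends
-> kinetics, with persisted stage artifacts and a consolidated summary.

Every stage reads/writes plain TSV/CSV so individual stages can be re-run
from persisted inputs (or on user data) bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import pandas as pd

from . import diffexpr, distances, io, kinetics, simulate, trends, variance
from .config import PipelineConfig, SimConfig, STAGES

log = logging.getLogger("ripesync")


def _timed(name: str, outdir: Path):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage=%s status=done wall_s=%.2f", name, dt)
            else:
                log.error("stage=%s status=FAILED wall_s=%.2f error=%s",
                          name, dt, exc)
            return False

    return _Ctx()


def stage_simulate(config: SimConfig, outdir: Path) -> dict:
    """Generate and persist expression + physiology + truth tables."""
    expr = simulate.simulate_expression(config)
    phys = simulate.simulate_physiology(config)
    io.write_expression(expr.matrix, outdir / "expression.tsv")
    io.write_metadata(expr.meta, outdir / "metadata.tsv")
    io.write_table(expr.truth, outdir / "expression_truth.tsv")
    io.write_physiology(phys, outdir / "physiology.csv")
    return {
        "n_genes": int(expr.matrix.shape[0]),
        "n_samples": int(expr.matrix.shape[1]),
        "n_berry_rows": int(len(phys)),
    }


def stage_dge(matrix, meta, outdir: Path, alpha: float, moderate: bool = True) -> dict:
    """Per-(tissue, stage) moderated paired tests for all class pairs."""
    summary = {}
    unions = {}
    for tissue in sorted(meta["tissue"].unique()):
        for stage in STAGES:
            results, union = diffexpr.dge_block(
                matrix, meta, tissue, stage, alpha=alpha, moderate=moderate
            )
            counts = {}
            for pair, res in results.items():
                io.write_table(res, outdir / f"dge_{tissue}_{stage}_{pair}.tsv")
                counts[pair] = int((res["q"] < alpha).sum())
            unions[(tissue, stage)] = union
            pd.DataFrame({"gene": union}).to_csv(
                outdir / f"dge_union_{tissue}_{stage}.tsv", sep="\t", index=False
            )
            summary[f"{tissue}/{stage}"] = {
                "per_pair": counts,
                "union": len(union),
            }
    return {"counts": summary, "unions": unions}


def stage_rv(matrix, meta, outdir: Path, alpha: float, universe=None) -> dict:
    out = {}
    for tissue in sorted(meta["tissue"].unique()):
        uni = universe.get(tissue) if universe else None
        rec = variance.rv_records(matrix, meta, tissue, gene_universe=uni)
        rec = variance.rv_ftest(rec, alpha=alpha)
        io.write_table(rec, outdir / f"rv_{tissue}.tsv")
        summ = variance.rv_distribution_summary(rec)
        summ["n_significant"] = int(rec["significant"].sum())
        out[tissue] = summ
    return out


def stage_distances(matrix, meta, outdir: Path, universe=None) -> dict:
    out = {}
    for tissue in sorted(meta["tissue"].unique()):
        uni = universe.get(tissue) if universe else None
        rec = distances.compute_distances(matrix, meta, tissue, gene_universe=uni)
        io.write_table(rec, outdir / f"distances_{tissue}.tsv")
        out[tissue] = {
            "X": distances.linearity(rec, "X"),
            "Y": distances.linearity(rec, "Y"),
        }
    return out


def stage_trends(matrix, meta, outdir: Path, alpha: float,
                 rv_dir: Path, hi: float, lo: float) -> dict:
    out = {}
    for tissue in sorted(meta["tissue"].unique()):
        calls = trends.trend_call(matrix, meta, tissue, alpha=alpha)
        io.write_table(calls, outdir / f"trends_{tissue}.tsv")
        props = calls["label"].value_counts(normalize=True).to_dict()
        entry = {"proportions": {k: float(props.get(k, 0.0))
                                 for k in trends.TREND_LABELS}}
        rv_path = rv_dir / f"rv_{tissue}.tsv"
        if rv_path.exists():
            rv = io.read_table(rv_path)
            ct = trends.trend_by_rv_crosstab(calls, rv, hi, lo)
            io.write_table(ct, outdir / f"trend_rv_crosstab_{tissue}.tsv")
            entry["crosstab"] = ct.to_dict(orient="records")
        out[tissue] = entry
    return out


def stage_kinetics(phys: pd.DataFrame, outdir: Path) -> dict:
    table = kinetics.add_colour_index(phys)
    stages = kinetics.define_reference_stages(table)
    io.write_table(stages, outdir / "reference_stages.tsv")
    out = {"reference_stages": stages.to_dict(orient="records")}
    for response in kinetics.RESPONSES:
        day_tab = kinetics.ripening_day_table(table, stages, response=response)
        lags = kinetics.lag_table(day_tab)
        rates = kinetics.accumulation_rates(stages, day_tab, response=response)
        io.write_table(day_tab, outdir / f"days_to_reference_{response}.tsv")
        io.write_table(lags, outdir / f"lag_table_{response}.tsv")
        io.write_table(rates, outdir / f"rate_table_{response}.tsv")
        out[response] = {
            "lags": lags.to_dict(orient="records"),
            "rates": rates.to_dict(orient="records"),
        }
        plant_rates = kinetics.per_plant_rates(table, stages, response=response)
        if plant_rates["class"].nunique() >= 2 and (
            plant_rates.groupby("class").size() >= 2
        ).all():
            cmp = kinetics.compare_rates(plant_rates)
            io.write_table(plant_rates, outdir / f"per_plant_rates_{response}.tsv")
            out[response]["rate_comparison"] = {
                "means": cmp["means"],
                "f_stat": cmp["f_stat"],
                "p_anova": cmp["p_anova"],
                "letters": cmp["letters"],
            }
    out["brix_spread"] = {
        "V": kinetics.between_class_spread(table, 0.0, "brix"),
        "PostV": kinetics.between_class_spread(table, 35.0, "brix"),
    }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Writes every stage's tables plus ``summary.json`` under
    ``config.outdir``.  Deterministic given ``config.seed`` (injected into
    the sim block when simulating).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        with _timed("simulate", outdir):
            summary["simulate"] = stage_simulate(sim, outdir)
        matrix = io.read_expression(outdir / "expression.tsv")
        meta = io.read_metadata(outdir / "metadata.tsv")
        phys = io.read_physiology(outdir / "physiology.csv")
    else:
        matrix = io.read_expression(config.expression_tsv)
        meta = io.read_metadata(config.metadata_tsv)
        phys = (
            io.read_physiology(config.physiology_csv)
            if config.physiology_csv
            else None
        )
        for path in (config.expression_tsv, config.metadata_tsv):
            log.info("input=%s sha256=%s", path, io.file_sha256(path))

    with _timed("dge", outdir):
        dge = stage_dge(matrix, meta, outdir, alpha=config.alpha_dge)
    summary["dge"] = dge["counts"]
    universe = {t: genes for (t, s), genes in dge["unions"].items() if s == "V"}

    with _timed("rv", outdir):
        summary["rv"] = stage_rv(matrix, meta, outdir, alpha=config.alpha_rv)
    with _timed("distances", outdir):
        summary["distances"] = stage_distances(
            matrix, meta, outdir,
            universe={t: g for t, g in universe.items() if g} or None,
        )
    with _timed("trends", outdir):
        summary["trends"] = stage_trends(
            matrix, meta, outdir, config.alpha_trend, outdir,
            config.rv_hi, config.rv_lo,
        )
    if phys is not None:
        with _timed("kinetics", outdir):
            summary["kinetics"] = stage_kinetics(phys, outdir)

    # RV-vs-variance top-gene ranking comparison (per tissue)
    overlaps = {}
    for tissue in sorted(meta["tissue"].unique()):
        rv = io.read_table(outdir / f"rv_{tissue}.tsv").set_index("gene")
        finite = rv[rv["rv_fold"].apply(lambda v: v == v and v != float("inf"))]
        n = min(config.top_n, len(finite))
        if n >= 1:
            overlaps[tissue] = variance.rank_overlap(
                finite["rv_fold"], finite["var_v"], n
            )
    summary["top_gene_overlap_rv_vs_variance"] = overlaps

    io.write_json(summary, outdir / "summary.json")
    return summary
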