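"""Physiological ripening kinetics.

Aligns berry classes on a common physiological axis: the °Brix and
colour-index states of RS berries at 0/7/14/21 d past mid-véraison define
reference stages R1-R4; per-class regression curves of class-mean response
vs day are inverted to obtain the day at which each under-ripe class
reaches a reference, yielding lag tables (days behind RS) and accumulation
rates (response units per day between consecutive references).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

RESPONSES = ("brix", "colour_index")
REFERENCE_DAYS = {"R1": 0.0, "R2": 7.0, "R3": 14.0, "R4": 21.0}


# ---------------------------------------------------------------------------
# colour index
# ---------------------------------------------------------------------------

def colour_index(L, h, C, formula: str = "ratio"):
    """Composite colour index from colorimeter readings.

    ``formula="ratio"`` (default) computes ``180*h / (L + C)``;
    ``formula="literal"`` computes ``180*h/L + C`` (the alternative reading
    of the printed expression).  Inputs may be scalars or arrays.
    """
    L = np.asarray(L, dtype=float)
    h = np.asarray(h, dtype=float)
    C = np.asarray(C, dtype=float)
    if formula == "ratio":
        denom = L + C
        if np.any(denom <= 0):
            raise ValueError("colour index undefined for L + C <= 0")
        out = 180.0 * h / denom
    elif formula == "literal":
        if np.any(L <= 0):
            raise ValueError("colour index undefined for L <= 0")
        out = 180.0 * h / L + C
    else:
        raise ValueError(f"unknown colour-index formula {formula!r}")
    return out if out.ndim else float(out)


def add_colour_index(table: pd.DataFrame, formula: str = "ratio") -> pd.DataFrame:
    """Return a copy of the physiology table with a ``colour_index`` column."""
    out = table.copy()
    out["colour_index"] = colour_index(out["L"], out["h"], out["C"], formula)
    return out


def _response_values(table: pd.DataFrame, response: str,
                     ci_formula: str = "ratio") -> pd.Series:
    if response == "brix":
        return table["brix"]
    if response == "colour_index":
        if "colour_index" in table.columns:
            return table["colour_index"]
        return pd.Series(
            colour_index(table["L"], table["h"], table["C"], ci_formula),
            index=table.index,
        )
    raise ValueError(f"unknown response {response!r}")


# ---------------------------------------------------------------------------
# curve fitting and inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsFit:
    """Polynomial fit of class-mean response vs day."""

    cls: str
    response: str
    coefficients: tuple  # highest power first (np.polyfit convention)
    window: tuple
    r_squared: float
    n_points: int

    def predict(self, t):
        return np.polyval(self.coefficients, t)


def fit_ripening_curve(
    table: pd.DataFrame,
    cls: str,
    response: str,
    window: tuple = (0.0, 21.0),
    degree: int = 2,
    ci_formula: str = "ratio",
) -> KineticsFit:
    """Least-squares polynomial of class-mean response vs day.

    The fit must be non-decreasing over the window (ripening responses are
    monotone); non-monotone fits are rejected.
    """
    sub = table[table["class"] == cls]
    sub = sub[(sub["day"] >= window[0]) & (sub["day"] <= window[1])]
    vals = _response_values(sub, response, ci_formula)
    means = vals.groupby(sub["day"]).mean()
    if len(means) < degree + 2:
        raise ValueError(
            f"need >= {degree + 2} distinct days in window for degree {degree}, "
            f"got {len(means)}"
        )
    days = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    coeffs = np.polyfit(days, y, degree)
    fitted = np.polyval(coeffs, days)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    grid = np.linspace(window[0], window[1], 512)
    deriv = np.polyval(np.polyder(coeffs), grid)
    if np.any(deriv < -1e-9):
        raise ValueError(
            f"fitted {response} curve for class {cls} is non-monotone on "
            f"{window}; refuse to invert"
        )
    return KineticsFit(
        cls=cls,
        response=response,
        coefficients=tuple(coeffs),
        window=(float(window[0]), float(window[1])),
        r_squared=r2,
        n_points=len(means),
    )


def days_to_reference(
    fit: KineticsFit, ref_value: float, margin: float = 7.0, tol: float = 1e-6
) -> float:
    """Earliest day at which the fitted curve reaches ``ref_value``.

    The search window is the fit window extended by ``margin`` days on both
    sides (bounded extrapolation).  Root located by bracketing + Brent to
    ``tol`` days.
    """
    lo = fit.window[0] - margin
    hi = fit.window[1] + margin
    f = lambda t: fit.predict(t) - ref_value
    grid = np.linspace(lo, hi, 2048)
    vals = f(grid)
    sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
    exact = np.nonzero(np.abs(vals) == 0.0)[0]
    candidates = []
    if exact.size:
        candidates.append(grid[exact[0]])
    if sign_change.size:
        i = sign_change[0]
        root = optimize.brentq(f, grid[i], grid[i + 1], xtol=tol)
        candidates.append(root)
    if not candidates:
        raise ValueError(
            f"reference {ref_value} for class {fit.cls} ({fit.response}) not "
            f"reachable within window {fit.window} + margin {margin}"
        )
    return float(min(candidates))


# ---------------------------------------------------------------------------
# reference stages, lags, rates
# ---------------------------------------------------------------------------

def define_reference_stages(
    table: pd.DataFrame,
    days: Sequence[float] = (0.0, 7.0, 14.0, 21.0),
    ci_formula: str = "ratio",
) -> pd.DataFrame:
    """RS class-mean °Brix and colour index at the stated days -> R1..R4.

    Returns a frame with columns ``stage, rs_day, brix_ref, ci_ref``.
    References must be strictly increasing R1 -> R4.
    """
    rs = table[table["class"] == "RS"]
    rows = []
    for i, day in enumerate(days, start=1):
        sub = rs[rs["day"] == day]
        if sub.empty:
            raise ValueError(f"RS class not sampled at day {day}")
        rows.append(
            {
                "stage": f"R{i}",
                "rs_day": float(day),
                "brix_ref": float(sub["brix"].mean()),
                "ci_ref": float(
                    _response_values(sub, "colour_index", ci_formula).mean()
                ),
            }
        )
    out = pd.DataFrame(rows)
    for col in ("brix_ref", "ci_ref"):
        if not np.all(np.diff(out[col]) > 0):
            raise ValueError(
                f"reference {col} values must be strictly increasing R1->R4"
            )
    return out


#: Response-specific fit defaults.  Brix rises smoothly through the whole
#: sampled window, so a cubic on days 0-35 (5 sampled days) halves the
#: inversion bias of a quadratic; the colour index has a flat pre-ripening
#: plateau that higher degrees overfit (non-monotone), so it keeps the
#: quadratic on the 0-21 d window.
DEFAULT_FIT_PARAMS = {
    "brix": {"degree": 3, "window": (0.0, 35.0)},
    "colour_index": {"degree": 2, "window": (0.0, 21.0)},
}


def ripening_day_table(
    table: pd.DataFrame,
    stages: pd.DataFrame,
    response: str = "brix",
    classes: Sequence[str] | None = None,
    window: tuple | None = None,
    degree: int | None = None,
    margin: float = 5.0,
    ci_formula: str = "ratio",
    stage_ids: Sequence[str] = ("R1", "R2", "R3"),
) -> pd.DataFrame:
    """Days for each class to reach the reference values of ``stage_ids``.

    Fits one polynomial per class (defaults per ``DEFAULT_FIT_PARAMS``) and
    inverts it for each reference value.  Returns columns
    ``class, stage, response, day``.
    """
    if window is None:
        window = DEFAULT_FIT_PARAMS[response]["window"]
    if degree is None:
        degree = DEFAULT_FIT_PARAMS[response]["degree"]
    if classes is None:
        classes = sorted(table["class"].unique())
    ref_col = "brix_ref" if response == "brix" else "ci_ref"
    refs = stages.set_index("stage")[ref_col]
    rows = []
    for cls in classes:
        fit = fit_ripening_curve(table, cls, response, window, degree, ci_formula)
        for stage in stage_ids:
            day = days_to_reference(fit, float(refs[stage]), margin=margin)
            rows.append(
                {"class": cls, "stage": stage, "response": response, "day": day}
            )
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def lag_table(
    days: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    rs_days: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-class lag behind RS at each reference stage.

    ``days`` is either a mapping ``{class: {stage: day}}`` or a frame with
    columns ``class, stage, day``.  ``rs_days`` defaults to the RS entries
    of ``days`` (or the canonical stage days 0/7/14/21).  Lags are reported
    both raw and rounded half-up to whole days.
    """
    if isinstance(days, pd.DataFrame):
        mapping: dict[str, dict[str, float]] = {}
        for _, row in days.iterrows():
            mapping.setdefault(row["class"], {})[row["stage"]] = float(row["day"])
        days = mapping
    if rs_days is None:
        rs_days = days.get("RS", REFERENCE_DAYS)
    rows = []
    for cls, per_stage in days.items():
        for stage, day in per_stage.items():
            if stage not in rs_days:
                raise ValueError(f"no RS day for stage {stage}")
            lag = float(day) - float(rs_days[stage])
            rows.append(
                {
                    "class": cls,
                    "stage": stage,
                    "day_to_reference": float(day),
                    "lag_vs_rs": lag,
                    "rounded_lag": _round_half_up(lag),
                }
            )
    return pd.DataFrame(rows)


def accumulation_rates(
    stages: pd.DataFrame,
    days: pd.DataFrame,
    response: str = "brix",
) -> pd.DataFrame:
    """Accumulation rate per class between consecutive reference stages.

    ``rate = (ref_j - ref_i) / (day_to_ref_j - day_to_ref_i)`` in response
    units per day.  Days must be strictly increasing across stages within
    each class.
    """
    ref_col = "brix_ref" if response == "brix" else "ci_ref"
    refs = stages.set_index("stage")[ref_col]
    rows = []
    for cls, sub in days.groupby("class"):
        sub = sub.set_index("stage").loc[[s for s in refs.index if s in sub["stage"].values]]
        stage_ids = list(sub.index)
        for s1, s2 in zip(stage_ids[:-1], stage_ids[1:]):
            dt = float(sub.loc[s2, "day"]) - float(sub.loc[s1, "day"])
            if dt <= 0:
                raise ValueError(
                    f"days to reference not increasing for class {cls} "
                    f"({s1}->{s2})"
                )
            rows.append(
                {
                    "class": cls,
                    "interval": f"{s1}-{s2}",
                    "response": response,
                    "rate": (float(refs[s2]) - float(refs[s1])) / dt,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rate comparison (ANOVA + Tukey HSD with compact letters)
# ---------------------------------------------------------------------------

def _compact_letters(groups: Sequence[str], means: Mapping[str, float],
                     not_different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups that are NOT
    significantly different share a letter."""
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all((min(g, o), max(g, o)) in not_different for o in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letters = {g: "" for g in groups}
    for s, ch in zip(letter_sets, "abcdefghijklmnopqrstuvwxyz"):
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def compare_rates(rates: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA on class + Tukey HSD pairwise tests + letter display.

    ``rates`` needs columns ``class`` and ``rate`` with one row per plant
    (or other replicate unit) per class.  Degenerate inputs (zero
    within-group variance with unequal means) are flagged.
    """
    groups = sorted(rates["class"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 classes to compare")
    arrays = [rates.loc[rates["class"] == g, "rate"].to_numpy() for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 replicates per class")
    means = {g: float(a.mean()) for g, a in zip(groups, arrays)}
    within_var = float(np.mean([a.var(ddof=1) for a in arrays]))
    between_scale = max(1e-300, float(np.var(list(means.values()))))
    degenerate = (
        within_var < 1e-12 * between_scale
        and len({round(m, 12) for m in means.values()}) > 1
    )
    if degenerate:
        f_stat, p_anova = np.inf, 0.0
        not_different = set()  # all pairs differ
    else:
        f_stat, p_anova = stats.f_oneway(*arrays)
        tuk = pairwise_tukeyhsd(
            rates["rate"].to_numpy(), rates["class"].to_numpy(), alpha=alpha
        )
        res = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        )
        not_different = {
            (min(r["group1"], r["group2"]), max(r["group1"], r["group2"]))
            for _, r in res.iterrows()
            if not r["reject"]
        }
    tukey_p = None
    if not degenerate:
        tukey_p = {
            (min(r["group1"], r["group2"]), max(r["group1"], r["group2"])): float(
                r["p-adj"]
            )
            for _, r in res.iterrows()
        }
    letters = _compact_letters(groups, means, not_different)
    return {
        "means": means,
        "f_stat": float(f_stat),
        "p_anova": float(p_anova),
        "tukey_p": tukey_p,
        "letters": letters,
        "degenerate": degenerate,
    }


def per_plant_rates(
    table: pd.DataFrame,
    stages: pd.DataFrame,
    response: str = "brix",
    interval: tuple[str, str] = ("R1", "R3"),
    window: tuple | None = None,
    degree: int | None = None,
    margin: float = 8.0,
    ci_formula: str = "ratio",
) -> pd.DataFrame:
    """Per-plant accumulation rate over a reference interval, per class.

    Fits each plant's class-mean trajectory separately, inverts for the two
    interval references and forms ``(ref_hi - ref_lo) / (t_hi - t_lo)``.
    Feeds ``compare_rates``.
    """
    if window is None:
        window = DEFAULT_FIT_PARAMS[response]["window"]
    if degree is None:
        degree = DEFAULT_FIT_PARAMS[response]["degree"]
    ref_col = "brix_ref" if response == "brix" else "ci_ref"
    refs = stages.set_index("stage")[ref_col]
    rows = []
    for (cls, plant), sub in table.groupby(["class", "plant"]):
        try:
            fit = fit_ripening_curve(sub, cls, response, window, degree, ci_formula)
            t0 = days_to_reference(fit, float(refs[interval[0]]), margin=margin)
            t1 = days_to_reference(fit, float(refs[interval[1]]), margin=margin)
        except ValueError:
            continue  # plant trajectory too noisy to invert; drop from ANOVA
        if t1 <= t0:
            continue
        rate = (float(refs[interval[1]]) - float(refs[interval[0]])) / (t1 - t0)
        rows.append({"class": cls, "plant": plant, "response": response,
                     "rate": rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# small utilities
# ---------------------------------------------------------------------------

def equivalent_stage_ratio(values_gs, values_rs):
    """Element-wise GS/RS ratio of analyte levels at equivalent stages."""
    gs = np.asarray(values_gs, dtype=float)
    rs = np.asarray(values_rs, dtype=float)
    if np.any(rs <= 0):
        raise ValueError("RS (denominator) values must be positive")
    out = gs / rs
    return out if out.ndim else float(out)


def between_class_spread(
    table: pd.DataFrame, day: float, response: str = "brix",
    ci_formula: str = "ratio"
) -> float:
    """Range (max - min) of class-mean response at one sampling day."""
    sub = table[table["day"] == day]
    if sub.empty:
        raise ValueError(f"no samples at day {day}")
    vals = _response_values(sub, response, ci_formula)
    means = vals.groupby(sub["class"]).mean()
    if len(means) < 2:
        raise ValueError(f"need >= 2 classes at day {day}")
    return float(means.max() - means.min())
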