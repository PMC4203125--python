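# Methods

This note documents the models implemented in `ripesync`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Study design being modelled

A véraison grape cluster contains berries at distinct ripening states —
green hard (GH), green soft (GS), pink soft (PS), red soft (RS) — that
converge to a common state at maturity. The design has two arms:

* **Expression**: GS/PS/RS berries sampled per tissue (pulp, skin, seed)
  at mid-véraison (V) and five weeks post-véraison (PostV), pooled per
  replicate plant (default 3 plants), giving a paired three-class,
  two-stage layout on the log2 scale.
* **Physiology**: all four classes tracked weekly (days 0, 7, 14, 21, 35,
  42) for total soluble solids (°Brix), colorimeter L/h/C readings, and
  elasticity, with ~30 berries per class per timepoint across 6 plants.

## Moderated paired differential expression

Within one (tissue, stage) block and class pair, per-gene paired
differences `d_gr` across replicate plants give the mean `m_g`, the sample
variance `s_g²` with `d = n−1` df, and the ordinary paired *t*. Because n
is small (3), per-gene variances are unstable; they are shrunk toward a
pooled prior under the standard hierarchical model `s² ~ s₀²·F(d, d₀)`.
`(d₀, s₀²)` are estimated by method of moments on `z = log s²`:

* `Var(z) − ψ′(d/2) = ψ′(d₀/2)`, solved for `d₀` by Newton on the inverse
  trigamma (if the left side is ≤ 0, `d₀ = ∞`: complete shrinkage);
* `log s₀² = mean(z) − [ψ(d/2) − log(d/2)] + [ψ(d₀/2) − log(d₀/2)]`.

The moderated statistic uses the posterior variance
`(d₀·s₀² + d·s²)/(d₀ + d)` and `d₀ + d` total df. With `d₀ = 0` it reduces
exactly to the ordinary paired *t* (tested against `scipy.stats.ttest_rel`
and an exhaustive sign-flip enumeration); the full procedure is tested
against a frozen run of an independent reference implementation of the
same moderation scheme on a synthetic fixture (agreement to 1e-6).
Genes with zero variance everywhere fall back to the pooled prior rather
than producing infinite statistics. Multiple testing uses
Benjamini–Hochberg step-up within each (tissue, stage, pair) family;
a gene significant in any of the three pairs at FDR < 0.05 enters the
differentially-expressed universe.

Pairing is by replicate plant: berries are pooled per plant, so the plant
is the only meaningful pairing unit.

## Reduction in variance (RV)

Per gene and tissue, the between-class variance is the sample variance
(denominator k−1 = 2) of the three class-mean log2 expressions, computed
independently at V and PostV; `RV = var_V / var_PostV`. Because the
variance is defined on class means, the natural reference distribution for
the ratio under no synchronization is F(2, 2), and the one-sided p-value
`P(F(2,2) > RV)` tests for variance *reduction* only. Defaults: df (2, 2)
(overridable), FDR threshold 0.2 — deliberately liberal, as a variance
ratio on 2 and 2 df has little power. `RV = 1` at df (2,2) gives p = 0.5
exactly (the median of F(d,d) is 1).

Degenerate folds (PostV variance exactly 0) are reported as infinite and
flagged, and excluded from distribution summaries; the summary reports
mean, median, quartiles and the fold bins ≤10, 10–20, >20, ≤100.
Note that the per-gene fold is approximately `target · F(2,2)` even when
every gene shares one true fold: F(2,2) has no finite mean, so the
*sample mean* of folds is heavy-tail dominated and lands well above the
generating fold — the distribution's location is read from the median
(the F(2,2) median is exactly 1). Generator-truth checks therefore
compare the median, not the mean, against the configured fold.

The RV-vs-variance ranking comparison (`rank_overlap`) takes the top-n
(default 100) genes by RV fold and by véraison variance, breaking ties by
gene id, and reports the overlap fraction.

## Transcriptional distances

With class-stage means `μ(c, s)` per gene:

```
a = μ(PS,V) − μ(GS,V)        x_obs = μ(GS,PostV) − μ(GS,V)
b = μ(RS,V) − μ(PS,V)        y_obs = μ(PS,PostV) − μ(PS,V)
z = μ(RS,PostV) − μ(RS,V)    x_calc = a + b + z,  y_calc = b + z
```

All on the log2 scale (a fold-change export applies 2^value). The
identity `x_calc − x_obs = μ(RS,PostV) − μ(GS,PostV)` holds for any input
by rearrangement; it is enforced to 1e-12 in property tests and is the
reason the observed-vs-calculated regression measures synchronization:
its residuals are exactly the PostV class-mean gaps. `linearity` fits OLS
of calculated on observed (R² is symmetric in the choice of axes for the
centered fit, so the headline metric does not depend on that convention).
The default gene universe is the V-stage DE union; a full-transcriptome
mode is available.

## Expression trends

The trend contrast compares the mean of all PostV samples with the mean
of the véraison RS samples using a pooled-variance two-sided t per gene
and BH FDR within tissue: significant-positive = "up",
significant-negative = "down", otherwise "plateau" (the gene completed
its ripening change by the RS stage, i.e. synchronized early post-
véraison). A per-class mode tests each PostV class against véraison RS
separately. The RV cross-tabulation reports trend proportions within the
high-RV (>20-fold) and low-RV (<10-fold) strata.

## Ripening kinetics

Colour index is `CI = 180·h/(L+C)` by default; the alternative literal
reading `180·h/L + C` is selectable (`formula="literal"`) since the
printed expression is ambiguous — the synthetic data are self-consistent
under either choice.

RS class means at days 0/7/14/21 define reference stages R1–R4 for both
°Brix and CI (strictly increasing required). Per class, the class-mean
response vs day is fitted by least-squares polynomial and inverted by
bracketed root-finding (Brent, 1e-6 d) for the earliest crossing of each
reference value, searching the fit window extended by a bounded margin
(default 5 d). Fits that are non-monotone on the window are rejected
rather than inverted. Fit defaults are response-specific:

* °Brix: degree 3 on days 0–35 (five sampled days). The cubic halves the
  inversion bias of a quadratic (≈0.10 vs ≈0.18 d noise-free) because the
  sugar curve bends smoothly through the whole window.
* Colour index: degree 2 on days 0–21. The colour trajectory has a flat
  pre-ripening plateau for deeply lagged classes that higher degrees
  overfit into non-monotone wiggles.

A 14-day per-class window starting at each class's own R1 day would
mirror the curve-alignment idea most literally, but with weekly sampling
such a window contains at most two distinct days — under-determined for
any quadratic — so one window per response is fitted instead and
`days_to_reference(R1)` itself supplies each class's start day. Lags are
`day_to_reference − RS day` per stage, reported raw and rounded half-up
to whole days; the headline lags come from the °Brix response.
Accumulation rates are `Δreference / Δdays` between consecutive stages;
per-plant rates (each plant's trajectory fitted separately) feed a
one-way ANOVA with Tukey HSD (α = 0.05) and a compact letter display
(insert-and-absorb). Equivalent-stage ratios (`GS/RS` per stage) and the
between-class range of class means at a day complete the module.

## Synthetic-data generator

**Expression.** Per gene: baseline `μ ~ N(8, 2²)` log2 units; véraison
gaps `a, b ~ N(0, effect_sd_v²)` (default 1.0 log2) give class means
`(μ, μ+a, μ+a+b)` for GS/PS/RS; a trend label (up/down/plateau, default
equal thirds) shifts the common PostV target `μ+a+b±trend_effect`
(default 1.0 log2); per-class PostV residuals `e_c ~ N(0, s²)`; replicate
noise `N(0, residual_sd²)` (default 0.25 log2) on every sample.

The PostV residual scale is calibrated against the *measured*
between-class variance: class means carry sampling noise `ν = σ²/n`, so
`s² = max(0, (var_V + ν)/target − ν)` makes the empirical variance ratio
match `rv_fold_target` (default 24) in expectation. Calibrating on the
true residuals instead would inflate the measured PostV variance by ν —
comparable to `var_V/24` at these settings — and bias the realized fold
to roughly half the target. Genes whose véraison variance is too small
for the target to clear the noise floor get `s² = 0` (exact
synchronization for that gene). An `exact_sync` flag forces `s² = 0`
globally; with `residual_sd = 0` as well, PostV class means are exactly
equal and the distance R² is 1 to machine precision. Optional knobs
(`rv_fold_sdlog`, a median-preserving lognormal spread of the per-gene
fold target, and `up_rv_multiplier`, a fold multiplier for up-trend
genes) are off by default and exist to exercise the trend-by-RV coupling.

**Physiology.** One common monotone logistic per response,
`f(t) = floor + (asym − floor)·σ(rate·(t − m))` with `m` set so
`f(0) = start` exactly; each class evaluates it at `t − lag`
(lags 13/10/7/0 d for GH/GS/PS/RS). Defaults: °Brix floor 0.5, start 12.6
(the R1 reference), asymptote 20.2, rate 0.08 /d; colour index is the
same shape rescaled (start 3.4, the R1 colour reference), so sugar and
pigment progress concomitantly. These values make the curve concave over
the sampled window: the class spread is ≈5 °Brix at day 0, shrinks
monotonically, and is ≈1.2 °Brix by day 35 — convergence through
saturation. L and C are emitted as near-constants (32, 8) and the hue
angle carries the colour signal, `h = CI·(L+C)/180`, so the colour-index
operation recovers the intended CI exactly. Per-measurement noise
defaults to 0.15 °Brix (CI noise scaled by the curve-range ratio): the
package's stated calibration is that the prescribed lag estimator
(class-day means of 30 berries, polynomial inversion) recovers the
generating lags to within 0.5 d at default settings, and the estimator's
error budget fixes the admissible noise at about this level. It should be
read as measurement-level repeatability: plant and cluster strata are
deliberately collapsed into this single term.

**What the generator does *not* emulate**, and hence what passing tests
do not show about real data:

* The pure time-shift physiology model means every class covers the same
  curve segment between equivalent stages — equal accumulation rates and
  stage-independent lags. Real under-ripe berries ripen *faster* between
  equivalent stages (lags shrink from 7/10/13 d at R1 to 1/3/5 d at R3);
  that behaviour enters the package only through the published
  days-to-reference values used as direct inputs to `lag_table`.
* Berry-to-berry, cluster and plant variance strata are a single noise
  term; real between-plant variation is substantially larger than the
  default noise.
* Expression is generated directly on log2 scale with Gaussian residuals:
  no probe/array-intensity model, no normalization artefacts, no
  mean-variance trend across expression levels.
* Trend effects are a single symmetric shift magnitude, not a
  distribution of effect sizes.

## Numerical choices

* Single pseudorandom stream per run seeded from the config; named
  SeedSequence substreams per tissue/component (CRC32 of the name), draws
  vectorized across genes. Identical configs give byte-identical outputs.
* BH adjustment via `statsmodels.stats.multitest`; Tukey HSD via
  `statsmodels pairwise_tukeyhsd`; both validated in tests against the
  step-up definition and a permutation oracle respectively.
* Root-finding tolerance 1e-6 d; earliest crossing taken when a
  polynomial recrosses within the extended window (monotone fits reach a
  value once; earliest is the physically meaningful time).
* Inversion margins are kept small (5–8 d) because extrapolated
  polynomials can recross far outside the data support.
* Zero-variance degeneracies: paired tests fall back to the pooled prior;
  `compare_rates` flags zero within-group variance with unequal means and
  reports letters with a degenerate p; 0/0 variance ratios are NaN and
  flagged.
* Problem sizes in tests and the acceptance script follow the study
  conditions (2000 genes, 3 replicates, 30 berries/class/week); the
  distance-linearity bound is evaluated as the minimum over 10 seeds.

## Known limitations

* The F(2,2) reference for RV assumes the three class means are
  independent and homoscedastic at both stages; the generator's véraison
  structure (cumulative gaps a, a+b) violates exchangeability mildly, so
  null-uniformity is exact only under the no-effect null used in the
  calibration tests.
* Trend calls treat all PostV samples as one group; residual between-class
  differences at PostV inflate the pooled variance slightly (conservative).
* The kinetics inversion is only as good as the polynomial approximation
  of the underlying trajectory; outside days 0–35 (Brix) / 0–21 (CI) it
  extrapolates and should not be trusted beyond the stated margins.
* `compare_rates` assumes balanced-ish group sizes for the studentized
  range; heavily unbalanced per-plant rate tables reduce the Tukey
  approximation quality.
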