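# Methods

## The measurement model

Extracellular flux analysis (EFA) reports, per well of a 96-well plate and
per ~6-minute measurement cycle, an oxygen consumption rate (OCR,
pmol O₂/min) and an extracellular acidification rate (ECAR, mpH/min).
`fluxstress` works from this "level-2" output; raw O₂-tension and pH
transients, and vendor-software export dialects, are out of scope. Plate
runs travel as a pair of long-format CSVs (per-cycle records + per-well
metadata) defined in `plate.py`.

**Mitochondrial stress test.** Eleven cycles in four phases (3/3/3/2)
around injections of oligomycin (or plain medium), the uncoupler FCCP,
and rotenone + antimycin A. Cycle selection follows the established
empirical convention: last two cycles of the pre- and post-first-injection
phases, first cycle post-FCCP, both cycles post-rot/AA. After per-cycle
blank subtraction and scaling to 10⁴ cells, each well yields

- non-mitochondrial OCR = post-rot/AA,
- basal respiration *B* = pre − post-rot/AA,
- maximal respiration *MR* = post-FCCP − post-rot/AA,
- spare respiratory capacity *SRC* = *MR* − *B*,
- ATP-linked respiration = pre − post-oligomycin (CV-inhibited arm only),
- proton leak = post-oligomycin − post-rot/AA (same arm).

*SRC* is implemented as *MR* − *B* (equivalently post-FCCP − pre). The
literal textbook phrasing "FCCP OCR minus basal" would retain
non-mitochondrial OCR in *SRC*; the figure arithmetic and standard
practice subtract it. The literal variant is available via
`src_literal=True`.

**The confound statistic.** Inhibiting ATP synthase (complex V, CV) with
oligomycin before uncoupling depresses the apparent *MR* in intact cells.
Running the test in paired arms — with oligomycin (CV_INHIBITED, FCCP
2 µM) and with a medium injection instead (CV_FREE, FCCP 3 µM) — gives the
percent underestimation

U = 100 · (value_CV-free − value_CV-inhibited) / value_CV-free

for *MR* and *SRC*. Pairing is at the experiment level: both arms share a
plate within an experiment, arm means over technical replicates are
compared per (experiment, condition), and aggregation across experiments
happens downstream. (Per-experiment-then-average was chosen over
grand-mean ratios; it matches "mean ± SEM of N independent experiments"
reporting.) If u is the fraction of true MR suppressed by CV inhibition,
the noise-free identities are U_MR = 100u and
U_SRC = 100·u·MR/(MR − B) — SRC amplifies the confound because the
(unaffected) basal term is subtracted from an underestimated MR.

**Glycolysis stress test.** Fourteen cycles in five phases (2/3/3/3/3)
around glucose, rotenone + antimycin A, monensin + FCCP, and 2-DG. ECAR
converts to a proton efflux rate PER = ECAR · BF · V · K_vol with
buffering factor BF = 2.4 mmol H⁺/L/pH (the medium's experimentally
determined value), microchamber volume V = 2.28 µL and volume scaling
K_vol = 1.6 (the analyzer vendor's published 96-well constants; they are
absent from the source study, and every reported quantity is a fold or
difference, hence invariant to this scale). Mitochondrial CO₂/bicarbonate
acidification is removed with the CO₂ contribution factor CCF = 0.61:
mito PER = CCF · max(phase OCR − post-rot/AA OCR, 0) before the rot/AA
injection and 0 after; glycolytic PER is the remainder. The clamp at zero
exists because blank noise can push a phase OCR below the post-rot/AA
level, and negative mitochondrial CO₂ production is unphysical. CCF is
assumed dose-independent.

Parameters: basal acidification (pre-glucose glycolytic PER), basal
glycolysis (post-glucose − pre-glucose glycolytic PER), ATP-demand-limited
glycolysis (post-rot/AA − pre-glucose **total** PER — the assay definition
says PER, not glycolytic PER, for this parameter; a glyco-only variant is
a config switch), maximal glycolytic capacity (post-monensin/FCCP −
pre-glucose glycolytic PER), glycolytic reserve (capacity − basal
glycolysis), and a 2-DG residual. The residual is computed on glycolytic
PER on both sides: on total PER the pre-glucose mitochondrial CO₂ term
(CCF·basal mito OCR) would survive as a spurious residual even when 2-DG
returns glycolysis exactly to baseline, defeating the quantity's purpose
as a glucose-dependence check.

**ATP production rates.** Mito ATP = ATP-linked OCR × 2 O/O₂ × P/O with
P/O = 2.75 (vendor convention; consistent with the study's own printed
slope ratio, mito-ATP slope / coupled-OCR slope ≈ 5.6 ≈ 2 × 2.75). Glyco
ATP maps 1:1 from ATP-demand-limited glycolytic PER (one ATP per lactate
per extruded H⁺); the source study's Methods name demand-limited
glycolysis while its Results mention basal glycolysis — the Methods
definition is the default, `glyco_atp_source="basal_glycolysis"` selects
the other. Because the two stress tests come from separate runs (and
possibly separate experiment sets), mito and glyco branches are aggregated
independently and the condition total is the sum of condition means.

## Statistics

Wells are technical replicates; experiments (n = 3–4) are the units of
analysis. Outliers are removed with Tukey's fences (k = 1.5, linear
interpolated quartiles; lists shorter than 4 pass untouched) at the
technical level (per-well derived parameters within experiment × condition
× arm — fencing parameters rather than raw cycles avoids distorting
traces) and at the experimental level (per-experiment means across
experiments). Summaries are mean ± SEM across experiment means.
Homoscedasticity is checked with the Brown–Forsythe variant of Levene's
test; normality is assumed. Dose-response slopes use OLS with an
F(1, n−2) test on the slope. Group comparisons: one-way ANOVA with
Dunnett's post hoc (each dose vs control; adjusted p from the
equicorrelated multivariate-t via `scipy.stats.dunnett`, seeded) and
two-way arm × condition ANOVA with Tukey–Kramer HSD over cell means
(studentized-range p via the table-interpolated `psturng`, accurate near
α = 0.05 and clipped to [0.001, 0.9]). Effect sizes are Cohen's d with the
normal-theory 95% CI, SE_d = √((n_a+n_b)/(n_a n_b) + d²/(2(n_a+n_b−2))).

The qualitative confound contrasts (is the 72-ppm change in MR/SRC
significant in each arm?) are evaluated as the Tukey cell-mean contrasts
of the two-way design, matching the analysis the claims derive from.

## The synthetic-data generator

The generator emulates the study design: per experiment one 96-well
plate; 7 conditions (control, Ni²⁺ at 6/12/24/48/72 ppm, LPS 1 µg/mL);
sextuplicate wells per condition and arm; 4 blank wells; 4 experiments
(3 for the ATP scenario); nominal 24 000 cells/well.

Ground truth per condition: non-mito OCR, basal mito OCR, leak fraction
λ, true MR, the underestimation fraction u, and glycolytic phase targets.
Absolute control magnitudes (non-mito 8.0, basal 34.0, MR 81.0, λ = 0.15,
ATP-linked 28.9 pmol O₂/min/10⁴ cells; glycolytic basal/demand/capacity
24.0/24.2/60.0 pmol H⁺/min/10⁴ cells) are fixture constants — the study
prints only ratios, percentages, folds and slopes, so the constants were
chosen once such that each printed scale-invariant quantity is reproduced
exactly in the noise-free limit: u = 0.56 at control declining by
0.005/ppm Ni (0.20 at 72 ppm), MR declining 33% at 72 ppm, ATP-linked OCR
declining 0.14/ppm, glycolytic parameters rising to 3.3-fold at 72 ppm and
with LPS, LPS MR = 42% of control with u = 0. The control glyco/mito ATP
ratio is 0.152, which pins the Ni-sweep identity "total ATP ≈ constant";
with the shared control this fixes the LPS total-ATP fold at
(0.90 + 3.3·0.152)/1.152 ≈ 1.22 (the printed value is 1.3 ± 0.2 — a single
control cannot simultaneously satisfy the 0.20 glyco/mito ratio implied by
the LPS panels).

Noise model (hierarchical, multiplicative between units, additive within):
experiment effect E ~ LogNormal(0, σ_exp = 0.10), well effect
W ~ LogNormal(0, σ_well = 0.06), cell count N ~ Normal(nominal,
0.10·nominal) rounded, and per-cycle additive noise with
SD = max(0.5, 2% of the well-level rate); blank wells are
Normal(0, 0.5). For the ECAR channel the additive floor and blank SD are
expressed in PER units and divided by BF·V·K_vol, so both channels carry
equivalent noise (0.5 mpH/min would be ~17% of a typical ECAR value, which
no functioning instrument exhibits). σ defaults were chosen to reproduce
between-experiment SEMs of roughly 3–12% of the mean, the magnitude
reported for this assay's group means. Each recorded cycle is
true_rate · E · W · (N/10⁴) + noise; the metadata records the same N, so
per-cell normalization is exact up to the additive noise. One RNG stream
per run, seeded from (scenario seed, experiment id, protocol kind), makes
every run independently reproducible.

What the generator does **not** emulate: raw sensor transients and drift,
plate-edge effects, injection-vehicle effects, FCCP titration error,
condition-dependent cell loss (available as an optional per-condition
cell-count multiplier, off by default), and — importantly — the full
between-experiment dispersion of the original data's *contrast* statistics.
The lognormal experiment effect is shared by all wells of a plate, so it
cancels in within-experiment contrasts (underestimation, folds); passing
tests therefore show pipeline correctness and calibration of the *printed
group-level* quantities, not that real data of this design would reach the
same inferential conclusions. In particular the original non-significant
contrasts (inhibited-arm MR across doses, free-arm SRC) imply larger
effective noise than the SEM-calibrated defaults produce, so the simulated
analysis is more powerful than the real one; under the default noise the
free-arm SRC decline (a fixed consequence of the anchored MR and
ATP-linked trends) is reliably detected rather than non-significant. The
replication driver (`analysis/04_confound_replication.py`) quantifies
exactly this.

## Numerical choices

- Representative phase value: arithmetic mean of the selected cycles
  (mean-vs-median is not specified anywhere authoritative; mean matches
  instrument-software convention). Blank aggregation: per-cycle mean,
  median behind `robust_blanks`.
- Negative blank-corrected rates are never clamped (clamping would bias
  non-mito estimates); a QC helper flags wells whose post-rot/AA OCR is
  below −2 SD of the blanks.
- Outlier fences set flagged values to NaN per parameter rather than
  dropping wells, so one aberrant parameter does not discard a well's
  other parameters.
- U is undefined (NaN, flagged) when the CV-free reference is 0; a
  condition missing one arm in an experiment is skipped with a warning.
- Dunnett adjusted p: scipy's randomized multivariate-t integration,
  seeded through the analysis config (tolerance ~10⁻³). Tukey HSD p:
  `psturng` table interpolation.
- Reports render deterministically (sorted-key JSON, fixed float
  formatting); identical inputs give byte-identical files.

## Problem sizes

Default analyses run one 96-well plate per experiment, 4 (confound) or
3 (ATP) experiments per scenario; the replication driver re-simulates the
confound scenario 100 times. These sizes mirror the emulated study design;
each full scenario analysis completes in roughly a second on one core.

## Known limitations

- Absolute rate levels are fixture conventions; only scale-invariant
  outputs are meaningful for comparison with the source experiments.
- The ATP budget mixes branches whose experiment sets may differ; the
  total is a sum of condition means and inherits both branches'
  uncertainties without a joint error model.
- Mixed-effects modelling of the well hierarchy is deliberately out of
  scope; experiment means are the observations, as in the emulated
  analysis.
- `psturng` p-values are clipped to [0.001, 0.9]; exact tail p-values for
  the Tukey contrasts are not reported.
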