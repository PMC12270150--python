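# fluxstress

Analysis of extracellular flux (Seahorse-type) stress tests, built around a
confound that standard practice overlooks: **inhibiting ATP synthase
(complex V, CV) with oligomycin — a core step of the mitochondrial stress
test — underestimates maximal respiration (MR) and spare respiratory
capacity (SRC) in intact cells, and test substances that shift cells
toward glycolysis change the size of that underestimation.** A treatment
effect measured under CV inhibition can therefore be masked or even
inverted. The package is aimed at cell-metabolism researchers who run
plate-based OCR/ECAR assays and want to quantify (or simulate) this
confound alongside the ordinary stress-test readouts.

## What it computes

From per-well, per-cycle OCR/ECAR traces (long-format CSVs):

- **Mitochondrial stress test** — blank correction, per-10⁴-cell
  normalization, phase-representative rates, and the six respiration
  parameters: non-mito OCR, basal *B*, ATP-linked, proton leak,
  *MR* = OCR_FCCP − OCR_rot/AA, *SRC* = *MR* − *B*.
- **The confound statistic** — paired ±CV-inhibition arms give the percent
  underestimation U = 100·(x_free − x_inhibited)/x_free of MR and SRC per
  condition, with the noise-free identities U_MR = 100u and
  U_SRC = 100·u·MR/(MR − B) for an underestimation fraction u.
- **Glycolysis stress test** — PER = ECAR·BF·V·K_vol (BF = 2.4
  mmol H⁺/L/pH, CCF = 0.61 for the mitochondrial CO₂ share) and the four
  glycolytic parameters (basal glycolysis, ATP-demand-limited glycolysis,
  maximal capacity, reserve) plus a 2-DG glucose-dependence check.
- **ATP production rates** — mito ATP = ATP-linked OCR × 2 × P/O
  (P/O = 2.75), glyco ATP = demand-limited PER, per-condition budgets and
  folds vs control.
- **Statistics** — Tukey-fence outlier removal at technical and
  experimental levels, mean ± SEM over independent experiments, one-way
  ANOVA + Dunnett, two-way ANOVA + Tukey HSD, Brown–Forsythe Levene,
  OLS slope F tests, Cohen's d with 95% CI.
- **Synthetic plate runs** — a seeded generator reproducing the study
  design (96-well plates, paired arms, sextuplicates, 3–4 experiments,
  Ni²⁺ 0–72 ppm and LPS conditions, hierarchical noise) for validation
  and power exploration.

## Worked example

```sh
python analysis/01_simulate_plates.py --seed 1        # write CSV plate runs
python analysis/02_mito_confound.py                   # paired ±CV analysis
python analysis/03_atp_budget.py                      # ATP production rates
python analysis/04_confound_replication.py --reps 100 # qualitative replication
```

The confound analysis prints (seed 1):

```
Percent underestimation caused by CV inhibition (mean over experiments):
  control: MR 55.9%  SRC 96.3%
  72 ppm Ni: MR 18.3%  SRC 31.3%
  U_MR vs Ni: slope -0.513 %/ppm (R2 0.97)
  U_SRC vs Ni: slope -0.896 %/ppm (R2 1.00)
MR change at 72 ppm: CV-free p=0.001, CV-inhibited p=0.51 -> masked=True
```

Read: in untreated cells CV inhibition hides ~56% of MR and ~96% of SRC
(SRC amplifies the bias because basal respiration is subtracted from an
underestimated MR). Ni²⁺ shrinks the underestimation roughly linearly with
dose, so the very same exposure that *decreases* true MR by a third looks
flat when the test is run with oligomycin — the Tukey contrast at 72 ppm
is significant only in the CV-free arm. The ATP analysis completes the
picture:

```
ATP production rate folds vs control:
  72 ppm Ni: mito 0.66, glyco 3.38, total 1.03
  LPS: mito 0.90, glyco 3.38, total 1.23
  mito ATP vs Ni: slope -0.756 pmol ATP/min/1e4 cells per ppm
```

i.e. Ni²⁺ trades mitochondrial for glycolytic ATP production at nearly
constant total — the glycolytic shift that accompanies (and presumably
drives) the shrinking underestimation.

Library use mirrors the scripts:

```python
from fluxstress import (scenario_mito_confound, simulate_experiment_set,
                        run_confound_analysis)

runs = simulate_experiment_set(scenario_mito_confound(seed=1), "MITO")
report = run_confound_analysis(runs)
print(report.underestimation)        # condition x parameter mean/SEM/n
print(report.dose_response["U_MR"])  # slope F test
```

`read_plate_run(cycles_csv, wells_csv, default_protocol("MITO"))` ingests
real exports in the same two-CSV dialect (see `plate.py` for columns).

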