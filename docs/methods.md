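# Methods

## The problem and the model

Diffuse-reflectance NIR quantitation of an analyte in a powder is
confounded by particle size. In the two-constant Kubelka-Munk description
of a semi-infinite scattering layer, reflectance satisfies
F(R) = (1 − R)²/2R = K/S; the scatter coefficient S is inversely related
to particle size, so coarser powder yields lower R and higher apparent
absorbance log(1/R). The effect is wavelength dependent: strongest in the
combination region (CR, 5000–4000 cm⁻¹), intermediate in the first
combination-overtone region (FCOT, 7100–5000 cm⁻¹), weak in the second
combination-overtone region (SCOT, 10000–7100 cm⁻¹). The package studies
two mitigations: scatter-correcting preprocessing, and a
*granularity-hybrid* (GH) calibration set that pools all sieve fractions
so the regression itself learns to discount the particle-size direction.

## Synthetic data generator

No measured spectra ship with the package; every experiment runs on a
generator that emulates the study design.

**What it emulates.** 90 samples (default) of one material, each divided
and sieved to 40/65/80/100 mesh (nominal openings 425/230/180/150 µm —
the standard sieve sizes), measured in triplicate on the instrument grid
10000–4000 cm⁻¹ at a 1.928 cm⁻¹ interval, stored descending. Reference
concentrations are drawn from a truncated normal with parent mean
3.695 mg/g and SD 1.452 mg/g clipped to [1.476, 8.162] mg/g; the
truncation is asymmetric, so the realised mean sits ≈0.19 mg/g above the
parent mean — the parent parameters are the configuration contract, not
the realised moments. The same concentration vector is shared by all four
mesh fractions of a sample (the material is identical; only fineness
differs).

**Spectral model.** Clean absorbance is a sloped baseline plus Gaussian
bands: five fixed matrix bands (O-H/C-H overtone and combination
positions typical of plant powders) and two analyte bands, at 5800 cm⁻¹
(FCOT) and 4400 cm⁻¹ (CR), with amplitude linear in concentration
(Beer-Lambert). The granularity effect is

    I(ν) = A(ν, c) · (1 + m·w(ν)·δ) + a·w(ν)·δ + ε,

with δ the relative particle-size deviation from a 250 µm anchor, w(ν) a
smooth (logistic-blended, 60 cm⁻¹ transition) region weight of
1.0/0.66/0.22 in CR/FCOT/SCOT, gain m = 0.08, offset a = 0.004, and
measurement noise ε ~ N(0, 0.002²) absorbance per replicate. The RSD of
intensity across the four classes is approximately w(ν)·SD(δ)·(m + a/A);
with SD(δ) ≈ 0.50 these magnitudes were chosen analytically to land the
region RSD near 0.045 (CR), 0.030 (FCOT) and 0.010 (SCOT) — inside the
conventional high/medium/low sensitivity bands — and are the package's
fixed defaults, not tuning knobs.

**What it does not emulate.** Real herb spectra have hundreds of
overlapping bands, heteroscedastic detector noise, moisture and
temperature drift, and matrix composition correlated with the analyte.
The synthetic spectra are far cleaner: local models reach RMSEP ≈ 0.01–
0.05 mg/g and RPD in the tens, an order of magnitude better than any real
assay. Passing tests therefore demonstrate that the *algorithms* recover
designed effects (region ordering, scatter-correction benefit, pooled-set
robustness), not that a real assay would reach any particular accuracy;
published RMSEP/R values for measured spectra are not reproducible from
synthetic data and are not targeted.

## Preprocessing

- **MSC**: per-spectrum OLS fit x ≈ a·ref + b, corrected (x − b)/a. The
  reference is the calibration-set mean spectrum, stored at fit time and
  reused on validation data; re-applying MSC against the stored reference
  is an exact identity (slope 1, intercept 0).
- **SNV**: per-spectrum standardisation with sample SD (n−1); constant
  spectra are rejected rather than returning NaN.
- **SG**: `scipy.signal.savgol_filter`, default window 11 / polyorder 2
  (common chemometrics defaults; unstated in most application papers,
  exposed in `PipelineParams`), edge handling by evaluating the terminal
  window's polynomial. Derivatives are with respect to wavenumber and
  divided by the physical step, so magnitudes are resolution independent
  and the sign is correct on descending grids.
- **ND**: centred segment moving average (default 5) then gap difference
  (default 5): first derivative (s̄ᵢ₊g − s̄ᵢ₋g)/(2g·Δν), second
  derivative (s̄ᵢ₊g − 2s̄ᵢ + s̄ᵢ₋g)/(g·Δν)²; edge points without a full
  gap are filled with the nearest valid value.
- **Pipelines**: labels parsed whitespace-insensitively; at most one
  scatter correction, one derivative order, one smoother. Order is
  scatter → derivative → smoother, with "1D + SG" executed as a single SG
  convolution at deriv = 1 (how the established commercial packages
  implement it; avoids double smoothing) and "1D + ND" as the Norris
  derivative filter itself. A bare derivative uses a gap-1 difference.

## Granularity analysis

Per-wavenumber RSD = sample SD (n−1) across the class-mean spectra
divided by their absolute mean — the standard relative-SD definition; the
denominator is applied to log(1/R), the quantity the sensitivity bands
describe. Points with across-class mean below 10⁻⁶ are flagged
unreliable and excluded from region summaries instead of producing huge
ratios. Regions tile the grid with boundary points assigned to the
lower-wavenumber region (7100 → FCOT, 5000 → CR) and the lowest region
keeping its endpoint (4000 → CR). Labels: mean region RSD < 0.015 low,
0.015–0.035 medium (the closed interval, so the 0.015–0.025 gap between
quoted bands is covered), > 0.035 high.

## Sample management

- **Kennard-Stone**: squared-Euclidean max-min greedy selection; the
  first pair maximises pairwise distance, later picks maximise the
  minimum distance to the selected set; every tie breaks to the lowest
  row index, making the split fully deterministic. By default the split
  is computed once on the raw averaged spectra and reused across the
  preprocessing grid, so all pipelines compete on the same validation
  set; `ExperimentConfig.split_on` accepts a pipeline label to split on
  preprocessed features instead.
- **Outlier screen**: the classical Dixon Q-test on the reference
  concentrations (gap/range, variant r10/r11/r21/r22 by n, two-tailed
  critical values after Rorabacher, *Anal. Chem.* 63 (1991) 139), default
  α = 0.05, iterating on the value farthest from the mean up to
  `max_removals` (default 1). For n > 30 — beyond the table — and on
  request (`variant="grubbs"`) the Grubbs test is used; the
  deviation-from-mean phrasing common in application papers actually
  describes Grubbs, so both are provided. Screening on concentrations
  (rather than spectral leverage or model residuals) is the literal
  reading of "deviation of a standard from the mean"; alternatives would
  require a fitted model before outlier removal.
- The "twenty concentration levels" style of leveled calibration design
  is not implemented (no defined procedure exists); splits target `n_cal`
  directly.

## PLS core

PLS1 by NIPALS on mean-centered X and y (no autoscaling by default —
standard for spectra, where channel variance carries information;
`scale=True` available). For one response the inner weight iteration
converges on the second pass; it is still bounded (tol 1e-12, 500
iterations). Rank exhaustion truncates the component set with a flag.
The regression vector B = W(PᵀW)⁻¹q reproduces the deflation-form
predictions to 1e-8 (tested).

PRESS(k) = Σᵢ(yᵢ − ŷ₋ᵢ,ₖ)² under leave-one-out by default — LOO is
deterministic and matches small-n chemometrics practice; contiguous or
seeded-shuffle k-fold are options. Each fold is fitted once at the
maximum LV and per-LV predictions are read off the component sequence,
which is numerically identical to refitting per k (tested to 1e-10).
RMSECV(k) = √(PRESS(k)/n).

LV selection: global PRESS minimum, ties to fewer components. When a
validation set participates, the anti-overfit guard applies: among LV
counts with RMSECV within 10% of the minimum, the smallest whose
|RMSECV − RMSEP|/RMSEP ≤ 10% wins, else the PRESS minimum stands. The
10% default quantifies the qualitative "RMSECV close to RMSEP" rule; it
is configurable. Note the guard consults validation error for model-order
choice — a deliberate reproduction of field practice; pipeline *ranking*
never does.

RPD = SD(y_val, n−1)/RMSEP. Sample SD with n−1 is used throughout — this
convention reproduces published RPD columns from their SD and RMSEP to
2 d.p. Perfect prediction reports RPD = ∞ with a flag; n_val < 2 reports
R and RPD absent.

## Workflows

Local models: per mesh class — screen, split, preprocessing grid (best
pipeline = lowest minimum PRESS, never lowest RMSEP, which would select
on the test set), LV selection, test-set validation. The cross-class
RMSEP matrix (every local model against every class's validation set) is
retained for robustness analysis. GH model: per-class screening and
splitting happen *before* pooling (each fraction keeps its own
representative split, and a pooled re-screen would let one fraction's
range mask another's outliers), then the four calibration subsets are
pooled — 4 × n_cal rows — and each pipeline's model is evaluated against
each class's validation set separately. Reports keep full precision;
display rounding (RMSE 3 d.p., R 4 d.p., RPD 2 d.p.) is an explicit
`rounded=True` render option so CSV round-trips are lossless.

The GH-vs-local comparison (`gh_vs_local_mean_rmsep`) fixes a single
shared pipeline, default RAW: the property under study is the
calibration-*set* design, and scatter correction would remove most of the
very effect whose handling is being compared. Both model families see
identical preprocessing, so the contrast is fair.

## Problem sizes and numerical choices

Tests and the acceptance script run on a reduced grid (step 15.424 cm⁻¹,
390 points — every 8th instrument channel; band structure is fully
resolved at this spacing) with 30 samples per class and n_cal = 20,
20 seeds per stochastic property; these sizes give stable pass/fail
behaviour at interactive runtimes. Degenerate inputs are rejected with
messages (zero-variance y or MSC reference, constant spectrum under SNV,
non-physical reflectance, concentration ranges with min ≥ max);
grid point counts use a ½-ulp-tolerant floor so CSV round-trips cannot
drop the last channel.

## Known limitations

- The granularity effect is linear in particle size with a fixed spectral
  weight; real scatter also changes band shapes and baselines
  nonlinearly.
- The Dixon critical-value table covers α ∈ {0.10, 0.05, 0.01} only.
- PLS1 only (single analyte); no SIMPLS/kernel variants, no
  wavelength-interval selection.
- JCAMP-DX support is the minimal fixed-step `(X++(Y..Y))` AFFN profile,
  single spectrum per file.
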