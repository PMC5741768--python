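# Methods notes

This note documents the statistical model, the numerical choices, and the
design decisions behind `sleepspec`, including what the synthetic cohorts do
and do not emulate.

## Spectral estimation

Windows are 4 s with 2 s steps, Hann-tapered, per-window demeaned before
tapering (suppresses DC leakage into the lowest bins). The 4 s length gives
exactly 0.25 Hz resolution, so the 1–40 Hz analysis grid (157 bins,
inclusive endpoints) maps onto FFT bins 4..160 with no interpolation; a
sampling rate whose 4 s window is not an integer sample count, or whose
native resolution differs from 0.25 Hz, is rejected rather than resampled.
One-sided Welch density scaling (`2/(fs·Σw²)`) is used; any constant factor
cancels in relative power. Windows are confined to maximal runs of
artifact-free 4 s segments *within a single epoch*: the artifact grid makes
a crossing window partially contaminated, and bridging two epochs of the
same stage would mix visually distinct stretches of sleep — so a clean 20 s
epoch yields at most 9 windows (2k−1 windows per k-segment run).

Relative log power floors exactly-zero bins at 10⁻¹² × the row maximum
(with a warning) before taking log₁₀; the antilogs of each channel's 157
values sum to 1 by construction.

## Calibration

The amplitude of a recorded calibration sinusoid is estimated by
least-squares fit of `a·cos + b·sin + c` at the known frequency (amplitude
`√(a²+b²)`). This is leakage-free for sweep frequencies that fall between
FFT bins, which most of the grid does; an FFT-peak readout would not be.
Ten cycles are required, relaxed to 4 s below 2.5 Hz. Rates from the 40 and
355 μV runs are averaged per frequency; a single-run frequency is accepted
with a warning; rates outside (0, 2] abort (implausible hardware). The
interpolant is a natural cubic spline — exact at the grid knots, smooth in
between; on a first-order high-pass response it is accurate to < 1 % over
1–40 Hz. Power correction divides by the squared rate. The sweep grid
(0.05 Hz; 0.1–2 Hz by 0.1; 2–20 Hz by 1; 10–100 Hz by 10) contains an
overlap between its segments as specified; the union of the lists is used.

## Scoring

RES unifies two tests: an APM raw score is its own RES; a CFT raw score is
converted CFT → IQ (age-banded table, linear interpolation within a band)
→ percentile (normal IQ distribution, mean 100, SD configurable, default
15) → the APM raw score at that percentile (monotone table, linear
interpolation, ties resolved toward the lower raw score); with both tests,
the two RES values are averaged. Published norm tables are copyrighted and
are therefore pluggable CSVs; the shipped `synthetic_norms()` tables are
monotone but entirely invented, for testing only.

## Correlation maps and sex comparisons

The partial correlation is computed as the Pearson correlation of
least-squares residuals after regressing both variables on [1, age]; QR is
used for the projection (numerically stabler than normal equations), and a
residual norm below 10⁻⁸ of the centered norm marks the cell undefined
(e.g. a variable identical to the covariate). Degrees of freedom are n−3
(one covariate); all tests are two-tailed. Cells use listwise deletion per
electrode — a subject missing one electrode still contributes everywhere
else — and cells with fewer than 5 subjects are reported missing.

The Fisher comparison uses the ordinary `1/(n−3)` variance for each
transformed correlation even though the correlations are partial; with one
covariate the refinement `1/(n−4)` changes z in the second decimal at these
sample sizes, and the simpler form is the one conventionally reported with
this method's name.

## Multiple-comparisons control

**Rüger areas.** "From the first to the last significant bin" is
implemented as *maximal contiguous runs* of bins containing ≥ 1 significant
cell — several disjoint areas per map are possible, which matches how such
results are reported in practice. Areas spanning < 4 bins (< 1 Hz) or with
all significant cells on one electrode are discarded as narrow-band
artifacts/outliers. The decision thresholds use the exact fractions α/2 and
α/3 (0.05/3 = 0.01667, not the rounded 0.016). Member-cell fractions are
computed over cells, not electrode-collapsed bins. The maximal-association
cell breaks |r| ties toward lower frequency, then montage order.

An important operating characteristic, measured on simulated null cohorts:
among truly null cells significant at α, the fraction below α/2 is 1/2 in
expectation, so a qualifying null area passes the decision rule with
roughly coin-flip probability, and a cohort-level false-area rate near 75 %
results. The Rüger rule is a *weak* screen, not family-wise control —
which is why the pipeline's headline findings (`RunReport.
corroborated_areas`) require a Rüger-significant area to overlap a
permutation-significant range.

**Permutation (rmax).** Both trait and spectra are residualized on age;
each permutation shuffles the subject labels of the trait residuals and
records the maximum |r| over the family. The +1-offset estimator keeps
corrected p ≥ 1/(n_perm+1). Two families are supported: `bin` (electrodes
within each frequency bin — the default, matching the method's usual
description for this design) and `grid` (all cells). The `bin` family
controls the FWER within each bin only; across 157 bins it still passes
spurious ranges, so specificity claims and the acceptance checks use the
`grid` family, which controls the FWER over the whole search space (null
familywise rejection ≈ 5 %, measured). The permutation engine requires a
seed in strict mode; identical seeds give bit-identical p-values.

Missing channels are imputed before permutation on the 12-channel montage
(temporal-arc electrodes dropped — they lack neighbours on one side):
Fz ← mean(F3, F4), Cz ← mean(C3, C4), otherwise the mean of available
configured neighbours, on relative log-power values. Averaging in log
space slightly breaks the antilog normalization of imputed channels; no
renormalization is applied, since a per-subject rescaling of one channel
would perturb the cross-subject correlations the procedure feeds on.

## Synthetic cohorts

The generator emulates the reference design: 68 females / 83 males, ages
uniform 17–69, 18-electrode 10–20 montage with 26 electrode failures
assigned to random subjects (frontopolar sites worst), a trait declining
with age (−0.35 SD/SD), an age trend on power (low-frequency gain,
high-frequency loss, ±0.075 log₁₀ units/SD), and female-only planted
effects at ρ = ±0.45 (REM delta/theta negative, REM beta positive, NREM
alpha/sigma positive). ρ = 0.45 is a simulation choice giving realistic
desk-scale power at n = 68, not an empirical value.

Spectra are generated directly in relative log₁₀-power space: a state-
specific mean profile (power-law decay, sigma bump in NREM), plus a
Gaussian field smooth across electrodes (exponential kernel on head
positions, length 1.5 head-radii) and bins (exponential kernel, length
5 Hz), with per-cell SD 0.15 log₁₀ units. These smoothness defaults
reflect real relative log sleep spectra, where neighbouring bins and
electrodes correlate highly and the 1–40 Hz spectrum has few effective
dimensions. The trait factor loads on planted cells so that the
model-implied age-partial correlation equals ρ.

Renormalization (antilogs sum to 1) interacts with planted effects: to
first order, the power-share-weighted mean of log relative power is
constant, so *no* loading pattern with a nonzero weighted mean survives —
a planted band correlation mechanically forces a complement of opposite
sign in the remaining bins. The generator therefore (a) constrains the
noise field to preserve total power while keeping unit per-bin variance
(alternating projection/rescaling, tracked analytically on the spectral
covariance), and (b) assigns the first-order-achievable loading: the
planted ρ on planted cells and the exact complement spread uniformly over
the electrode's remaining bins. Measured at n = 4000, planted cells
recover r within ~2 % of ρ; the off-band complement is small for
low-power-share bands (beta) and up to ~0.15 for the power-heavy
delta/theta band — which is also what sum-constrained real data would
show. `GroundTruth.rho_maps` stores the full achieved loading maps.

What the cohorts do **not** emulate: real EEG time series (spectra are
generated directly; raw-signal fixtures are separate sinusoid+1/f-noise
constructions), realistic sleep architecture, non-Gaussian spectral
variability, inter-night variability, or device differences beyond the
calibration module's analytic filters. Passing tests therefore demonstrate
the statistical machinery's operating characteristics under a smooth
Gaussian model, not performance on real recordings.

## Problem sizes used in checks

The Monte-Carlo checks use sizes chosen to give stable estimates at
interactive cost: the null FWER runs 400 cohorts of n = 60 at 1000
permutations over the 10-electrode × 157-bin grid family (binomial SE
≈ 0.011 at the nominal 0.05); power/specificity runs 100 cohorts of the
full 151-subject design at 1000 permutations; window-planning equivalence
runs 1000 random hypnogram/mask cases against a brute-force enumerator;
Rüger-detector equivalence enumerates 65 536 canonical 3 × 8 significance
patterns plus 2000 random ones against an independent oracle.

## Known limitations

- EDF support is plain EDF (16-bit, one-second records); EDF+ annotations
  are out of scope.
- The spectral pipeline assumes recordings already re-referenced to linked
  mastoids; no re-referencing is applied.
- No FDR, cluster-mass or TFCE alternatives; no Spearman variant.
- The Rüger procedure is reported faithfully but is intrinsically a weak
  screen (see above); interpret uncorroborated areas accordingly.
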