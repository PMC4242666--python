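# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the limitations of `casr_coop`.

## Oscillation-pattern quantification

Single-cell traces are ratiometric fluorescence time series on a uniform
grid, bound to a stepwise [Ca²⁺]ₒ protocol (strictly increasing step start
times, non-decreasing Ca²⁺, fixed L-Phe per protocol). The three pattern
parameters are computed from called peaks:

* **Peak calling.** The trace is smoothed with a moving average
  (default window 5 s, edge-preserving), and local maxima are kept if
  their prominence exceeds k× a robust noise SD (default k = 3) with a
  minimum separation of 10 s. The noise SD is the Gaussian-scaled median
  absolute deviation of the first-difference signal divided by √2:
  differencing removes slow trends, the MAD ignores the sparse spikes, and
  the √2 corrects for the variance doubling of differenced white noise.
* **Oscillatory classification.** Within one step's dwell, the first peak
  is treated as the concentration-step transient and discarded; the cell
  oscillates at that step iff ≥ 3 peaks remain. This "count after the
  initial peak" rule is applied *per step*, because every step change
  elicits its own transient.
* **Starting point** = lowest step concentration whose window classifies
  as oscillatory (ties between adjacent steps resolve to the lower
  concentration). **Frequency** = qualifying peaks per minute at a
  *caller-designated* step (the assay reports construct-specific steps:
  3.0, 2.5, 15.0 and 5.0 mM); the per-cell frequency is defined only for
  cells actually oscillating at that step, so population means are not
  diluted by cells that have not reached their onset. **Ending point** =
  lowest step at or above the start with no oscillation and a sustained
  plateau: the mean of the last half of the dwell must be ≥ 0.8× the
  cell's maximum ratio (per-cell maximum, a deliberate choice — a global
  maximum would couple cells) with a coefficient of variation ≤ 0.05.
* Cells with no oscillatory step anywhere are non-oscillatory; they are
  excluded from the start/end histograms but counted in the denominator
  of the oscillatory fraction. Histograms use (lo, hi] bins on the
  protocol's step concentrations, so a cell starting exactly at a step
  falls in that step's bin.

The assay does not state the dwell per concentration step nor the
sampling rate; the defaults are 180 s and 1 Hz and both are configurable.
Frequency-recovery experiments in the acceptance script use 600-s dwells
so the peaks-per-minute quantisation (±1 count per dwell) is well below
the reported precision.

## Hill and biphasic-Hill fitting

The four-parameter Hill model r(c) = r0 + (rmax − r0)·cⁿ/(EC50ⁿ + cⁿ) is
fitted by Levenberg–Marquardt least squares (lmfit) on replicate points
(unweighted — the source assays state no weighting scheme). Initialisation:
EC50₀ at the concentration where the mean curve crosses half of its
observed span, n₀ = 2; bounds EC50 ∈ (0, 10·max c], n ∈ [0.3, 10]
(stabilises steep curves, n ≈ 2.4–5 in this system). Standard errors come
from the local curvature at the optimum; a case-resampling bootstrap
(500 resamples) is available as `HillResults.bootstrap_se`. The
convergence flag is false if the optimizer fails or any free parameter
ends at a bound. Fits require ≥ 4 distinct concentrations.

`r0` and `rmax` can each be fixed (e.g. `fix_rmax=1` for normalized
data). The default keeps both free even for normalized data: the
normalisation divides by the *mean response at the top concentration*,
which for curves not yet saturated there (e.g. the P221Q [Ca²⁺]ᵢ response,
≈ 0.93·rmax at the top step) sits below the true plateau; pinning rmax to
1 then injects systematic lack of fit and inflates false biphasic calls.

The biphasic model r(c) = r0 + A·[f·h₁(c) + (1−f)·h₂(c)] uses unit Hill
terms h᷀ᵢ with the identifiability constraint EC50₁ < EC50₂ built into the
parameterisation (EC50₂ = EC50₁·ratio, ratio ≥ 1.01). The amplitude split
f is bounded to [0.05, 0.95] to avoid boundary degeneracy. Fits run from
a small grid of six starting points (f ∈ {0.3, 0.5, 0.7} × n ∈ {2, 4})
and keep the lowest RSS. A fit whose optimal ratio is < 1.5 is flagged
*degenerate* (phases not separable). Biphasic fits require ≥ 7 distinct
concentrations spanning both phases.

**Model selection** returns "biphasic" only when AICc improves on the
monophasic fit by more than 2 *and* the fit is not degenerate; the margin
of 2 is an assumption (the source analysis asserts the biphasic shape
without a criterion). Operating characteristics under the default
synthetic conditions (5% CV, 3 replicates, 12-concentration grid, equal
amplitude split): ≈ 96% specificity on monophasic data and ≈ 80%
sensitivity on two-phase data — with 5% multiplicative noise the
monophasic fit absorbs much of the two-phase shape, and the 3-extra-
parameter AICc penalty then dominates near the margin. Noiseless
two-phase data are always detected. The test suite asserts these measured
rates.

**IP₁ transform.** Raw competition-assay values are converted to percent
inhibition of IP₁-HRP binding, (1 − stimulated/unstimulated) × 100, before
Hill fitting; on noiseless data the transform composed with the raw-assay
generator is the identity on the underlying curve.

**Heterotropic shift.** ΔEC50 = EC50(without) − EC50(with modulator)
(positive = left shift/sensitisation), plus the EC50 ratio and Δn.

## Synthetic-data generators

The generators are phenomenological: they reproduce the *statistical
structure* the analysis assumes, not the biophysics.

* **Traces.** A cell has an oscillation-onset and a plateau threshold in
  mM and a spike rate (peaks/min). Below onset: baseline + Gaussian noise
  (additive, ratiometric error structure). Each step change to > 0.5 mM
  elicits one initial transient peak. Between the thresholds, a spike
  train of Gaussian-shaped transients rides on the baseline: a *regular*
  train at the target rate with uniform jitter of ±10% of the inter-spike
  interval (not Poisson), so recovered frequencies are tight, which is
  how the stable reported peaks/min values behave. The first train event
  sits near half an interval into the step but at least 18 s after the
  step change, keeping it separated from the transient at the default
  10-s peak separation; events keep their apex inside the dwell. At and
  above the plateau threshold the ratio holds a sustained elevation
  (the generator's reading of the plateau morphology; a slow decline is
  not modelled) whose step-entry rise carries a 5% overshoot that reads
  as the initial peak. There is no IP₃-receptor kinetics or PKC feedback
  — no mechanistic oscillator.
* **Populations.** Onset and plateau thresholds are log-normal across
  cells, parameterised by median and CV (strictly positive,
  right-skewed, matching the observed threshold histograms); rare draws
  with plateau ≤ onset are repaired to 1.5× onset. A fixed fraction of
  cells never responds (default 0.1 — the field's typical share of
  untransfected/silent cells; the sources do not report it).
* **Dose-response.** Hill (or two-phase mixture) curves with
  multiplicative noise: each replicate is the noiseless value times
  (1 + ε), ε ~ N(0, CV), the plate-reader error structure. Defaults:
  5% CV, 3 replicates. The IP₁ generator emits raw binding
  B(c) = B₀·(1 − H(c)/100) with the same noise, so the percent-inhibition
  transform recovers H(c).
* **Ensembles.** Frames are independent draws from a zero-mean
  multivariate normal over per-residue displacements added to a fixed,
  gently curved Cα-like reference chain. The covariance is assembled from
  block correlations between residue sets on top of per-residue variances
  (default 1 Å², split equally over x, y, z); it is validated positive
  semi-definite incrementally, and a violating block is named in the
  error. `CovarianceSpec.coupled_sites` also sets within-set correlation
  (default 0.9), because a bare inter-set block is rarely PSD. Frames
  share the reference frame, so generated ensembles are already
  superposed. No force-field dynamics: frames are exchangeable, with no
  autocorrelation in time.

Because the generators define the recovery experiments, passing tests
show that the pipeline extracts what the generators encode under
realistic noise — not that real imaging artefacts (photobleaching,
baseline drift, motion), plate effects, or true MD ensembles would be
handled; drift correction and spectral oscillation analysis are
explicitly out of scope.

## Construct presets

Presets for WT, L173F, P221L (gain of function) and L173P, P221Q (loss of
function) bundle each construct's published functional parameters — EC50
and Hill coefficient of the [Ca²⁺]ᵢ response, IP₁ and ERK EC50s, L-Phe
EC50s, oscillation thresholds and frequencies, each with and without 5 mM
L-Phe; the L173P [Ca²⁺]ᵢ response is the two-phase mixture (3.8 and
13.0 mM without L-Phe; amplitude split not reported, set to 0.5). Hill
coefficients for the IP₁, ERK and L-Phe readouts are not reported; the
presets use n = 3 (matching the cooperative Ca²⁺ readouts) and n = 2 for
L-Phe. The IP₁ percent-inhibition plateau is set to 75%. Threshold
medians and CVs are calibrated so the modal starting/ending steps and
modal fractions match the reported single-cell distributions (e.g. onset
median 2.85 mM, CV 0.12 for WT puts ≈ 53% of oscillatory cells in the
3.0 mM bin); with L-Phe the WT frequency step (3.0 mM) lies at the modal
*ending* point, so only the upper-tail cells (plateau > 3.0 mM)
contribute to the frequency there, as in the source assay. Protocols are
uniform-dwell ramps over construct-specific step grids (up to 8, 15 or
30 mM).

## Dynamics analyses

Correlations use one point per residue (documented as the Cα proxy; the
atom selection in the source workflow is unstated). Superposition is the
SVD-based least-squares (Kabsch) rigid fit of every frame onto a
reference frame (default frame 0, full residue mask); collinear reference
coordinates are rejected. The DCCM uses population (1/F) averaging of
mean-centred displacements; zero-variance residues yield NaN rows/columns
(serialised as empty cells in CSV) with the diagonal kept at 1. PCA takes
the SVD of the mean-centred flattened coordinates; eigenvalues are
variances in Å² on the same 1/F normalisation (so their sum equals the
total coordinate variance), modes are orthonormal, and projections are
mean-free by construction. Site-coupling scores (mean signed correlation,
mean |C|, fraction of pairs with |C| ≥ 0.5 over the A×B rectangle) are
this package's operationalisation of between-site coupled motion — the
source comparison is visual — and reports label them as such. Site
residue lists are user-supplied configuration
(`examples/sites_example.json` is an editable placeholder, not the
published site definitions). Map plots use blue = −1, green ≈ 0,
red = +1, with an optional axis offset for construct residue numbering.

## Pipeline and reproducibility

`run_pipeline` chains generation → oscillation analysis → cooperativity
fits (→ dynamics when configured) for one preset, writing a JSON report,
CSV tables and optional figures. Stage seeds derive deterministically
from the run seed; reports contain a configuration hash (output location
excluded) and no timestamps, so identical configurations reproduce
byte-identical reports. Units are fixed: mM, seconds, Å.

Problem sizes in the acceptance script: 10 simulation seeds per fitted
quantity (median reported), 3 replicates at 5% CV; 300 pooled cells for
distributional oscillation quantities (the modal step of a broad,
calibrated threshold distribution — e.g. the P221L onset bin holding only
≈ 40% of cells — needs a large sample to be a stable statistic);
5000-frame ensembles for correlation-block recovery.

## Known limitations

* The generators share their parameterisation with the recovery targets;
  they validate the analysis pipeline, not the biology.
* The plateau criterion references the per-cell maximum; traces whose
  plateau is much lower than their largest spike would need
  `plateau_fraction` adjusted.
* Biphasic model selection near the AICc margin is conservative by
  design; weakly separated phases at realistic noise resolve to
  "monophasic".
* PCA/DCCM assume a rigid-body-free ensemble; superposing highly flexible
  few-residue ensembles mixes internal and overall motion, as it does in
  any Kabsch-based workflow.
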