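# Methods

## Kinetic model

The conversion of the open conformer to the closed conformer is modelled
as irreversible first-order kinetics. Two schemes are supported:

* **two-state** O → C with rate constant `k1` (min⁻¹):
  `P_O(t) = exp(−k1·t)`, `P_C = 1 − P_O`;
* **three-state** O → I → C with rates `k1`, `k2`:
  `P_I(t) = k1/(k2−k1)·(exp(−k1·t) − exp(−k2·t))` (the `k1 = k2` limit
  `P_I = k1·t·exp(−k1·t)` is handled explicitly), `P_C = 1 − P_O − P_I`.

Irreversibility reflects the biology: the reverse closed→open reaction is
ATP-dependent and enzyme-catalyzed, and is absent under the in-vitro
conditions the analysis addresses. All molecules are assumed open at the
start of the measurement and converted at its end; these two assumptions
are exactly what the normalization conventions encode (below).

Peak intensities are proportional to state populations: the open-state
peak of residue r tracks `P_O`, closed-state peaks track `P_C`, and
(three-state only) an intermediate peak tracks `P_I`. Per-residue rate
heterogeneity is offered as a phenomenological multiplier on `k1`: a
strict global two-state mechanism forces a single rate, but observed
per-residue "initial conversion rates" vary across the sequence, and both
modes are needed — uniform rates to test the machinery, heterogeneous
rates to emulate the observable.

## Acquisition and merging

The reference schedule is 500 spectra of 5 min each (a ~42 h window).
Spectrum i is timestamped at its completion time `dt·(i+1)`: the intensity
integrates the state of the sample over the acquisition, and end-stamping
is the conservative choice. To lift signal-to-noise, `window` consecutive
spectra are summed with stride 1 (sum, not mean — downstream normalization
removes the scale), so 500 spectra yield 497 merged points whose
consecutive timestamps still differ by 5 min; each merged point is stamped
with the mean of its window's timestamps. Disjoint blocks would give
20-min offsets and are deliberately not offered.

A consequence worth knowing: adjacent merged points share `window − 1` raw
spectra, so residuals of fits to merged series are autocorrelated and the
reported regression errors (which assume independence) are lower bounds.
The intermediate-state score corrects its noise estimate for this overlap
(first-difference noise rescaled by `sqrt(window/2)`).

## Normalization and decay fitting

Open-state trajectories are divided by their value in the first merged
spectrum (all molecules open at t=0); closed-state trajectories by their
value in the last merged spectrum (all molecules converted at the end).
References below a configurable floor (default 1e-6) exclude the residue
with a logged reason. Every fitted quantity is invariant to global
intensity scaling.

O-decays are fitted by nonlinear least squares to
`y = (y₀ − y_min)·exp(−k·x) + y_min` with `k ≥ 0`. A fit is non-converged
— and carries no rate — when the optimizer fails, the series does not
decay, or `k` is within two standard errors of zero; an exactly noiseless
series has a singular covariance and is treated as `se_k = 0`. The
"initial conversion rate" reported per residue is the fitted `k`; the true
initial slope `k·(y₀ − y_min)` is also exposed since either reading of
"initial rate" is defensible.

C-appearance is never force-fitted to an exponential plateau for headline
rates: when intermediate states are populated the appearance is lagged
(sigmoidal) and an exponential fit would be a model error. Instead each
C-trajectory is summarized by its half-rise time and a non-exponentiality
score (below).

Completion is defined as 97% converted (~5 half-lives),
`t = ln(1/(1−fraction))/k`, configurable. The 97% convention reproduces
the observed ~24 h / ~250 min / ~30 min completion relationships
self-consistently; the underlying experimental completion call is visual,
so this is a declared convention, not a measured fact.

## Rate-profile comparison

Two conditions are compared per residue as the rate ratio `k_b/k_a` over
residues with converged fits in both. In `median_ratio` mode the ratios
are rescaled by their global median, so a uniform acceleration maps to 1
everywhere and residue-specific deviations stand out; residues whose
scaled ratio deviates from 1 by more than a configurable factor (default
1.5 in either direction) are flagged. The median (not mean) is used
because the comparison is designed to find outlier residues, which must
not drag the reference. With the reference acquisition and ≤5% intensity
noise, fitted-rate errors are a few percent, so the 1.5 factor cleanly
separates a ≥2-fold residue-specific change from fit noise.

## Intermediate-state scoring

Two readouts address whether O-disappearance and C-appearance are mutually
consistent with direct two-state conversion:

* **Per-residue non-exponentiality** — the RMS residual of the best
  exponential-plateau fit to the C-trajectory, noise-corrected (robust
  first-difference estimate, merge-window-aware) and normalized by the
  trajectory range. Closed-form analysis on the 42 h / 5 min grid puts
  two-state curves at ~1e-10 and sequential kinetics with `k2 ≤ k1/5` at
  3e-3 to 2e-2 across `k1` in [0.002, 0.05] min⁻¹; the verdict threshold
  is set between the two populations at 2e-3 (configurable).
* **Rank correlation** between per-residue O-decay rates and C-appearance
  rates (1/half-rise). A direct correspondence argues against resolvable
  intermediates. The correlation enters the verdict only when fitted rates
  genuinely vary across residues (max/min ≥ 1.5 by default); with uniform
  rates the ranking reflects only fit noise and is reported as a
  diagnostic but ignored by the verdict.

## State fingerprinting

The two tryptophan indole N–H resonances shift characteristically between
the open state, the empty closed state and ligand-bound closed states, and
serve as a two-peak fingerprint. An observed spectrum is assigned to the
nearest reference state under the RMS weighted-CSP distance over matched
reporter peaks; calls whose two best distances differ by less than a
configurable margin (default 0.02 ppm) are ambiguous, and missing
reporters reduce confidence with an attached warning.

## Chemical shifts and binding

Secondary chemical shifts are
`(δCα_obs − δCα_rc) − (δCβ_obs − δCβ_rc)`; positive values indicate
helical, negative values strand propensity. Classification uses a
configurable ±0.7 ppm band for the coil call; the scientific conclusions
depend on sign only. Random-coil references come from a static shipped
table of standard random-coil Cα/Cβ values; neighbor, pH and temperature
corrections are intentionally out of scope, and the lookup logs that
fact. Glycine carries no Cβ and is scored on the Cα term alone, as is any
record with missing Cβ data (flagged reduced-confidence).

Weighted CSPs are `√((Δδ_H·W_HN)² + (Δδ_N·W_N)²)`, `W_HN = 1`,
`W_N = 0.16` (weights configurable). Titration CSPs are fitted to the
single-site quadratic (tight-binding) isotherm

    Δδ_obs = Δδ_max·[(P + L + K_D) − √((P + L + K_D)² − 4PL)]/(2P)

which passes through (0, 0) and saturates at Δδ_max by construction — both
limits are enforced as tests.

Three selection modes: the residue with the largest final CSP, an explicit
residue, or a **global fit** sharing one K_D across all residues with an
independent Δδ_max per residue (profiled out linearly). The global mode
exists because a single-residue, 8-point titration at 5% noise carries
limited information: a Cramér–Rao analysis gives sd(ln K_D) ≈ 0.42 at the
best achievable protein concentration, i.e. ~30% typical error, whereas
pooling ~10 reporting residues brings median recovery error under 10%.
Estimating the affinity from the residues with the most significant CSPs,
jointly, is standard practice for single-site binding.

**Lower-bound semantics.** When the fitted curve reaches less than 50%
saturation at the highest ligand concentration, or the profile-likelihood
confidence interval for K_D is unbounded above (F-test on the profiled sum
of squares at 95%), the result is reported as a lower bound — "K_D >
value" — where the value is the largest K_D rejected at that confidence.
Weak binders probed over a limited ligand range are therefore never given
a sham point estimate.

## Relaxation

T1/T2 series are fitted per residue to `I(τ) = I₀·exp(−τ/T)`. The shipped
mixing-time lists contain eleven distinct delays plus a repeat of the
first (12 points); repeated delays are retained as separate points and
their within-pair differences estimate replicate noise. Flexible-region
flagging uses a robust threshold, median + c·scale (c = 2 default), with
the scale estimated one-sidedly from the *quiet* side of the median so the
flexible residues themselves do not inflate it. High T1/T2/RMSF and low
hetNOE/peak-height mark flexibility; flagged runs separated by at most one
unflagged residue are bridged, runs shorter than 3 residues are dropped,
and intervals are reported 1-based inclusive. Exchange-broadened (missing)
residues are representable as absent rows, but no exchange model is
fitted.

## Ensemble statistics

Superposition uses the closed-form least-squares (Kabsch) rotation;
degenerate selections (fewer than 3 atoms, or collinear/coincident points)
raise. RMSD is computed per frame over all protein backbone atoms to a
fixed reference (the first frame by default). Cα RMSF follows
fit-to-average: within each simulation repeat, frames are superposed on
the running average (Cα selection by default, all-backbone selectable) and
the average recomputed until it moves less than 1e-6 Å (≤10 iterations;
a one-pass mode is offered for comparison); RMSF is the root mean squared
Cα distance to the converged average, averaged over repeats (contiguous
frame blocks). Contact probability drops an initial equilibration window
(default 200 ns, i.e. 1000 frames at 0.2 ns), then reports for each
receptor residue the fraction of retained frames in which its Cβ (Cα for
glycine) lies within 8 Å of any ligand Cβ.

Two small-sample properties worth knowing: the rigid-body fit absorbs six
degrees of freedom of genuine fluctuation, biasing RMSF down by a factor
≈ √(1 − 6/(3N)) for N fitted atoms (~3.4% at N = 30, ~1% at N = 100); and
per-residue values written into PDB B-factor columns are quantized to two
decimals, with uniform rescaling (and a recorded factor) when a value
exceeds the 999.99 column limit.

## Synthetic data: what it does and does not establish

The generators reproduce the *structure* of the real measurements — decay
and growth curves on the real acquisition grid, additive Gaussian
intensity noise (sd as a fraction of each residue's initial amplitude; the
real spectra's noise level is not public, so the default 2% is a
configuration value, not a claim about the data), well-separated 2D
Gaussian peaks, isotropic Gaussian coordinate ensembles whose analytic
RMSF `σ√3` gives a closed-form check. They do not reproduce lineshape
physics, chemical-exchange broadening, peak-position drift during
conversion, relaxation dispersion, or anisotropic correlated motions.
Passing tests therefore establish that the *pipeline* is correct under its
stated model, not that the model captures every property of experimental
spectra.

The shipped 205-residue sequence is a synthetic stand-in (clearly labelled
in its FASTA header): it reproduces the coordinate landmarks the construct
definitions need — the TAKDDSAPR loop at 109–117, tryptophan reporters at
75/167, Arg133, Leu13 — and a 6-proline composition, but it is not the
real protein sequence. Mass and composition checks against published
values (23.5/47.0 kDa, 199 non-proline residues) apply when the user
supplies the canonical full-length sequence as FASTA.

## Numerical choices and degenerate inputs

* All nonlinear fits use `scipy.optimize.curve_fit` (trust-region with
  bounds); starting values come from the data (first/last values, a
  third-of-window rate guess). Exact fits with singular covariance are
  recognized by near-zero residuals.
* Constant or non-decaying series yield non-converged fits, never
  exceptions; empty profiles are valid objects.
* The K_D profile grid is geometric over [1e-3, 1e4·max(L_max, P)] µM with
  local refinement; `se_kd` comes from the log-profile curvature when
  positive.
* Sequence edits apply sequentially with 1-based inclusive coordinates
  interpreted on the current sequence state; guards protect against
  off-by-one errors. Average (not monoisotopic) masses, one water per
  chain, purification tags excluded.
* Seeded `numpy.random.default_rng` everywhere; identical spec + seed
  gives bit-identical outputs, and the pipeline writes a resolved config
  beside every output from which runs reproduce byte-for-byte within a
  fixed software environment (cross-platform floating-point determinism is
  documented, not promised).

## Problem sizes used in the test and acceptance suites

Stochastic suites run at sizes chosen to make the statistical assertions
meaningful while keeping the full test run fast: rate-recovery over six
rate constants × four seeds on the full 497-point grid; K_D recovery over
three affinities × six seeds with ten reporting residues; RMSF on a
100-residue, 3000-frame fixture; discrimination suites over 20 noiseless
fixtures and five noisy replicates. These sizes are package defaults, and
all thresholds asserted in tests were fixed from the closed-form or
Cramér–Rao analyses described above.

## Known limitations

* Regression standard errors on merged series underestimate uncertainty
  (autocorrelated residuals); Monte-Carlo over seeds is the honest
  uncertainty estimate and is what the test suite uses.
* The intermediate-state verdict detects *lagged* appearance; a fast
  pre-equilibrium intermediate (`k2 ≫ k1`) is kinetically silent here, as
  it is in the real experiment.
* No global multi-residue simultaneous kinetic fit; no reverse-reaction
  kinetics; no lineshape-based modelling.
* The flexibility flagger assumes a majority of rigid residues; profiles
  in which most of the chain is mobile violate the quiet-side scale
  estimate.
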