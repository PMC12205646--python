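# Methods

`clampdyn` packages the quantitative analyses used to characterise the
dynamics of the Hsp90 chaperone clamp cycle: fast-exchange fitting of ¹⁹F
CPMG relaxation dispersion, lineshape/population analysis of 1-D ¹⁹F
spectra, deconvolution of coupled ATPase assays on dimer mixtures, and
dynamical cross-correlation analysis of trajectory windows.  Every input
class can be produced by the synthetic-data generators with known ground
truth, so the whole chain is testable without measured data.

## Two-state fast exchange (`clampdyn.exchange`, `clampdyn.cpmg`)

### Model

For two conformations A and B interconverting faster than their
chemical-shift difference (k_ex ≫ Δω), a single population-weighted
resonance is observed, and the effective transverse relaxation rate
measured under a CPMG pulse train of field strength ν_CPMG = 1/(4·τ_CPMG)
follows the Luz–Meiboom form

    R₂(ν) = R₂,₀ + (R_ex / k_ex) · [1 − (4ν / k_ex) · tanh(k_ex / 4ν)]

with

* R₂,₀ — intrinsic (population-weighted) transverse rate, s⁻¹;
* k_ex = k_AB + k_BA — exchange rate constant, s⁻¹;
* R_ex = p_A·p_B·Δω² — exchange amplitude, rad²·s⁻².

R₂ decreases monotonically in ν from R₂,₀ + R_ex/k_ex (slow pulsing) to
R₂,₀ (fast pulsing); the full dispersion amplitude is exactly R_ex/k_ex.
Two amplitude conventions circulate: the rad²·s⁻² amplitude R_ex used
here, and the s⁻¹ plateau R_ex/k_ex.  Fitted values are reported in the
amplitude convention; `rex_amplitude_to_plateau` /
`rex_plateau_to_amplitude` convert between the two.  ppm ↔ rad·s⁻¹
conversion needs the ¹⁹F Larmor frequency; the default is 657 MHz
(16.4 T), overridable everywhere it appears.

Numerics: the dispersion factor g(x) = 1 − tanh(x)/x with x = k_ex/(4ν)
cancels catastrophically as x → 0, so below x = 10⁻⁴ it is evaluated by
its Taylor series x²/3 − 2x⁴/15.  At the switch-over the residual
double-precision error in g is ≲10⁻⁷ relative — invisible in R₂ because
the exchange term there is ≲10⁻⁸ of R₂,₀.

### Fitting

Profiles are fit by weighted nonlinear least squares,
Σ[(R₂,obs − R₂,model)/σ]², with bounds R₂,₀ ≥ 0, R_ex ≥ 0, k_ex > 0
(unit σ when per-point errors are absent).  Because the model is linear
in (R₂,₀, R_ex) at fixed k_ex, the global search profiles those two
parameters out in closed form (non-negative 2-variable solve) over a
64-point log-spaced k_ex grid spanning 1–10⁷ s⁻¹, then polishes the best
candidates with a bounded trust-region optimiser.  This variable-projection
strategy is what makes the fit reliable in the shallow k_ex valleys of
the tanh model: in pilot runs a conventional 5-point multi-start missed
the global optimum on roughly one in six null (flat) profiles.

Temperatures are fit independently (no Arrhenius/Eyring coupling); a
temperature series simply maps the single-profile fit over its inputs,
converting per-profile failures into flagged results instead of aborting.

### Monte Carlo uncertainties

Parameter errors come from parametric Monte Carlo resampling: Gaussian
noise — the per-point errors when available, otherwise the residual RMS
of the best fit — is added to the best-fit curve, each draw is refit
(seeded from the best-fit parameters), and the standard deviation of each
parameter over draws is reported.  The default is 500 draws, enough to
stabilise a second-moment estimate at negligible cost; results are
deterministic given a seed.  On the synthetic study design (11 points,
σ = 0.5 s⁻¹) the MC standard deviations agree with the spread over
independently regenerated datasets to well within a factor of two.

### Flat-vs-exchange model selection

`compare_flat_vs_exchange` performs the nested comparison of the
1-parameter flat model (no exchange) against the 3-parameter dispersion
model via F = [(SSE_flat − SSE_ex)/2] / [SSE_ex/(n−3)].  The classical
F(2, n−3) reference distribution is *conservative* for this comparison:
R_ex sits on the boundary of its parameter space and k_ex is unidentified
when R_ex = 0, so under the null the observed F is stochastically smaller
than F(2, n−3) (empirical size ≈ 0.02 at nominal 0.05).  The default
therefore calibrates the p-value by parametric bootstrap under the fitted
flat model: n_boot null datasets are simulated, F is recomputed on each,
and p = (1 + #{F* ≥ F})/(n_boot + 1).  This Monte Carlo p-value has exact
size whenever (n_boot + 1)·α is an integer (e.g. n_boot = 59 or 199 at
α = 0.05).  The analytic F-tail is still available via
`calibration="analytic"`.  Ties in SSE prefer the flat model (parsimony).

## Lineshape and populations (`clampdyn.lineshape`)

Peaks are pure Lorentzians over a jointly-fitted linear baseline — the
lineshape whose width carries the T₂ interpretation (FWHM = 1/(π·T₂));
Voigt profiles are deliberately out of scope.  Each peak contributes
A·hw²/((δ−c)² + hw²); its analytic area is A·π·hw, and
T₂ [ms] = 1000/(π·FWHM [Hz]).  Initial centres supplied by the user are
refined to the nearest local signal maximum, with the starting half-width
taken from the half-height span — this makes narrow lines (a few grid
points wide) fit robustly.  The ppm axis may arrive in either direction
and is normalised internally to increasing order.  T₂ is read from the
linewidth; an echo-decay readout is not modelled.

Under fast exchange the observed shift is the population-weighted average
δ_obs = p_A·δ_A + p_B·δ_B; `population_from_shift` inverts it for p_B and
flags (but still returns) populations outside [0, 1].

Slow conformational build-up after nucleotide addition is fit as a
two-state single-exponential with a shared rate: closed(t) =
A_∞·(1 − e^(−k_obs·t)) and NM(t) decaying to its plateau with the same
k_obs.  This is a deliberate simplification of the multi-step
nucleotide-binding rate law and is flagged as `simplified_rate_law` in
the result.  Series whose amplitude is indistinguishable from noise (or
exactly constant — the "too rapid to observe" regime where the closed
state is already at plateau at the first sampled point) are flagged
`no_buildup` with k_obs reported as 0.

## ATPase assays (`clampdyn.atpase`)

In the NADH-coupled, ATP-regenerating assay each ATP turnover oxidises
one NADH, so the rate is the initial linear loss of A340:

    rate [µM ATP·min⁻¹·(µM dimer)⁻¹] = −slope(A340/min) / ε_NADH · 10⁶ / [dimer]

with ε_NADH = 6220 M⁻¹·cm⁻¹ at 340 nm (1 cm path; configurable).  When no
window is specified, the largest initial stretch of the curve with linear
R² ≥ 0.98 (minimum 5 points) is used, which excludes late-time NADH
depletion without manual gating.  Backgrounds from inhibitor-blocked
companion wells are subtracted (mean minus mean; replicate SDs combined
in quadrature); negative net rates are clamped to zero with a warning and
treated as "no detectable activity".

Mixing two subunit variants 1:1 yields binomial (1:2:1) proportions of
homodimer1 : heterodimer : homodimer2 (general mixing fraction f1 gives
(f1², 2f1(1−f1), (1−f1)²)).  With all activities expressed as fractions
of WT homodimer activity, the pure-heterodimer activity is

    hetD = [homhetmix − 0.25·homD1 − 0.25·homD2] / 0.5

and the modulation statistics are Δ_asymm = hetD − homhetmix
(off-diagonal; equivalently homhetmix minus the homodimer average, hence
0 when the mixture is exactly the average) and Δ_symm = homD − WT
(diagonal; −1 for a dead homodimer, 0 for WT by construction).  These are
assembled into a lower-triangular matrix over variants; pairs lacking a
measured mixture or a constituent homodimer are left undefined (NaN) with
an annotation, never zero-filled.

Error propagation is first order through the linear identities above.
Activity records carry the replicate SD (the convention of the assay
literature); Δ entries carry SEM-based propagated errors, so reported Δ
uncertainties shrink as 1/√n_reps.  Because everything is normalised to
WT, Δ values are invariant to the absolute rate scale, and the ambiguity
between monomer and dimer concentration conventions on the plate cancels.

Aha1 (cochaperone) stimulation is summarised as the fold ratio of net
rates ±Aha1; the fold is undefined — an error, not 0 or ∞ — when the
basal rate is zero, as for dead homodimers.

## Dynamical cross-correlation (`clampdyn.dccm`)

Frames are superposed onto a reference (the first frame by default) by
least-squares rigid-body fitting of a selection — main-chain N, Cα, C of
a residue range by default, mirroring alignment on residues 4–207 of the
ATPase domain.  The rotation comes from `scipy`'s Kabsch solver; an
independent closed-form SVD implementation serves as a test oracle only.

The DCCM over the selected Cα atoms is

    C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩·⟨|Δr_j|²⟩),

Δr_i the displacement from atom i's mean position.  C is symmetric with
unit diagonal and entries in [−1, 1]; zero-variance atoms are an error
naming the atom.  Region-pair coupling is summarised by the *total
correlation*: the sum of C_ij over residue pairs spanned by two regions,
counting each unordered pair once and never including the diagonal
(within a region this is the sum over i < j).  Overlapping, non-identical
regions follow the same unordered-pair semantics.  The windowed driver
samples frames every `step_ns` over `window_ns` — by default one window
covering the final 800 ns at 10 ns steps (80 + 1 frames when available),
the sampling design used for µs-scale ATPase-domain simulations — or
tiles the trajectory with non-overlapping windows.

Region defaults follow the ATPase-domain anatomy: N-terminal β-strap
(residues 1–8), helix 1 (9–22), ATP gate (94–125); helix 1 × gate is the
default pair for total correlation.  Residue indexing follows the
topology's (1-based) numbering; no re-indexing is performed.

## Synthetic data (`clampdyn.synthetic`)

All generators use Gaussian noise (matching the least-squares assumptions
of every fitter), are bit-reproducible under a fixed seed, and emit a
JSON-serialisable truth record containing every generating parameter plus
the seed.

* **CPMG**: 11-point ν grid, 50–1000 Hz, model curve + iid noise
  (default σ = 0.5 s⁻¹), defaults at 657 MHz / 25 °C.
* **Spectra**: sums of Lorentzians (FWHM = 1/(π·T₂)) plus noise; a peak
  of area a and FWHM f has noise-free height 2a/(πf).
* **Plates**: per-subunit activity contributions (homodimer = 2×
  contribution; WT contribution 0.25 → WT homodimer 0.5 µM·min⁻¹·µM⁻¹,
  i.e. k_cat ≈ 0.5 min⁻¹ per dimer, a typical yeast Hsp90 turnover);
  mixtures combine (0.25, 0.5, 0.25) dimer species with an overridable
  heterodimer activity to emulate asymmetric stimulation; inhibited
  companion wells carry background only; 4 replicates; linear A340 decay
  from 3.4 over 40 min.  Homodimer wells default to 2.5 µM dimer and
  mixture wells to 5 µM dimer (the normalisation cancels the convention).
* **Build-ups**: shared-rate exponentials, 25 points over 1 h.
* **Trajectories**: contiguous regions of Cα pseudo-atoms (default sizes
  14 and 32, mirroring helix 1 and the ATP gate) on an extended chain;
  per-frame, per-axis displacements drawn from N(0, σ²R) with R a block
  correlation matrix.  A non-positive-definite request is projected to
  the nearest valid correlation matrix (eigenvalue clipping + rescale),
  with the projection distance recorded.  Optional random rigid-body
  motion per frame exercises the superposition step; because the optimal
  superposition composes with any rigid transform, the DCCM after
  superposition is identical with and without it, to rounding.

What the generators do **not** emulate: spectrometer artefacts and
non-Gaussian (e.g. shot) noise; coupled-enzyme (PK/LDH) transients and
Michaelis–Menten saturation; force-field physics, solvent, and the
non-stationary slow modes of real MD.  Passing tests therefore establish
the correctness and calibration of the estimators under their stated
noise models, not robustness to every artefact of real measurements.

## Problem sizes used in tests and the acceptance script

Ensembles are sized to bound runtime while keeping statistical checks
meaningful: 100 profiles for recovery medians, 500 Monte Carlo draws for
parameter errors, 400–1000 flat simulations (n_boot = 59) for the
type-I-error calibration, 80 frames for DCCM recovery (the 10 ns / 800 ns
design), 4096-point spectra, and 4-replicate plates.

## Known limitations

* Fast-exchange only: no Carver–Richards or Bloch–McConnell treatment of
  intermediate/slow exchange, and no >2-site models.
* The build-up model is a documented single-exponential stand-in for the
  full nucleotide-binding kinetics.
* Δ error propagation is first order and ignores correlation between a
  mixture and its homodimer references beyond the shared WT normaliser.
* DCCM windows assume the process is stationary within a window; no
  statistical test of stationarity is performed.
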