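# Methods

## Dielectric model and conventions

The in-band (0.3–2.5 THz) permittivity of an aqueous sample is modelled as
bulk-like water scaled by its volume fraction *c*: two Debye relaxations
plus one damped harmonic oscillator. Two conventions matter and are fixed
throughout:

- **Units.** Frequencies ν are linear frequencies in THz and relaxation
  times τ are in ps, so the Debye denominators use the dimensionless
  product 2πν·τ while the oscillator term is formed directly in THz²
  (ν_s² − ν² − iνγ_s). This is the standard convention of the THz
  dielectric-relaxation literature; treating every ω as angular would move
  the stretching resonance far outside the measured band and give an
  unphysical pure-water ε″ (the adopted convention gives ε″ ≈ 2.76 at
  1 THz for pure water, the expected magnitude).
- **Sign.** We use the physics convention ε = ε′ + iε″ with denominators
  (1 − i·2πντ), so ε″ ≥ 0 for passive media. Writing the denominators with
  +i merely conjugates the result; all magnitudes are identical.

Assumptions inherited from the measurement physics: osmolytes at 0.75 M
absorb negligibly compared with water, so the whole ε″ signal is attributed
to (bulk-like) water; hydration water's slow relaxation is shifted far
below the band rather than broadened within it; the stretching mode is
unaffected by solutes. There is no ε∞ offset in the model — a real
constant contributes nothing to ε″, which is the only quantity fitted
(ε′ responds weakly to hydration and is noisier).

## Spectrum fitting

Bounded nonlinear least squares (lmfit/`least_squares`, trust-region
reflective) on uniform-weight ε″ residuals restricted to the 0.3–2.5 THz
band, requiring at least 10 in-band points. The freezing protocol is:

| parameter | pure water | solution |
|---|---|---|
| τ_slow, τ_fast, ν_s, γ_s | fixed (9.20 ps, 0.245 ps, 5.30 THz, 32.5 THz) | fixed |
| A_s | free | fixed (35.0 THz² default) |
| Δε_slow, Δε_fast | free | free |
| c | 1 | from solution density |

Amplitudes are bounded below by 0 and above by 10× the pure-water values —
the upper bound exists purely to stabilize the optimizer and is never
active for sensible data; in particular urea-like solutions may and do fit
Δε_slow above the water value. Initial values are the pure-water
amplitudes themselves (not scaled by c: c already multiplies the model, so
scaling the initials would double-count it). Convergence tolerances are
1e-10 on cost/step/gradient with at most 1000 iterations per free
parameter; non-convergence is reported on the result object, never
silently accepted. Because ε″ is linear in the three amplitudes the
problem is nearly quadratic and converges in a handful of iterations; the
optimum matches the exact normal-equation solution to better than four
digits.

A caveat on c-linearity: fitting the *same* data at c and c/2 scales the
fitted Debye amplitudes by exactly 2 only when the oscillator term is
absent, because a fixed A_s is also multiplied by c and the mismatched
oscillator background is otherwise partially absorbed by the free
amplitudes. The linearity test in the suite therefore switches the
oscillator off.

## Hydration quantities

The water volume fraction is reconstructed from a per-liter mass balance:
osmolyte mass C·M_s, water mass m_w = 1000ρ − C·M_s, and
c = (m_w/ρ_w)/1000 with ρ_w = 0.9975 g/mL, pure water at the 23 °C
density-measurement temperature (configurable). α = (m_w/M_w)/C. Both
raise composition errors for implausible molarity/density pairs; α is
undefined for pure water.

a_hyd divides the Kirkwood-corrected amplitude changes by the
Kirkwood-corrected water amplitudes; the fast-relaxation factor 1.0 is
kept as an explicit division for auditability. a_hyd ≤ 1 with equality
only when both solution amplitudes vanish; it is strictly decreasing in
both solution amplitudes. n_hyd = α·a_hyd is only reported for binary
osmolyte/water systems; ternary (enzyme-containing) systems report a_hyd
for the whole system, since waters-per-molecule is ill-defined there.

**A_s sensitivity.** The fixed oscillator amplitude is the least certain
frozen constant, so hydration results carry bounds from refitting at
A_s ∈ {33, 35, 37} THz². The water reference is refit consistently at each
A_s (amplitudes free, A_s fixed to the sweep value) so that water and
solution share the same oscillator background; the central value is taken
at 35.0 THz² and the bounds are the sweep extrema. Consistent refitting
makes much of the A_s error common-mode, so synthetic half-widths are
small; on real spectra, where the water and solution backgrounds differ,
the sweep produces the larger error bars expected of this protocol. A
single water reference per dataset is assumed.

## Kinetics

Decays are fitted with scipy's bounded `curve_fit` to B + A₀e^(−kt) with
all three parameters non-negative. Samples before 15 s are discarded and
time is re-origined at the first retained sample, so A₀ + B is the
absorbance at 15 s; a pure exponential on absolute time would only rescale
A₀ and leave k unchanged. Initial guesses come from the trace minimum (B),
the first retained point (A₀) and the 1/e crossing (k). Traces with a
positive linear trend are flagged as non-decays and excluded rather than
fitted. First-order kinetics is assumed throughout; no lag or biphasic
model selection is attempted.

Normalization: per bottle, k_water is the mean over that bottle's water
control runs (plural controls are averaged); each osmolyte run contributes
one ratio k/k_water; ratios are aggregated per osmolyte with mean and
sample (n−1) SD. Runs whose bottle lacks a water control are excluded,
flagged and counted, never silently dropped. Any common multiplicative
per-bottle factor cancels exactly.

## Correlation

One planned simple regression per panel, unweighted OLS via the centered
normal equations, R² = 1 − SS_res/SS_tot (equal to the squared Pearson r
for simple regression; the suite checks this identity to 12 digits and
cross-checks slope/intercept/R² against statsmodels). Displayed error bars
(rate SD, A_s sweep half-width) are carried for reporting only; no
errors-in-variables correction is attempted. The joint report flags
whether both panels have negative slopes — the signature that
water-binding osmolytes suppress activity in binary and ternary systems
alike.

## Synthetic data

The generator replaces the spectrometer and the plate reader:

- **Spectra**: exact model evaluation on a 45-point 0.3–2.5 THz grid plus
  i.i.d. additive Gaussian noise (default σ = 0.02 on ε″, an
  instrument-scale choice). Solution spectra are built by closed-form
  inversion of the hydration relation: given a target n_hyd and a
  composition, Δε_slow^s is chosen so the pipeline recovers exactly that
  target (fast amplitude held at the water value).
- **Decays**: B + A₀e^(−k(t−15 s)) sampled every 5 s for 10 min including
  pre-trim samples, plus additive Gaussian noise (default σ = 0.005).
- **Studies**: per-bottle amylose factors uniform in 0.8–1.2 multiply a
  base k_water = 0.01 s⁻¹ and the initial amplitude A₀ (emulating the
  filtration-induced concentration variation); each realized rate gets
  multiplicative lognormal noise (default σ = 0.05 in log space); the
  planted activity law is linear, ratio = −0.05·n_hyd + 1.00, over a
  seven-osmolyte panel with n_hyd from −3 (urea-like) to +9
  (trehalose-like), so urea-like arms land near 1.15 and trehalose-like
  near 0.55. Solution densities are nominal 0.75 M literature-scale values
  fixed once in the panel definition. Ternary spectra plant the same
  a_hyd with 10 % less water volume (enzyme displacement).

Everything is driven by one `numpy` Generator seed; identical designs and
seeds give identical bundles.

What the generator does **not** emulate: baseline drift and etalon fringes
in ε″, frequency-dependent noise, day-to-day drift of k, deviations from
first-order kinetics, direct osmolyte THz absorption, and any direct
osmolyte–enzyme interaction. Passing tests therefore demonstrate that the
estimation machinery is unbiased and self-consistent under the stated
noise model, not that real spectra are free of systematic effects.

## Problem sizes and tie-breaks

Default test/demonstration sizes: 45-point spectra; 50 noisy spectral
replicates; 200 noisy decays; studies with 2–5 bottles, 1–3 replicates and
7 osmolytes; 100-seed Monte-Carlo slope recovery. The dense 2-D grid
search used as a fitting oracle runs at 0.01 resolution around the truth;
note that under noise the *discrete* grid argmin can slide several steps
along the strongly anti-correlated (Δε_slow, Δε_fast) valley even though
the continuous optimum is exact, so coordinate-level agreement is asserted
on noiseless instances and cost dominance on all.

## Known limitations

- The volume-fraction formula is a mass-balance reconstruction; measured
  partial volumes would differ at the third decimal.
- Fixed relaxation times mean amplitude changes absorb any true
  osmolyte-induced shift of τ_slow within the band.
- a_hyd mixes slow-depletion and fast-enhancement contributions into one
  number; the two are not separable here.
- The correlation is descriptive; no causal or errors-in-variables
  inference is made, and a single regression per panel means no
  multiple-testing control is needed or applied.
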