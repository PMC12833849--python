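# thzhyd

Analysis pipeline linking osmolyte-induced changes in picosecond water
dynamics, measured as terahertz dielectric spectra, to α-amylase reaction
rates from iodine–starch bleaching kinetics.

Osmolytes — small neutral solutes such as urea, sugars and polyols — alter
the collective reorientational dynamics of water. This package quantifies
that change from the imaginary permittivity ε″(ν) of aqueous solutions in
the 0.3–2.5 THz band, converts it into hydration numbers, measures enzyme
activity from 615 nm absorbance decays, and correlates the two. It is aimed
at biophysical chemists analysing THz-TDS (ATR) data of aqueous solutions
alongside simple enzymatic assays. Because such datasets are rarely
deposited, a first-class synthetic-data module generates every input with
planted ground truth, so the full pipeline is testable end to end.

## The model

The permittivity of an aqueous sample is modelled as bulk-like water scaled
by its volume fraction *c*:

    ε(ν) = c [ Δε_slow / (1 − i·2πν·τ_slow)
             + Δε_fast / (1 − i·2πν·τ_fast)
             + A_s / (ν_s² − ν² − i·ν·γ_s) ]

with ν in THz and τ in ps: a slow Debye relaxation (collective
reorientation of the hydrogen-bonded network, τ_slow = 9.20 ps), a fast
Debye relaxation (transiently free water, τ_fast = 0.245 ps), and a damped
harmonic oscillator for the intermolecular stretch (ν_s = 5.30 THz,
γ_s = 32.5 THz). Fits target ε″ only; relaxation times and oscillator shape
are always fixed, and for solutions A_s is fixed at 35.0 THz² as well, so
only the two amplitudes are free.

Water bound by an osmolyte relaxes far below the THz window, depleting
Δε_slow relative to pure water. With Kirkwood correlation factors 2.9
(slow) and 1.0 (fast), the fraction of dynamically altered water and the
per-osmolyte hydration number are

    a_hyd = [ (Δε_slow^w − Δε_slow^s)/2.9 − (Δε_fast^s − Δε_fast^w)/1.0 ]
            / [ Δε_slow^w/2.9 + Δε_fast^w/1.0 ],        n_hyd = α · a_hyd

where α is the number of water molecules per osmolyte molecule from the
molarity, solution density and molar masses. Negative n_hyd ("negative
hydration", e.g. urea) means accelerated water dynamics.

The kinetics arm fits Abs(t) = B + A₀·e^(−kt) to 615 nm absorbance decays
(5 s sampling, 10 min, first 15 s discarded) and normalizes each rate
constant by a pure-water control measured with the same amylose bottle,
cancelling bottle-to-bottle concentration differences. An unweighted OLS
line of k/k_water against n_hyd (binary solutions) or a_hyd (ternary,
enzyme-containing solutions) summarizes the correlation.

## Worked example

```python
import thzhyd as tz

water_spec = tz.gen_spectrum(tz.water_params(), label="water")
wfit = tz.fit_pure_water(water_spec)

sucrose = tz.SolutionComposition(molarity=0.75, density=1.094,
                                 molar_mass_osmolyte=342.30)
spec = tz.gen_spectrum_for_nhyd(5.8, sucrose, noise_sd=0.02, seed=7)
res = tz.sensitivity_sweep(spec, water_spec, composition=sucrose)

trace = tz.gen_decay_trace(k=0.0100, A0=1.0, B=0.2, noise_sd=0.005, seed=7)
run = tz.fit_decay(trace)
```

prints (via the obvious f-strings):

```
water fit: d_slow=73.8  d_fast=1.85  A_s=35.0 THz^2
sucrose-like sample: c=0.8394  alpha=61.97
a_hyd=0.0911  n_hyd=5.65  [5.64, 5.65] (A_s 33-37 THz^2)
decay fit: k=0.01004 1/s  A0=0.998  B=0.200  (118 samples)
```

The pure-water refit recovers the reference amplitudes (73.8, 1.85); the
0.75 M sucrose-like spectrum (planted n_hyd = 5.8, with instrument-scale
noise) yields n_hyd = 5.65 — about 5.7 water molecules per sucrose with
retarded collective dynamics — with the bracket showing the sensitivity to
the fixed A_s swept over 33–37 THz²; the decay fit recovers the planted
rate constant within 0.5 %.

A whole campaign can be generated and analysed from the shell:

```
thzhyd simulate --out study/ --seed 1
thzhyd run study/manifest.csv --out summary.json
```

`summary.json` holds the water fit, the per-osmolyte hydration table, the
bottle-normalized rates and both correlation panels (slope, intercept, R²).

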