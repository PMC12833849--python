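"""Physical constants and protocol defaults used across the pipeline.

All values live here so that every stage logs and uses one consistent,
versioned set. Frequencies are in THz, relaxation times in ps, densities
in g/mL, molar masses in g/mol.
"""

from __future__ import annotations

#: Pure-water dielectric parameters at 20 °C. The relaxation times and the
#: stretching-vibration constants are literature values held fixed during
#: fitting; the two amplitudes are the fitted pure-water reference values.
WATER_DELTA_EPS_SLOW = 73.8
WATER_DELTA_EPS_FAST = 1.85
TAU_SLOW_PS = 9.20
TAU_FAST_PS = 0.245
AMP_STRETCH_THZ2 = 35.0
FREQ_STRETCH_THZ = 5.30
DAMPING_STRETCH_THZ = 32.5

#: Kirkwood dipole-correlation factors applied when converting amplitude
#: changes of the slow and fast relaxations into water-molecule counts.
KIRKWOOD_SLOW = 2.9
KIRKWOOD_FAST = 1.0

#: Reliable band of the ATR THz measurement (THz).
FIT_BAND = (0.3, 2.5)

#: A_s values swept to put sensitivity bounds on hydration quantities (THz²).
AS_SWEEP = (33.0, 35.0, 37.0)

#: Absorbance sampling protocol: one point every 5 s for 10 min, with the
#: first 15 s discarded (stirring transients).
SAMPLE_INTERVAL_S = 5.0
TRACE_DURATION_S = 600.0
START_TRIM_S = 15.0

#: Density of pure water at the density-measurement temperature (23 °C).
WATER_DENSITY_REF = 0.9975
MOLAR_MASS_WATER = 18.015

#: Least-squares convergence settings.
FIT_COST_TOL = 1e-10
FIT_MAX_ITER = 1000

#: Amplitude upper bounds as multiples of the pure-water values — purely to
#: stabilize the optimizer on pathological inputs, never binding in practice.
AMP_BOUND_FACTOR = 10.0


def effective_config() -> dict:
    """Return the full constant set as a dict, for logging with every run."""
    return {
        "water_delta_eps_slow": WATER_DELTA_EPS_SLOW,
        "water_delta_eps_fast": WATER_DELTA_EPS_FAST,
        "tau_slow_ps": TAU_SLOW_PS,
        "tau_fast_ps": TAU_FAST_PS,
        "amp_stretch_thz2": AMP_STRETCH_THZ2,
        "freq_stretch_thz": FREQ_STRETCH_THZ,
        "damping_stretch_thz": DAMPING_STRETCH_THZ,
        "kirkwood_slow": KIRKWOOD_SLOW,
        "kirkwood_fast": KIRKWOOD_FAST,
        "fit_band_thz": list(FIT_BAND),
        "as_sweep_thz2": list(AS_SWEEP),
        "start_trim_s": START_TRIM_S,
        "water_density_ref_g_per_ml": WATER_DENSITY_REF,
        "molar_mass_water": MOLAR_MASS_WATER,
    }
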