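"""Synthetic stand-in for the instruments: spectra, decays, whole studies.

Everything the pipeline consumes can be generated here with planted ground
truth, so every stage is testable end to end without measured data. The
generators emulate the experimental campaign: THz eps'' spectra over the
reliable 0.3-2.5 THz band with additive Gaussian instrument noise,
615 nm absorbance decays sampled every 5 s for 10 min, bottle-to-bottle
variation of the amylose concentration, and a linear activity law mapping
the planted hydration number to the expected normalized rate k/k_water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .dielectric_model import DielectricModelParams, DielectricSpectrum, water_params
from .hydration import SolutionComposition, water_volume_fraction, waters_per_osmolyte
from .kinetics import AbsorbanceTrace

__all__ = [
    "OsmolyteCondition",
    "StudyDesign",
    "SyntheticStudy",
    "default_grid",
    "gen_spectrum",
    "gen_spectrum_for_nhyd",
    "gen_decay_trace",
    "gen_study",
]


def default_grid(step: float = 0.05) -> np.ndarray:
    """Frequency grid spanning the reliable band 0.3-2.5 THz (45 points)."""
    lo, hi = C.FIT_BAND
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def gen_spectrum(
    params: DielectricModelParams,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    label: str = "",
    temperature: float = 20.0,
) -> DielectricSpectrum:
    """eps'' = model + i.i.d. Gaussian noise; reproducible for a fixed seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    from .dielectric_model import eval_imag_on_grid

    y = eval_imag_on_grid(params, g)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=g.size)
    return DielectricSpectrum(frequencies=g, eps_imag=y, label=label,
                              temperature=temperature)


def slow_amplitude_for_ahyd(
    a_hyd: float, water: DielectricModelParams
) -> float:
    """Invert the hydration relation for the solution slow amplitude.

    With the fast amplitude held at the water value, the hydration fraction
    reduces to (d_slow_w - d_slow_s)/2.9 over the water denominator; solve
    for d_slow_s. Negative targets (accelerated dynamics) give amplitudes
    above the water value.
    """
    den = water.delta_eps_slow / C.KIRKWOOD_SLOW + water.delta_eps_fast / C.KIRKWOOD_FAST
    d_slow_s = water.delta_eps_slow - C.KIRKWOOD_SLOW * a_hyd * den
    if d_slow_s < 0:
        raise ValueError(
            f"infeasible hydration target a_hyd={a_hyd}: slow amplitude would "
            f"be negative"
        )
    return d_slow_s


def gen_spectrum_for_nhyd(
    true_n_hyd: float,
    composition: SolutionComposition,
    water: DielectricModelParams | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    grid: np.ndarray | None = None,
    label: str = "",
) -> DielectricSpectrum:
    """Solution spectrum whose pipeline-recovered n_hyd equals the target.

    The planted a_hyd is true_n_hyd / alpha; the slow amplitude is chosen by
    closed-form inversion and the fast amplitude stays at the water value.
    """
    water = water or water_params()
    alpha = waters_per_osmolyte(composition)
    c = water_volume_fraction(composition)
    d_slow_s = slow_amplitude_for_ahyd(true_n_hyd / alpha, water)
    params = water.with_(delta_eps_slow=d_slow_s, water_volume_fraction=c)
    return gen_spectrum(params, grid=grid, noise_sd=noise_sd, seed=seed, label=label)


def gen_decay_trace(
    k: float,
    A0: float = 1.0,
    B: float = 0.2,
    interval_s: float = C.SAMPLE_INTERVAL_S,
    duration_s: float = C.TRACE_DURATION_S,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    osmolyte: str = "water",
    bottle_id: str = "",
    replicate_id: str = "",
) -> AbsorbanceTrace:
    """Absorbance decay sampled on the instrument schedule (0-600 s, 5 s).

    The exponential is referenced to the trim point (15 s), so A0 + B is
    the absorbance at 15 s exactly as the decay fitter defines it. Pre-trim
    samples are included so downstream trimming is exercised.
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    y = B + A0 * np.exp(-k * (t - C.START_TRIM_S))
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return AbsorbanceTrace(times=t, absorbance=y, osmolyte=osmolyte,
                           bottle_id=bottle_id, replicate_id=replicate_id)


@dataclass(frozen=True)
class OsmolyteCondition:
    """One osmolyte arm of the study with its planted hydration number."""

    label: str
    true_n_hyd: float
    molar_mass: float
    molarity: float = 0.75
    density: float = 1.0


#: Seven-osmolyte panel mirroring the measured set: urea accelerates water
#: (negative n_hyd), polyols bind mildly, sugars bind strongly. Densities
#: are nominal 0.75 M solution values at 23 degC.
DEFAULT_PANEL = (
    OsmolyteCondition("urea", -3.0, 60.06, 0.75, 1.0085),
    OsmolyteCondition("pg", 1.5, 76.09, 0.75, 1.0035),
    OsmolyteCondition("deg", 2.5, 106.12, 0.75, 1.006),
    OsmolyteCondition("glycerol", 3.5, 92.09, 0.75, 1.012),
    OsmolyteCondition("fructose", 6.0, 180.16, 0.75, 1.046),
    OsmolyteCondition("sucrose", 7.5, 342.30, 0.75, 1.094),
    OsmolyteCondition("trehalose", 9.0, 342.30, 0.75, 1.095),
)


@dataclass
class StudyDesign:
    """Design of a full synthetic campaign.

    activity_law maps n_hyd to the expected k/k_water as
    ratio = slope * n_hyd + intercept; the default slope is negative
    (water-binding osmolytes suppress activity). Noise levels: additive
    Gaussian on eps'' and on absorbance, multiplicative lognormal (sigma in
    log space) on every realized rate constant.
    """

    osmolytes: tuple[OsmolyteCondition, ...] = DEFAULT_PANEL
    activity_slope: float = -0.05
    activity_intercept: float = 1.0
    n_bottles: int = 5
    bottle_factor_range: tuple[float, float] = (0.8, 1.2)
    replicates: int = 3
    noise_eps: float = 0.02
    noise_abs: float = 0.005
    noise_k: float = 0.05
    base_k: float = 0.01
    include_ternary: bool = True
    ternary_c_scale: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_bottles < 1:
            raise ValueError("need >= 1 replicate and >= 1 bottle")
        lo, hi = self.bottle_factor_range
        if not (0 < lo <= hi):
            raise ValueError("bottle factors must be positive")
        if min(self.noise_eps, self.noise_abs, self.noise_k) < 0:
            raise ValueError("noise levels must be >= 0")
        for osm in self.osmolytes:
            if self.expected_ratio(osm.true_n_hyd) <= 0:
                raise ValueError(
                    f"activity law gives non-positive expected ratio for "
                    f"{osm.label} (n_hyd={osm.true_n_hyd})"
                )

    def expected_ratio(self, n_hyd: float) -> float:
        return self.activity_slope * n_hyd + self.activity_intercept

    def composition(self, osm: OsmolyteCondition) -> SolutionComposition:
        return SolutionComposition(
            molarity=osm.molarity, density=osm.density,
            molar_mass_osmolyte=osm.molar_mass,
        )


@dataclass
class SyntheticStudy:
    """Generated inputs plus the ground truth they encode."""

    water_spectrum: DielectricSpectrum
    solution_spectra: dict
    ternary_spectra: dict
    compositions: dict
    ternary_c: dict
    traces: list
    ground_truth: dict


def gen_study(design: StudyDesign) -> SyntheticStudy:
    """Generate the full campaign for a design, fully seeded.

    Per bottle b: k_water = base_k * bottle_factor_b. Per osmolyte run on
    bottle b: k = k_water_b * expected_ratio(n_hyd) * lognormal noise.
    Water control replicates carry the same run noise. The THz arm gets one
    water spectrum and one (binary, and optionally ternary) spectrum per
    osmolyte.
    """
    rng = np.random.default_rng(design.seed)
    water = water_params()

    water_spectrum = gen_spectrum(
        water, noise_sd=design.noise_eps, seed=rng, label="water"
    )

    solution_spectra: dict = {}
    ternary_spectra: dict = {}
    compositions: dict = {}
    ternary_c: dict = {}
    truth_osm: dict = {}
    for osm in design.osmolytes:
        comp = design.composition(osm)
        compositions[osm.label] = comp
        alpha = waters_per_osmolyte(comp)
        a_hyd = osm.true_n_hyd / alpha
        solution_spectra[osm.label] = gen_spectrum_for_nhyd(
            osm.true_n_hyd, comp, water=water, noise_sd=design.noise_eps,
            seed=rng, label=osm.label,
        )
        truth_osm[osm.label] = {
            "true_n_hyd": osm.true_n_hyd,
            "alpha": alpha,
            "true_a_hyd": a_hyd,
            "expected_ratio": design.expected_ratio(osm.true_n_hyd),
        }
        if design.include_ternary:
            # enzyme displaces some water volume; planted a_hyd unchanged
            c3 = design.ternary_c_scale * water_volume_fraction(comp)
            ternary_c[osm.label] = c3
            d_slow = slow_amplitude_for_ahyd(a_hyd, water)
            params3 = water.with_(delta_eps_slow=d_slow, water_volume_fraction=c3)
            ternary_spectra[osm.label] = gen_spectrum(
                params3, noise_sd=design.noise_eps, seed=rng,
                label=f"{osm.label}+amylase",
            )

    bottle_ids = [f"b{i+1}" for i in range(design.n_bottles)]
    lo, hi = design.bottle_factor_range
    factors = rng.uniform(lo, hi, size=design.n_bottles)
    k_water_bottle = {b: design.base_k * f for b, f in zip(bottle_ids, factors)}

    def run_noise() -> float:
        if design.noise_k == 0:
            return 1.0
        return float(rng.lognormal(mean=0.0, sigma=design.noise_k))

    traces: list[AbsorbanceTrace] = []
    for b in bottle_ids:
        # initial absorbance scales with the bottle's amylose concentration
        a0 = 1.0 * k_water_bottle[b] / design.base_k
        for rep in range(design.replicates):
            traces.append(gen_decay_trace(
                k_water_bottle[b] * run_noise(), A0=a0, B=0.2,
                noise_sd=design.noise_abs, seed=rng,
                osmolyte="water", bottle_id=b, replicate_id=f"r{rep+1}",
            ))
        for osm in design.osmolytes:
            expected = design.expected_ratio(osm.true_n_hyd)
            for rep in range(design.replicates):
                traces.append(gen_decay_trace(
                    k_water_bottle[b] * expected * run_noise(), A0=a0, B=0.2,
                    noise_sd=design.noise_abs, seed=rng,
                    osmolyte=osm.label, bottle_id=b, replicate_id=f"r{rep+1}",
                ))

    ground_truth = {
        "seed": design.seed,
        "activity_slope": design.activity_slope,
        "activity_intercept": design.activity_intercept,
        "base_k": design.base_k,
        "bottle_factors": {b: float(f) for b, f in zip(bottle_ids, factors)},
        "osmolytes": truth_osm,
        "noise": {"eps": design.noise_eps, "abs": design.noise_abs,
                  "k": design.noise_k},
    }
    return SyntheticStudy(
        water_spectrum=water_spectrum,
        solution_spectra=solution_spectra,
        ternary_spectra=ternary_spectra,
        compositions=compositions,
        ternary_c=ternary_c,
        traces=traces,
        ground_truth=ground_truth,
    )
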