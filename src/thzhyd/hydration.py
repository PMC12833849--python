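"""Hydration fraction and hydration number from fitted dielectric amplitudes.

The drop of the slow-relaxation amplitude relative to pure water counts
water molecules whose collective dynamics have been retarded out of the
THz window; a rise of the fast amplitude counts molecules freed from the
network and is subtracted. Kirkwood correlation factors (2.9 slow, 1.0
fast) correct the dipole correlation before the amplitudes are read as
molecule counts::

    a_hyd = [ (d_slow_w - d_slow_s)/2.9 - (d_fast_s - d_fast_w)/1.0 ]
            / [ d_slow_w/2.9 + d_fast_w/1.0 ]

    n_hyd = alpha * a_hyd

where alpha is the number of water molecules per osmolyte molecule,
computed from molarity, solution density and molar masses. A negative
n_hyd marks a structure-breaking ("negative hydration") osmolyte that
accelerates the collective water dynamics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

from . import constants as C
from .dielectric_model import DielectricSpectrum
from .spectral_fit import FitConfig, FitResult, fit_pure_water, fit_solution

__all__ = [
    "SolutionComposition",
    "HydrationResult",
    "water_volume_fraction",
    "waters_per_osmolyte",
    "hydration_fraction",
    "hydration_number",
    "sensitivity_sweep",
    "osmolyte_molar_mass",
]

log = logging.getLogger(__name__)


class CompositionError(ValueError):
    """Implausible molarity/density pair (non-positive water mass)."""


@dataclass(frozen=True)
class SolutionComposition:
    """Osmolyte solution make-up: molarity C (mol/L), density rho (g/mL).

    ``water_density_ref`` is the pure-water density at the temperature the
    solution density was measured (23 degC by default).
    """

    molarity: float
    density: float
    molar_mass_osmolyte: float
    molar_mass_water: float = C.MOLAR_MASS_WATER
    water_density_ref: float = C.WATER_DENSITY_REF

    def __post_init__(self) -> None:
        if self.molarity < 0:
            raise ValueError("molarity must be >= 0")
        if self.density <= 0 or self.molar_mass_osmolyte <= 0:
            raise ValueError("density and molar mass must be positive")
        if self.water_mass_per_liter() <= 0:
            raise CompositionError(
                f"molarity {self.molarity} mol/L of M={self.molar_mass_osmolyte}"
                f" g/mol leaves no water at density {self.density} g/mL"
            )

    def water_mass_per_liter(self) -> float:
        """Grams of water per liter of solution, by mass balance."""
        return 1000.0 * self.density - self.molarity * self.molar_mass_osmolyte


def water_volume_fraction(comp: SolutionComposition) -> float:
    """Volume fraction c of water, from the solution density.

    Mass balance per liter: the osmolyte contributes C*M_s grams, the rest
    is water; dividing the water mass by the pure-water reference density
    gives the water volume.
    """
    m_w = comp.water_mass_per_liter()
    c = (m_w / comp.water_density_ref) / 1000.0
    if not (0.0 < c <= 1.0):
        raise CompositionError(
            f"computed water volume fraction {c:.4f} outside (0, 1]"
        )
    return c


def waters_per_osmolyte(comp: SolutionComposition) -> float:
    """alpha: water molecules per osmolyte molecule in the solution."""
    if comp.molarity <= 0:
        raise ValueError("alpha is undefined for pure water (molarity = 0)")
    moles_water = comp.water_mass_per_liter() / comp.molar_mass_water
    return moles_water / comp.molarity


def hydration_fraction(water_fit: FitResult, solution_fit: FitResult) -> float:
    """Fraction a_hyd of all water with solute-altered collective dynamics.

    May be negative (accelerated dynamics); never exceeds 1.
    """
    if not (water_fit.converged and solution_fit.converged):
        raise ValueError("both fits must have converged")
    dsw = water_fit.params.delta_eps_slow
    dfw = water_fit.params.delta_eps_fast
    if dsw <= 0:
        raise ValueError("water slow amplitude must be positive")
    if solution_fit.temperature != water_fit.temperature:
        log.warning(
            "temperature mismatch: water fit at %.1f C, solution fit at %.1f C",
            water_fit.temperature, solution_fit.temperature,
        )
    dss = solution_fit.params.delta_eps_slow
    dfs = solution_fit.params.delta_eps_fast
    num = (dsw - dss) / C.KIRKWOOD_SLOW - (dfs - dfw) / C.KIRKWOOD_FAST
    den = dsw / C.KIRKWOOD_SLOW + dfw / C.KIRKWOOD_FAST
    return num / den


def hydration_number(a_hyd: float, alpha: float) -> float:
    """n_hyd = alpha * a_hyd; waters per osmolyte with altered dynamics."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha * a_hyd


@dataclass
class HydrationResult:
    """Central hydration estimate with A_s-sweep sensitivity bounds.

    For ternary (enzyme-containing) systems only a_hyd is meaningful;
    n_hyd fields are None there.
    """

    a_hyd: float
    a_hyd_lo: float
    a_hyd_hi: float
    n_hyd: float | None = None
    n_hyd_lo: float | None = None
    n_hyd_hi: float | None = None
    alpha: float | None = None
    water_volume_fraction_used: float | None = None
    converged: bool = True
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "a_hyd": self.a_hyd,
            "a_hyd_lo": self.a_hyd_lo,
            "a_hyd_hi": self.a_hyd_hi,
            "n_hyd": self.n_hyd,
            "n_hyd_lo": self.n_hyd_lo,
            "n_hyd_hi": self.n_hyd_hi,
            "alpha": self.alpha,
            "water_volume_fraction": self.water_volume_fraction_used,
            "converged": self.converged,
        }


def sensitivity_sweep(
    solution_spectrum: DielectricSpectrum,
    water_spectrum: DielectricSpectrum,
    composition: SolutionComposition | None = None,
    a_s_values: tuple[float, ...] = C.AS_SWEEP,
    c_override: float | None = None,
    config: FitConfig | None = None,
) -> HydrationResult:
    """Refit at each A_s and report central value plus min/max bounds.

    The solution spectrum is refit with A_s fixed at each sweep value; the
    water reference is refit consistently with A_s fixed to the same value
    (only the two amplitudes free) so that water and solution share the
    oscillator background. The central estimate is at 35.0 THz² (or the
    sweep's midpoint if 35.0 is absent); bounds are the sweep min/max.

    If ``composition`` is given, c and alpha come from it and n_hyd is
    reported; with ``c_override`` (ternary systems) only a_hyd is reported.
    """
    if not a_s_values:
        raise ValueError("a_s_values must be non-empty")
    config = config or FitConfig()
    if composition is not None:
        c = water_volume_fraction(composition)
        alpha = waters_per_osmolyte(composition)
    elif c_override is not None:
        c = c_override
        alpha = None
    else:
        raise ValueError("provide either composition or c_override")

    a_vals: list[float] = []
    ok = True
    for a_s in a_s_values:
        cfg = FitConfig(fit_band=config.fit_band, fixed=config.fixed,
                        initial=config.initial, amp_stretch=a_s)
        # consistent reference: water amplitudes refit with this A_s fixed
        wfit = fit_solution(water_spectrum, 1.0, cfg)
        sfit = fit_solution(solution_spectrum, c, cfg)
        ok = ok and wfit.converged and sfit.converged
        a_vals.append(hydration_fraction(wfit, sfit))

    central_as = 35.0 if 35.0 in a_s_values else a_s_values[len(a_s_values) // 2]
    central = a_vals[list(a_s_values).index(central_as)]
    lo, hi = min(a_vals), max(a_vals)
    res = HydrationResult(
        a_hyd=central, a_hyd_lo=lo, a_hyd_hi=hi,
        water_volume_fraction_used=c, converged=ok,
        label=solution_spectrum.label,
    )
    if alpha is not None:
        nv = [hydration_number(a, alpha) for a in a_vals]
        res.alpha = alpha
        res.n_hyd = hydration_number(central, alpha)
        res.n_hyd_lo = min(nv)
        res.n_hyd_hi = max(nv)
    return res


def osmolyte_molar_mass(name: str) -> float:
    """Molar mass (g/mol) of a known osmolyte from the shipped table."""
    table = json.loads(
        resources.files("thzhyd.data").joinpath("osmolytes.json").read_text()
    )
    key = name.lower()
    if key not in table:
        raise KeyError(
            f"unknown osmolyte {name!r}; known: {sorted(table)}"
        )
    return float(table[key]["molar_mass"])
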