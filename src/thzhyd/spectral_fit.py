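"""Constrained least-squares fitting of eps'' spectra in the 0.3-2.5 THz band.

Protocol: the relaxation times and the stretching-vibration shape
parameters are always held at the pure-water literature values. For pure
water the two Debye amplitudes and the oscillator amplitude A_s are free;
for solutions A_s is additionally fixed (35.0 THz² by default) and only
the two amplitudes are fitted, with the water volume fraction c supplied
from the solution composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np

from . import constants as C
from .dielectric_model import DielectricModelParams, DielectricSpectrum, eval_imag_on_grid

__all__ = ["FitConfig", "FitResult", "fit_pure_water", "fit_solution"]

log = logging.getLogger(__name__)

#: Parameters that are never free: literature values at 20 degC.
_FIXED_SHAPE = {
    "tau_slow": C.TAU_SLOW_PS,
    "tau_fast": C.TAU_FAST_PS,
    "freq_stretch": C.FREQ_STRETCH_THZ,
    "damping_stretch": C.DAMPING_STRETCH_THZ,
}

_MIN_POINTS = 10


class InsufficientDataError(ValueError):
    """Raised when fewer than the minimum number of in-band points exist."""


@dataclass(frozen=True)
class FitConfig:
    """Fit protocol knobs.

    fit_band is the (min, max) frequency window in THz; only samples inside
    it enter the residual. ``fixed`` overrides which parameters are held
    constant (name -> value); ``initial`` overrides start values; bounds are
    [0, AMP_BOUND_FACTOR * water value] for amplitudes. Weighting is uniform.
    """

    fit_band: tuple[float, float] = C.FIT_BAND
    fixed: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    amp_stretch: float = C.AMP_STRETCH_THZ2

    def __post_init__(self) -> None:
        lo, hi = self.fit_band
        if not (0 < lo < hi):
            raise ValueError("fit_band must satisfy 0 < min < max (THz)")


@dataclass
class FitResult:
    """Outcome of one spectrum fit: fitted + fixed parameters merged."""

    params: DielectricModelParams
    residual_rms: float
    n_points: int
    converged: bool
    free_names: tuple[str, ...]
    stderr: dict | None = None
    label: str = ""
    temperature: float = 20.0

    def to_dict(self) -> dict:
        d = {
            "delta_eps_slow": self.params.delta_eps_slow,
            "delta_eps_fast": self.params.delta_eps_fast,
            "tau_slow_ps": self.params.tau_slow,
            "tau_fast_ps": self.params.tau_fast,
            "amp_stretch_thz2": self.params.amp_stretch,
            "freq_stretch_thz": self.params.freq_stretch,
            "damping_stretch_thz": self.params.damping_stretch,
            "water_volume_fraction": self.params.water_volume_fraction,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "converged": self.converged,
            "free": list(self.free_names),
            "label": self.label,
            "temperature_C": self.temperature,
        }
        if self.stderr:
            d["stderr"] = dict(self.stderr)
        return d


def _run_fit(
    spectrum: DielectricSpectrum,
    config: FitConfig,
    free: tuple[str, ...],
    fixed_values: dict,
    c: float,
) -> FitResult:
    band = spectrum.band(*config.fit_band)
    if len(band) < _MIN_POINTS:
        raise InsufficientDataError(
            f"only {len(band)} points inside fit band {config.fit_band}; "
            f"need >= {_MIN_POINTS}"
        )

    p = lmfit.Parameters()
    water_ref = {
        "delta_eps_slow": C.WATER_DELTA_EPS_SLOW,
        "delta_eps_fast": C.WATER_DELTA_EPS_FAST,
        "amp_stretch": C.AMP_STRETCH_THZ2,
    }
    for name in ("delta_eps_slow", "delta_eps_fast", "amp_stretch"):
        if name in free:
            init = config.initial.get(name, water_ref[name])
            p.add(name, value=init, min=0.0, max=C.AMP_BOUND_FACTOR * water_ref[name])
        else:
            p.add(name, value=fixed_values[name], vary=False)
    for name, val in _FIXED_SHAPE.items():
        p.add(name, value=config.fixed.get(name, val), vary=False)

    grid = band.frequencies
    data = band.eps_imag

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        mp = DielectricModelParams(
            delta_eps_slow=pars["delta_eps_slow"].value,
            delta_eps_fast=pars["delta_eps_fast"].value,
            tau_slow=pars["tau_slow"].value,
            tau_fast=pars["tau_fast"].value,
            amp_stretch=pars["amp_stretch"].value,
            freq_stretch=pars["freq_stretch"].value,
            damping_stretch=pars["damping_stretch"].value,
            water_volume_fraction=c,
        )
        return eval_imag_on_grid(mp, grid) - data

    # near-zero residuals (noiseless spectra) make lmfit's correlation
    # matrix divide by zero; that path is irrelevant here
    with np.errstate(invalid="ignore", divide="ignore"):
        out = lmfit.minimize(
            residual,
            p,
            method="least_squares",
            max_nfev=C.FIT_MAX_ITER * (len(free) + 1),
            ftol=C.FIT_COST_TOL,
            xtol=C.FIT_COST_TOL,
            gtol=C.FIT_COST_TOL,
        )
    converged = bool(out.success)
    if not converged:
        log.warning("fit of %r did not converge: %s", spectrum.label, out.message)

    fitted = DielectricModelParams(
        delta_eps_slow=out.params["delta_eps_slow"].value,
        delta_eps_fast=out.params["delta_eps_fast"].value,
        tau_slow=out.params["tau_slow"].value,
        tau_fast=out.params["tau_fast"].value,
        amp_stretch=out.params["amp_stretch"].value,
        freq_stretch=out.params["freq_stretch"].value,
        damping_stretch=out.params["damping_stretch"].value,
        water_volume_fraction=c,
    )
    resid = residual(out.params)
    stderr = {
        n: out.params[n].stderr
        for n in free
        if out.params[n].stderr is not None
    } or None
    log.info(
        "fit %r: band=%s free=%s rms=%.3e n=%d converged=%s",
        spectrum.label, config.fit_band, free,
        float(np.sqrt(np.mean(resid**2))), len(band), converged,
    )
    return FitResult(
        params=fitted,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(band),
        converged=converged,
        free_names=free,
        stderr=stderr,
        label=spectrum.label,
        temperature=spectrum.temperature,
    )


def fit_pure_water(
    spectrum: DielectricSpectrum, config: FitConfig | None = None
) -> FitResult:
    """Fit a pure-water eps'' spectrum (c = 1).

    Free parameters: the two Debye amplitudes and the oscillator amplitude
    A_s. Relaxation times and oscillator shape are fixed at the 20 degC
    literature values (9.20 ps, 0.245 ps, 5.30 THz, 32.5 THz).
    """
    config = config or FitConfig()
    return _run_fit(
        spectrum,
        config,
        free=("delta_eps_slow", "delta_eps_fast", "amp_stretch"),
        fixed_values={},
        c=1.0,
    )


def fit_solution(
    spectrum: DielectricSpectrum,
    composition_c: float,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a solution eps'' spectrum at known water volume fraction c.

    Free parameters: the two Debye amplitudes only. A_s is fixed
    (config.amp_stretch, default 35.0 THz²). Amplitudes are bounded below
    by zero but not clipped at the pure-water values: solutes that
    accelerate water dynamics (urea-like) legitimately exceed them.
    """
    if not (0.0 < composition_c <= 1.0):
        raise ValueError(f"composition_c must be in (0, 1], got {composition_c}")
    config = config or FitConfig()
    return _run_fit(
        spectrum,
        config,
        free=("delta_eps_slow", "delta_eps_fast"),
        fixed_values={"amp_stretch": config.amp_stretch},
        c=composition_c,
    )
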