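"""Dielectric function of water in the THz band.

The model is the sum of two Debye relaxations (the collective "slow"
reorientation of the hydrogen-bonded network, ~9 ps, and the "fast"
relaxation of transiently free water molecules, ~0.25 ps) plus one damped
harmonic oscillator for the intermolecular stretching vibration near
5.3 THz, the whole scaled by the water volume fraction ``c``::

    eps(nu) = c * [ d_slow / (1 - i*2*pi*nu*tau_slow)
                  + d_fast / (1 - i*2*pi*nu*tau_fast)
                  + A_s / (nu_s**2 - nu**2 - i*nu*gamma_s) ]

with ``nu`` in THz and ``tau`` in ps, so that ``2*pi*nu*tau`` is
dimensionless and the oscillator term is formed in THz². The sign
convention is eps = eps' + i*eps'' with eps'' >= 0 for passive media;
solutes are assumed not to absorb in this band, so the whole signal is
attributed to (bulk-like) water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C

__all__ = [
    "DielectricModelParams",
    "DielectricSpectrum",
    "water_params",
    "eval_model",
    "eval_imag_on_grid",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class DielectricModelParams:
    """Parameter set of the water dielectric model.

    Attributes
    ----------
    delta_eps_slow, delta_eps_fast : float
        Dimensionless amplitudes of the slow and fast Debye relaxations.
    tau_slow, tau_fast : float
        Relaxation times in ps; the slow time must exceed the fast one.
    amp_stretch : float
        Oscillator amplitude A_s in THz².
    freq_stretch, damping_stretch : float
        Resonance frequency and damping constant of the intermolecular
        stretching vibration, both in THz.
    water_volume_fraction : float
        Volume fraction c of water in the sample, in (0, 1].
    """

    delta_eps_slow: float
    delta_eps_fast: float
    tau_slow: float = C.TAU_SLOW_PS
    tau_fast: float = C.TAU_FAST_PS
    amp_stretch: float = C.AMP_STRETCH_THZ2
    freq_stretch: float = C.FREQ_STRETCH_THZ
    damping_stretch: float = C.DAMPING_STRETCH_THZ
    water_volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_eps_slow < 0 or self.delta_eps_fast < 0:
            raise ValueError("relaxation amplitudes must be non-negative")
        if not (self.tau_slow > self.tau_fast > 0):
            raise ValueError("require tau_slow > tau_fast > 0 (ps)")
        if self.amp_stretch < 0:
            raise ValueError("oscillator amplitude A_s must be non-negative")
        if self.freq_stretch <= 0 or self.damping_stretch <= 0:
            raise ValueError("oscillator frequency and damping must be positive")
        if not (0.0 < self.water_volume_fraction <= 1.0):
            raise ValueError(
                f"water volume fraction must lie in (0, 1], got "
                f"{self.water_volume_fraction}"
            )

    def with_(self, **changes) -> "DielectricModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)


def water_params(c: float = 1.0) -> DielectricModelParams:
    """Pure-water parameter set at 20 °C, optionally diluted to fraction c."""
    return DielectricModelParams(
        delta_eps_slow=C.WATER_DELTA_EPS_SLOW,
        delta_eps_fast=C.WATER_DELTA_EPS_FAST,
        water_volume_fraction=c,
    )


@dataclass
class DielectricSpectrum:
    """Sampled complex permittivity on a strictly increasing frequency grid.

    ``eps_real`` is optional: the analysis fits the imaginary part only,
    because the real part barely responds to hydration and carries a larger
    standard deviation.
    """

    frequencies: np.ndarray
    eps_imag: np.ndarray
    eps_real: np.ndarray | None = None
    temperature: float = 20.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must all be positive (THz)")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.eps_imag.shape != self.frequencies.shape:
            raise ValueError("eps_imag must match the frequency grid length")
        if not np.all(np.isfinite(self.eps_imag)):
            raise ValueError("eps_imag must be finite")
        if self.eps_real is not None:
            self.eps_real = np.asarray(self.eps_real, dtype=float)
            if self.eps_real.shape != self.frequencies.shape:
                raise ValueError("eps_real must match the frequency grid length")

    def band(self, fmin: float, fmax: float) -> "DielectricSpectrum":
        """Restrict to samples with fmin <= frequency <= fmax."""
        m = (self.frequencies >= fmin) & (self.frequencies <= fmax)
        return DielectricSpectrum(
            frequencies=self.frequencies[m],
            eps_imag=self.eps_imag[m],
            eps_real=None if self.eps_real is None else self.eps_real[m],
            temperature=self.temperature,
            label=self.label,
        )

    def __len__(self) -> int:
        return int(self.frequencies.size)


def eval_model(params: DielectricModelParams, freq) -> np.ndarray | complex:
    """Evaluate the complex permittivity contribution of water at ``freq``.

    Parameters
    ----------
    params : DielectricModelParams
    freq : float or array
        Frequency in THz; must be positive.

    Returns
    -------
    complex or complex ndarray, with non-negative imaginary part for valid
    parameters.
    """
    nu = np.asarray(freq, dtype=float)
    scalar = nu.ndim == 0
    if np.any(nu <= 0):
        raise ValueError("frequency must be positive (THz)")

    slow = params.delta_eps_slow / (1.0 - 1j * _TWO_PI * nu * params.tau_slow)
    fast = params.delta_eps_fast / (1.0 - 1j * _TWO_PI * nu * params.tau_fast)
    osc = params.amp_stretch / (
        params.freq_stretch**2 - nu**2 - 1j * nu * params.damping_stretch
    )
    eps = params.water_volume_fraction * (slow + fast + osc)
    return complex(eps) if scalar else eps


def eval_imag_on_grid(params: DielectricModelParams, grid) -> np.ndarray:
    """Vectorized eps'' on a strictly increasing positive frequency grid.

    This is the quantity the fitter targets; same length as ``grid``.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(g <= 0):
        raise ValueError("grid frequencies must be positive (THz)")
    if np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly increasing")
    return np.imag(eval_model(params, g))
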