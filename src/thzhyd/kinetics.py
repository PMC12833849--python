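"""First-order kinetics of the iodine-starch bleaching assay.

Amylase cleavage of amylose destroys the iodine-binding helix, so the
615 nm absorbance decays as Abs(t) = B + A0*exp(-k*t). Samples within the
first 15 s are discarded (stirring transients) and time is re-origined at
the first retained sample, so A0 + B is the absorbance at 15 s. Rate
constants are normalized per amylose bottle against same-bottle water
controls, which cancels the bottle-to-bottle amylose concentration
variation introduced by filtration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import constants as C

__all__ = ["AbsorbanceTrace", "KineticsRun", "NormalizedRate", "fit_decay", "normalize_rates"]

log = logging.getLogger(__name__)

_MIN_RETAINED = 10


@dataclass
class AbsorbanceTrace:
    """One 615 nm absorbance time series with its sample identity."""

    times: np.ndarray
    absorbance: np.ndarray
    osmolyte: str = "water"
    bottle_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.absorbance.shape != self.times.shape:
            raise ValueError("absorbance must match times in length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class KineticsRun:
    """Fitted decay: rate k (1/s), amplitude A0, background B."""

    k: float
    A0: float
    B: float
    residual_rms: float
    converged: bool
    n_points: int
    osmolyte: str = "water"
    bottle_id: str = ""
    replicate_id: str = ""
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.k, "A0": self.A0, "B": self.B,
            "residual_rms": self.residual_rms, "converged": self.converged,
            "n_points": self.n_points, "osmolyte": self.osmolyte,
            "bottle_id": self.bottle_id, "replicate_id": self.replicate_id,
            "flag": self.flag,
        }


@dataclass
class NormalizedRate:
    """Per-osmolyte aggregation of bottle-paired k/k_water ratios."""

    osmolyte: str
    ratios: list = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.ratios)

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def sd_ratio(self) -> float:
        # sample (n-1) standard deviation, as for the published error bars
        if len(self.ratios) < 2:
            return 0.0
        return float(np.std(self.ratios, ddof=1))

    def to_dict(self) -> dict:
        return {
            "osmolyte": self.osmolyte, "ratios": list(map(float, self.ratios)),
            "mean_ratio": self.mean_ratio, "sd_ratio": self.sd_ratio,
            "n_runs": self.n_runs,
        }


def fit_decay(trace: AbsorbanceTrace, start_trim_s: float = C.START_TRIM_S) -> KineticsRun:
    """Fit Abs(t) = B + A0*exp(-k*t) to a trimmed, re-origined trace.

    Points earlier than ``start_trim_s`` are dropped and t = 0 is reset to
    the first retained sample. k is bounded positive. A trace whose
    absorbance trends upward is flagged as a non-decay rather than fitted
    silently.
    """
    keep = trace.times >= start_trim_s
    t = trace.times[keep]
    y = trace.absorbance[keep]
    if t.size < _MIN_RETAINED:
        raise ValueError(
            f"only {t.size} samples at/after {start_trim_s} s; need >= {_MIN_RETAINED}"
        )
    if t[-1] - t[0] < 60.0:
        raise ValueError("trace must cover at least 60 s beyond the trim")
    t = t - t[0]

    meta = dict(osmolyte=trace.osmolyte, bottle_id=trace.bottle_id,
                replicate_id=trace.replicate_id)

    # guard: a rising trace is not a first-order bleaching decay
    slope = np.polyfit(t, y, 1)[0]
    if slope > 0:
        log.warning("trace %s/%s/%s rises with time; flagged as non-decay",
                    trace.osmolyte, trace.bottle_id, trace.replicate_id)
        return KineticsRun(k=np.nan, A0=np.nan, B=np.nan, residual_rms=np.nan,
                           converged=False, n_points=t.size,
                           flag="non-decay", **meta)

    b0 = max(float(y.min()), 0.0)
    a0 = max(float(y[0] - b0), 1e-6)
    # crude rate from the 1/e crossing of the baseline-subtracted signal
    yc = y - b0
    below = np.nonzero(yc < a0 / np.e)[0]
    k0 = 1.0 / t[below[0]] if below.size and below[0] > 0 else 1.0 / max(t[-1], 1.0)

    def model(tt, B, A0, k):
        return B + A0 * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[b0, a0, k0],
            bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        log.warning("decay fit failed for %s/%s/%s: %s",
                    trace.osmolyte, trace.bottle_id, trace.replicate_id, exc)
        return KineticsRun(k=np.nan, A0=np.nan, B=np.nan, residual_rms=np.nan,
                           converged=False, n_points=t.size,
                           flag="non-convergent", **meta)

    B, A0, k = map(float, popt)
    resid = y - model(t, B, A0, k)
    return KineticsRun(k=k, A0=A0, B=B,
                       residual_rms=float(np.sqrt(np.mean(resid**2))),
                       converged=True, n_points=t.size, **meta)


def normalize_rates(runs: list[KineticsRun]) -> tuple[list[NormalizedRate], list[KineticsRun]]:
    """Normalize osmolyte rate constants by same-bottle water controls.

    k_water for a bottle is the mean k over that bottle's (converged) water
    runs. Each osmolyte run contributes one ratio k/k_water, grouped by
    osmolyte. Runs whose bottle has no water control are excluded and
    returned in the rejects list along with non-converged runs.
    """
    ok = [r for r in runs if r.converged]
    rejects = [r for r in runs if not r.converged]

    k_water: dict[str, float] = {}
    for bottle in {r.bottle_id for r in ok if r.osmolyte == "water"}:
        ks = [r.k for r in ok if r.osmolyte == "water" and r.bottle_id == bottle]
        k_water[bottle] = float(np.mean(ks))

    grouped: dict[str, NormalizedRate] = {}
    for r in ok:
        if r.osmolyte == "water":
            continue
        if r.bottle_id not in k_water:
            log.warning("run %s/%s/%s has no same-bottle water control; excluded",
                        r.osmolyte, r.bottle_id, r.replicate_id)
            r.flag = "no-water-control"
            rejects.append(r)
            continue
        grouped.setdefault(r.osmolyte, NormalizedRate(r.osmolyte)).ratios.append(
            r.k / k_water[r.bottle_id]
        )
    return list(grouped.values()), rejects
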