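"""Ordinary least-squares correlation of water-dynamics measures with activity.

One planned simple regression per panel: normalized reaction rate
k/k_water against n_hyd (binary osmolyte/water systems) or a_hyd (ternary
enzyme/osmolyte/water systems). The fit is unweighted; error bars on both
axes are carried along for reporting and plotting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorrelationInput", "CorrelationResult", "linear_fit", "report"]


@dataclass
class CorrelationInput:
    """Per-osmolyte points (x = n_hyd or a_hyd, y = mean k/k_water)."""

    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    x_err: np.ndarray | None = None
    labels: list = field(default_factory=list)
    axis_kind: str = "n_hyd"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise ValueError("need at least 3 points for a correlation")
        if np.any(self.y <= 0):
            raise ValueError("normalized rates must be positive")
        if self.axis_kind not in ("n_hyd", "a_hyd"):
            raise ValueError("axis_kind must be 'n_hyd' or 'a_hyd'")


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    axis_kind: str = "n_hyd"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n_points": self.n_points,
            "axis_kind": self.axis_kind,
        }


def linear_fit(inp: CorrelationInput) -> CorrelationResult:
    """Unweighted OLS of y on x with R² = 1 - SS_res/SS_tot.

    Solved by the normal equations in centered coordinates; for simple
    regression this R² equals the squared Pearson correlation.
    """
    x, y = inp.x, inp.y
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values equal")
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(np.dot(xc, yc) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.dot(yc, yc))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CorrelationResult(slope=slope, intercept=intercept, r_squared=r2,
                             n_points=int(x.size), axis_kind=inp.axis_kind)


def _panel(inp: CorrelationInput | None, res: CorrelationResult | None) -> dict | None:
    if inp is None or res is None:
        return None
    d = res.to_dict()
    d["points"] = [
        {
            "label": (inp.labels[i] if i < len(inp.labels) else str(i)),
            "x": float(inp.x[i]),
            "y": float(inp.y[i]),
            "y_err": (float(inp.y_err[i]) if inp.y_err is not None else None),
            "x_err": (float(inp.x_err[i]) if inp.x_err is not None else None),
        }
        for i in range(inp.x.size)
    ]
    return d


def report(
    binary: CorrelationResult,
    ternary: CorrelationResult | None = None,
    binary_input: CorrelationInput | None = None,
    ternary_input: CorrelationInput | None = None,
) -> dict:
    """Joint summary of the binary and ternary correlation panels.

    Adds a sign-consistency flag: both slopes negative means water-binding
    osmolytes suppress activity in both system types.
    """
    out: dict = {
        "binary": _panel(binary_input, binary) or binary.to_dict(),
        "ternary": None,
        "consistent_negative_slopes": None,
        "note": "",
    }
    if ternary is None:
        out["note"] = "ternary panel omitted: no ternary input provided"
        return out
    out["ternary"] = _panel(ternary_input, ternary) or ternary.to_dict()
    consistent = binary.slope < 0 and ternary.slope < 0
    out["consistent_negative_slopes"] = consistent
    if consistent:
        out["note"] = ("both slopes negative: water-binding osmolytes suppress "
                       "activity; water-mobilizing osmolytes enhance it")
    else:
        out["note"] = ("slopes disagree in sign between binary and ternary "
                       "panels; no unified water-mediated trend")
    return out
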