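"""Constant-voltage GFET measurement model.

A graphene field-effect transistor operated at fixed gate (V_g) and drain
(V_ds) voltages transduces the oxidized-product concentration (e.g. the ABTS
radical cation) into a drain–source current change. This module provides

* calibration-curve construction: ordinary least squares of |ΔI_ds| against
  product concentration, with automatic detection of the linear range;
* the bidirectional mapping between current traces and concentration time
  series, with a smooth saturation plateau above the linear range and
  seeded Gaussian current noise for the forward (synthesis) direction.

The absolute current change |ΔI_ds| is used as the response; graphene's
bipolar (ambipolar) conduction makes the sign of the raw shift depend on the
operating point, so sign is metadata, not signal. The per-trace baseline is
the first sample, matching measurements where the current returns to baseline
after washing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CurrentTrace",
    "CalibrationModel",
    "CalibrationError",
    "fit_calibration",
    "current_to_concentration",
    "concentration_to_current",
]


class CalibrationError(ValueError):
    """No contiguous concentration window yields an acceptable linear fit."""


@dataclass(frozen=True)
class CurrentTrace:
    """Drain–source current (μA) sampled over time at constant voltages."""

    times: np.ndarray
    I_ds: np.ndarray
    V_g_mV: float
    V_ds_mV: float
    condition_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        I = np.asarray(self.I_ds, dtype=float)
        if times.shape != I.shape or times.ndim != 1:
            raise ValueError("times and I_ds must be aligned 1-D arrays")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "I_ds", I)

    @property
    def baseline(self) -> float:
        return float(self.I_ds[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "I_ds_uA": self.I_ds,
                "V_g_mV": self.V_g_mV,
                "V_ds_mV": self.V_ds_mV,
                "condition_id": self.condition_id,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CurrentTrace":
        return cls(
            times=df["time_s"].to_numpy(dtype=float),
            I_ds=df["I_ds_uA"].to_numpy(dtype=float),
            V_g_mV=float(df["V_g_mV"].iloc[0]),
            V_ds_mV=float(df["V_ds_mV"].iloc[0]),
            condition_id=str(df["condition_id"].iloc[0]) if "condition_id" in df else "",
        )

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class CalibrationModel:
    """Affine |ΔI| ↔ concentration map valid over a detected linear range.

    slope is in μA/μM, intercept in μA; ``linear_range`` is the (low, high)
    concentration window (μM) over which the fit reached the requested r².
    """

    slope: float
    intercept: float
    linear_range: tuple
    r2: float
    residual_sd: float

    def __post_init__(self) -> None:
        low, high = self.linear_range
        if not (np.isfinite(self.slope) and self.slope != 0):
            raise ValueError("slope must be finite and nonzero")
        if not low < high:
            raise ValueError("linear_range must satisfy low < high")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope_uA_per_uM": self.slope,
            "intercept_uA": self.intercept,
            "linear_range_uM": list(self.linear_range),
            "r2": self.r2,
            "residual_sd_uA": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=d["slope_uA_per_uM"],
            intercept=d["intercept_uA"],
            linear_range=tuple(d["linear_range_uM"]),
            r2=d["r2"],
            residual_sd=d["residual_sd_uA"],
        )


def fit_calibration(
    concs: Sequence[float], delta_I: Sequence[float], r2_min: float = 0.99
) -> CalibrationModel:
    """Fit the calibration line and detect the linear range.

    The linear range is the largest contiguous prefix window (anchored at the
    lowest concentration, where biosensor calibration curves are linear) whose
    OLS fit of |ΔI| on concentration reaches r² ≥ ``r2_min`` with at least 3
    points; slope and intercept come from that window.
    """
    c = np.asarray(concs, dtype=float)
    dI = np.abs(np.asarray(delta_I, dtype=float))
    if c.ndim != 1 or c.shape != dI.shape or len(c) < 4:
        raise ValueError("need >= 4 aligned (concentration, delta_I) pairs")
    if not np.all(np.diff(c) > 0):
        raise ValueError("concentrations must be distinct and sorted ascending")

    best: Optional[tuple] = None
    for stop in range(len(c), 2, -1):  # longest window first
        res = stats.linregress(c[:stop], dI[:stop])
        r2 = res.rvalue**2
        if np.isfinite(r2) and r2 >= r2_min:
            best = (stop, res, r2)
            break
    if best is None:
        raise CalibrationError(
            f"no contiguous prefix window of >= 3 points reaches r2 >= {r2_min}"
        )
    stop, res, r2 = best
    resid = dI[:stop] - (res.intercept + res.slope * c[:stop])
    dof = max(stop - 2, 1)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        linear_range=(float(c[0]), float(c[stop - 1])),
        r2=float(r2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def _saturate(conc: np.ndarray, high: float, width: float) -> np.ndarray:
    """Identity below ``high``; smooth rational plateau above.

    For excess x = c - high the effective concentration is
    high + x/(1 + x/width): continuous with unit slope at the breakpoint and
    bounded by high + width, emulating the response plateau seen once the
    transducer leaves its linear range.
    """
    excess = np.maximum(conc - high, 0.0)
    return np.minimum(conc, high) + excess / (1.0 + excess / width)


def concentration_to_current(
    product: Sequence[float],
    cal: CalibrationModel,
    noise_sd: float,
    seed: int,
    *,
    times: Optional[Sequence[float]] = None,
    baseline: float = 10.0,
    V_g_mV: float = 500.0,
    V_ds_mV: float = 500.0,
    condition_id: str = "",
) -> CurrentTrace:
    """Forward signal model: synthesize a current trace from product (μM).

    I(t) = baseline + slope·sat(product(t)) + intercept + N(0, noise_sd²),
    where ``sat`` is the identity inside the linear range and a smooth plateau
    above it. The seed is mandatory; identical seeds give identical traces.
    """
    prod = np.asarray(product, dtype=float)
    if np.any(prod < 0) or not np.all(np.isfinite(prod)):
        raise ValueError("product concentrations must be finite and non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    low, high = cal.linear_range
    width = 0.5 * (high - low)
    effective = _saturate(prod, high, width)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=prod.shape) if noise_sd > 0 else 0.0
    I = baseline + cal.slope * effective + cal.intercept + noise
    t = np.arange(len(prod), dtype=float) if times is None else np.asarray(times, dtype=float)
    return CurrentTrace(times=t, I_ds=I, V_g_mV=V_g_mV, V_ds_mV=V_ds_mV, condition_id=condition_id)


def current_to_concentration(
    trace: CurrentTrace, cal: CalibrationModel
) -> pd.DataFrame:
    """Invert a trace to product concentration via the calibration line.

    c(t) = (|I(t) − I(0)| − intercept)/slope, clamped at 0. Returns a frame
    with columns time_s, conc_uM and in_linear_range; out-of-range values are
    flagged, never dropped.

    The magnitude is taken trace-wise, not point-wise: the shift direction is
    a property of the operating point (graphene's ambipolar conduction), so
    the dominant sign of the whole excursion is applied before inversion —
    folding each noisy sample individually would bias near-baseline values
    upward. ``conc_raw_uM`` carries the unclamped series for unbiased
    regression (zero-clamping folds noise at the start of a trace).
    """
    if cal.slope == 0:
        raise ValueError("calibration slope is zero")
    shift = trace.I_ds - trace.baseline
    sign = 1.0 if float(np.sum(shift)) >= 0 else -1.0
    raw = (sign * shift - cal.intercept) / cal.slope
    conc = np.maximum(raw, 0.0)
    low, high = cal.linear_range
    return pd.DataFrame(
        {
            "time_s": trace.times,
            "conc_uM": conc,
            "conc_raw_uM": raw,
            "in_linear_range": conc <= high,
        }
    )
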