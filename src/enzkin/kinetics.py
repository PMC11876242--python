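"""Forward kinetic models for heme-peroxidase reactions.

Two levels of description are provided:

* the four-species Michaelis–Menten (MM) mechanism
  ``E + S <-> C -> E + P`` with association rate ``k1``, dissociation rate
  ``k2`` and catalytic rate ``k_cat``, from which ``K_M = (k2 + k_cat)/k1``
  and ``V_max = k_cat * E_total``;
* the peroxidase catalytic network with compound I/II/III intermediates and
  irreversible bleaching (suicide inactivation by H2O2).

Concentrations are in μM and times in seconds throughout; unit conversions
belong at I/O boundaries, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "MMState",
    "PeroxidaseNetworkParameters",
    "PeroxidaseState",
    "Trajectory",
    "IntegrationError",
    "InsufficientDataError",
    "mm_rate",
    "simulate_mm",
    "simulate_peroxidase",
    "initial_rate",
    "initial_rate_series",
]

#: Solver tolerances: conservation checks downstream require tight values.
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; message carries the solver diagnostic."""


class InsufficientDataError(ValueError):
    """Not enough points in the requested window to estimate a rate."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the single-substrate MM mechanism.

    Parameters
    ----------
    k1 : float
        Enzyme–substrate association rate, 1/(μM·s).
    k2 : float
        Complex dissociation rate, 1/s.
    k_cat : float
        Catalytic (turnover) rate, 1/s.
    E_total : float
        Total enzyme concentration, μM.
    """

    k1: float
    k2: float
    k_cat: float
    E_total: float

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k2=self.k2, k_cat=self.k_cat, E_total=self.E_total)

    @property
    def K_M(self) -> float:
        """Michaelis constant (k2 + k_cat)/k1, μM. Always derived, never stored."""
        return (self.k2 + self.k_cat) / self.k1

    @property
    def V_max(self) -> float:
        """Maximal rate k_cat * E_total, μM/s."""
        return self.k_cat * self.E_total


@dataclass(frozen=True)
class MMState:
    """Concentrations (μM) of the four MM species: substrate, free enzyme,
    complex, product."""

    S: float
    E: float
    C: float
    P: float

    def __post_init__(self) -> None:
        _require_nonnegative(S=self.S, E=self.E, C=self.C, P=self.P)

    @property
    def E_total(self) -> float:
        return self.E + self.C

    @property
    def S_total(self) -> float:
        return self.S + self.C + self.P

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.E, self.C, self.P], dtype=float)

    species: tuple = field(default=("S", "E", "C", "P"), init=False, repr=False)


@dataclass(frozen=True)
class PeroxidaseNetworkParameters:
    """Mass-action rates for the peroxidase catalytic cycle.

    Pathways (one rate each):

    1. ``E + H2O2 -> CpdI`` (``k_p1``, 1/(μM·s)) — compound I formation.
    2. ``CpdI + AH2 -> CpdII + Prod`` (``k_p2``) — first reduction by the
       cosubstrate (ascorbic acid or reduced ABTS), releasing oxidized product.
    3. ``CpdII + AH2 -> E + Prod`` (``k_p3``) — return to resting state.
    5. ``CpdII + H2O2 -> CpdIII`` (``k_p5``) — off-pathway compound III.
    6. ``CpdIII -> E_inact`` (``k_p6``, 1/s) — bleaching, irreversible.
    4. ``CpdIII -> E`` (``k_p4``, 1/s, default 0) — optional slow recovery.

    ``k_p1b`` (``CpdI + H2O2 -> CpdII``, default 1e-4) is the catalase-like
    reduction of compound I by peroxide itself; it is the route by which
    compound III — and hence bleaching — arises with no reducing cosubstrate
    present at all, when excess cosubstrate cannot compete with H2O2 for the
    oxidized intermediates.

    With ``k_p6 = 0`` the sum of the catalytically competent species
    (E + CpdI + CpdII + CpdIII) is conserved.
    """

    k_p1: float
    k_p2: float
    k_p3: float
    k_p5: float
    k_p6: float
    k_p4: float = 0.0
    k_p1b: float = 1e-4

    def __post_init__(self) -> None:
        _require_positive(k_p1=self.k_p1)
        _require_nonnegative(
            k_p2=self.k_p2, k_p3=self.k_p3, k_p5=self.k_p5, k_p6=self.k_p6,
            k_p4=self.k_p4, k_p1b=self.k_p1b,
        )


@dataclass(frozen=True)
class PeroxidaseState:
    """Concentrations (μM) of the peroxidase-network species."""

    E: float
    CpdI: float
    CpdII: float
    CpdIII: float
    E_inact: float
    H2O2: float
    AH2: float
    Prod: float

    def __post_init__(self) -> None:
        _require_nonnegative(
            E=self.E,
            CpdI=self.CpdI,
            CpdII=self.CpdII,
            CpdIII=self.CpdIII,
            E_inact=self.E_inact,
            H2O2=self.H2O2,
            AH2=self.AH2,
            Prod=self.Prod,
        )

    @property
    def enzyme_total(self) -> float:
        return self.E + self.CpdI + self.CpdII + self.CpdIII + self.E_inact

    @property
    def active_fraction(self) -> float:
        """Fraction of enzyme that is still catalytically competent."""
        tot = self.enzyme_total
        return 1.0 if tot == 0 else (tot - self.E_inact) / tot

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.E, self.CpdI, self.CpdII, self.CpdIII, self.E_inact, self.H2O2, self.AH2, self.Prod],
            dtype=float,
        )

    species: tuple = field(
        default=("E", "CpdI", "CpdII", "CpdIII", "E_inact", "H2O2", "AH2", "Prod"),
        init=False,
        repr=False,
    )


@dataclass(frozen=True)
class Trajectory:
    """Time series of species concentrations.

    ``states`` is a DataFrame indexed like ``times`` with one column per
    species (μM). Negative solver round-off is clamped to zero on construction
    (output only; the ODE right-hand sides never clamp).
    """

    times: np.ndarray
    states: pd.DataFrame

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or len(times) != len(self.states):
            raise ValueError("times and states must align")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", self.states.clip(lower=0.0))

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[species].to_numpy()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame with columns time_s, species, value_uM."""
        wide = self.states.copy()
        wide.insert(0, "time_s", self.times)
        return wide.melt(id_vars="time_s", var_name="species", value_name="value_uM")

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "Trajectory":
        wide = tidy.pivot(index="time_s", columns="species", values="value_uM").sort_index()
        return cls(times=wide.index.to_numpy(dtype=float), states=wide.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_tidy(pd.read_csv(path))


def mm_rate(S, V_max: float, K_M: float):
    """Closed-form Michaelis–Menten rate ``V_max * S / (K_M + S)`` in μM/s.

    ``S`` may be a scalar or array of substrate concentrations (μM). The rate
    is monotone non-decreasing in ``S`` and bounded above by ``V_max``.
    """
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)) or np.any(S < 0):
        raise ValueError("substrate concentrations must be finite and non-negative")
    _require_positive(V_max=V_max, K_M=K_M)
    rate = V_max * S / (K_M + S)
    return float(rate) if rate.ndim == 0 else rate


def _integrate(rhs, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-D grid with >= 2 points")
    if times[0] != 0:
        raise ValueError("time grid must start at 0")
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def simulate_mm(params: KineticParameters, init: MMState, times: Sequence[float]) -> Trajectory:
    """Integrate the full (no quasi-steady-state assumption) MM ODE system.

    dS/dt = -k1*E*S + k2*C
    dE/dt = -k1*E*S + (k2 + k_cat)*C
    dC/dt =  k1*E*S - (k2 + k_cat)*C
    dP/dt =  k_cat*C

    Enzyme (E + C) and substrate (S + C + P) totals are conserved exactly by
    the vector field; the solver preserves them to within its tolerance.
    """
    k1, k2, kcat = params.k1, params.k2, params.k_cat

    def rhs(_t, y):
        S, E, C, _P = y
        bind = k1 * E * S
        unbind = k2 * C
        cat = kcat * C
        return (-bind + unbind, -bind + unbind + cat, bind - unbind - cat, cat)

    ys = _integrate(rhs, init.as_array(), times)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=pd.DataFrame(ys, columns=list(init.species)),
    )


def simulate_peroxidase(
    params: PeroxidaseNetworkParameters, init: PeroxidaseState, times: Sequence[float]
) -> Trajectory:
    """Integrate the peroxidase-network mass-action ODEs.

    One term per pathway; pathways 2 and 3 each consume one AH2 and produce
    one product molecule. E_inact and Prod are non-decreasing.
    """
    p = params

    def rhs(_t, y):
        E, c1, c2, c3, _ei, h, a, _pr = y
        r1 = p.k_p1 * E * h
        r1b = p.k_p1b * c1 * h
        r2 = p.k_p2 * c1 * a
        r3 = p.k_p3 * c2 * a
        r5 = p.k_p5 * c2 * h
        r6 = p.k_p6 * c3
        r4 = p.k_p4 * c3
        return (
            -r1 + r3 + r4,          # E
            r1 - r2 - r1b,          # CpdI
            r2 + r1b - r3 - r5,     # CpdII
            r5 - r6 - r4,           # CpdIII
            r6,                     # E_inact
            -r1 - r5 - r1b,         # H2O2
            -r2 - r3,               # AH2
            r2 + r3,                # Prod
        )

    ys = _integrate(rhs, init.as_array(), times)
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=pd.DataFrame(ys, columns=list(init.species)),
    )


def initial_rate_series(
    times: np.ndarray, P: np.ndarray, S0: float, fraction: float = 0.05
) -> float:
    """Initial rate v0 (μM/s) from a (time, product) series.

    Least-squares slope of product vs time over the earliest contiguous
    points where accumulated product stays below ``fraction`` of the initial
    substrate ``S0``, so substrate depletion does not bias the slope. The
    window is located on a lightly smoothed copy of the series (so a single
    noisy sample cannot truncate it) but the slope is fit to the raw points.
    """
    if not 0 < fraction <= 0.2:
        raise ValueError("fraction must be in (0, 0.2]")
    times = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    if len(times) < 5:
        raise InsufficientDataError("series needs >= 5 points")
    kernel = np.ones(5) / 5
    smooth = np.convolve(np.pad(P, 2, mode="edge"), kernel, mode="valid")
    window = smooth - smooth[0] < fraction * S0
    # keep the earliest contiguous run only
    stop = int(np.argmin(window)) if not window.all() else len(window)
    if stop < 3:
        raise InsufficientDataError(f"only {stop} points inside the initial-rate window")
    slope = np.polyfit(times[:stop], P[:stop], 1)[0]
    return float(slope)


def initial_rate(traj: Trajectory, fraction: float = 0.05, product: str = "P") -> float:
    """Initial product-formation rate v0 (μM/s) from a simulated progress curve."""
    P = traj[product]
    if product == "P":
        S0 = traj["S"][0] + traj["C"][0] + P[0]
    else:
        S0 = traj["AH2"][0] + P[0]
    return initial_rate_series(traj.times, P, S0, fraction)
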