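"""Synthetic study generator.

Emulates a constant-voltage GFET enzymatic study: a grid of experimental
conditions (enzyme ∈ {HRP, heme}, pH ∈ {4, 7}, temperature 18–25 °C,
substrate 25–1000 μM of ABTS or H2O2, ~100 cases), a smooth ground-truth law
giving each condition its (K_M, k_cat), Michaelis–Menten simulation of the
product progress curve with cosubstrate in excess, and noisy current traces
through the calibration model. Everything is a pure function of the inputs
and a master seed, so the whole study regenerates bit-identically.

The ground-truth law is a modelling device, not a measured relation: the
temperature dependence is Arrhenius-like (exponential in T − T_ref) and the
pH dependence of k_cat is a Gaussian bump centred on the enzyme's optimal pH
(7 for HRP, 4 for heme).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gfet_signal import CalibrationModel, CurrentTrace, concentration_to_current
from .kinetics import (
    KineticParameters,
    MMState,
    PeroxidaseNetworkParameters,
    PeroxidaseState,
    Trajectory,
    simulate_mm,
    simulate_peroxidase,
)

__all__ = [
    "ExperimentCondition",
    "GroundTruthLaw",
    "ExperimentSet",
    "GridSpec",
    "DEFAULT_LAWS",
    "DEFAULT_CALIBRATION",
    "ground_truth",
    "generate_experiment_set",
    "generate_inactivation_scenarios",
    "condition_seed",
]

ENZYMES = ("HRP", "heme")
SUBSTRATES = ("ABTS", "H2O2")

#: Concentration series used for each assay, μM.
CONC_SERIES_UM = (25.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0)

#: Cosubstrate excess (μM) under which single-substrate MM kinetics applies
#: (2.5 mM H2O2 when ABTS is the varied substrate).
COSUBSTRATE_EXCESS_UM = 2500.0


@dataclass(frozen=True)
class ExperimentCondition:
    """One measured case: enzyme, environment, substrate level, voltages."""

    enzyme: str
    pH: float
    temperature_C: float
    substrate: str
    substrate_conc_uM: float
    cosubstrate_conc_uM: float = COSUBSTRATE_EXCESS_UM
    V_g_mV: float = 500.0
    V_ds_mV: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"enzyme must be one of {ENZYMES}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"substrate must be one of {SUBSTRATES}")
        if self.substrate_conc_uM <= 0:
            raise ValueError("substrate_conc_uM must be positive")

    @property
    def condition_id(self) -> str:
        return (
            f"{self.enzyme}_pH{self.pH:g}_T{self.temperature_C:g}"
            f"_{self.substrate}{self.substrate_conc_uM:g}"
        )

    @property
    def series_id(self) -> str:
        """Assay-series key: conditions differing only in concentration share it."""
        return f"{self.enzyme}_pH{self.pH:g}_T{self.temperature_C:g}_{self.substrate}"


@dataclass(frozen=True)
class GroundTruthLaw:
    """Smooth (K_M, k_cat) law over the condition grid for one enzyme.

    k_cat = kcat_ref · exp(Ea_like·(T − T_ref)) · exp(−((pH − pH_opt)/pH_width)²)
    K_M   = K_M_ref · exp(K_M_pH_slope·(pH − pH_opt))
    """

    kcat_ref: float
    Ea_like: float
    pH_opt: float
    pH_width: float
    K_M_ref: float
    K_M_pH_slope: float
    T_ref: float = 22.0

    def __post_init__(self) -> None:
        if self.kcat_ref <= 0 or self.K_M_ref <= 0 or self.pH_width <= 0:
            raise ValueError("kcat_ref, K_M_ref and pH_width must be positive")


#: Synthetic ground truth, literature-plausible magnitudes (not measured values).
DEFAULT_LAWS: Dict[str, GroundTruthLaw] = {
    "HRP": GroundTruthLaw(
        kcat_ref=50.0, Ea_like=0.08, pH_opt=7.0, pH_width=2.5, K_M_ref=150.0, K_M_pH_slope=0.25
    ),
    "heme": GroundTruthLaw(
        kcat_ref=5.0, Ea_like=0.06, pH_opt=4.0, pH_width=2.0, K_M_ref=400.0, K_M_pH_slope=-0.2
    ),
}

#: Default transducer response: 2 μA/μM through the origin, linear to 70 μM.
DEFAULT_CALIBRATION = CalibrationModel(
    slope=2.0, intercept=0.0, linear_range=(10.0, 70.0), r2=1.0, residual_sd=0.0
)


def ground_truth(law: GroundTruthLaw, cond: ExperimentCondition) -> Tuple[float, float]:
    """Deterministic (K_M μM, k_cat 1/s) for a condition under the law."""
    dT = cond.temperature_C - law.T_ref
    dpH = cond.pH - law.pH_opt
    k_cat = law.kcat_ref * np.exp(law.Ea_like * dT) * np.exp(-((dpH / law.pH_width) ** 2))
    K_M = law.K_M_ref * np.exp(law.K_M_pH_slope * dpH)
    return float(K_M), float(k_cat)


@dataclass(frozen=True)
class GridSpec:
    """Enumerates the condition grid.

    The default mirrors the study design: for each enzyme and each pH in
    {4, 7}, an ABTS concentration series at each temperature; plus, per
    enzyme, one H2O2-varied series at its optimal pH and the reference
    temperature. With three temperatures and the 7-point series this yields
    98 conditions.
    """

    enzymes: tuple = ENZYMES
    pH_values: tuple = (4.0, 7.0)
    temperatures_C: tuple = (18.0, 22.0, 25.0)
    conc_series_uM: tuple = CONC_SERIES_UM
    include_h2o2_series: bool = True
    V_g_mV: float = 500.0
    V_ds_mV: float = 500.0

    def conditions(self) -> List[ExperimentCondition]:
        conds: List[ExperimentCondition] = []
        for enzyme in self.enzymes:
            for pH in self.pH_values:
                for T in self.temperatures_C:
                    for conc in self.conc_series_uM:
                        conds.append(
                            ExperimentCondition(
                                enzyme=enzyme,
                                pH=pH,
                                temperature_C=T,
                                substrate="ABTS",
                                substrate_conc_uM=conc,
                                V_g_mV=self.V_g_mV,
                                V_ds_mV=self.V_ds_mV,
                            )
                        )
            if self.include_h2o2_series:
                pH_opt = DEFAULT_LAWS[enzyme].pH_opt if enzyme in DEFAULT_LAWS else self.pH_values[0]
                for conc in self.conc_series_uM:
                    conds.append(
                        ExperimentCondition(
                            enzyme=enzyme,
                            pH=pH_opt,
                            temperature_C=22.0,
                            substrate="H2O2",
                            substrate_conc_uM=conc,
                            V_g_mV=self.V_g_mV,
                            V_ds_mV=self.V_ds_mV,
                        )
                    )
        return conds


@dataclass(frozen=True)
class ExperimentSet:
    """The generated study: conditions, one trace each, and ground truth."""

    conditions: List[ExperimentCondition]
    traces: List[CurrentTrace]
    truth: pd.DataFrame  # columns condition_id, K_M_uM, kcat_per_s
    master_seed: int

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.traces):
            raise ValueError("one trace per condition required")
        if len(self.truth) != len(self.conditions):
            raise ValueError("truth row required for every condition")

    def conditions_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            rows.append(
                {
                    "condition_id": c.condition_id,
                    "series_id": c.series_id,
                    "enzyme": c.enzyme,
                    "pH": c.pH,
                    "temperature_C": c.temperature_C,
                    "substrate": c.substrate,
                    "substrate_conc_uM": c.substrate_conc_uM,
                    "cosubstrate_conc_uM": c.cosubstrate_conc_uM,
                    "V_g_mV": c.V_g_mV,
                    "V_ds_mV": c.V_ds_mV,
                    "seed": c.seed,
                }
            )
        return pd.DataFrame(rows)

    def traces_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.traces], ignore_index=True)


def condition_seed(master_seed: int, index: int) -> int:
    """Counter-based per-condition seed: order-independent and reproducible."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _simulate_condition_product(
    K_M: float, k_cat: float, cond: ExperimentCondition, times: np.ndarray,
    E_total_uM: float, k1: float,
) -> Trajectory:
    # back out k2 from the target K_M at fixed k1; keep k2 positive
    k2 = K_M * k1 - k_cat
    if k2 <= 0:
        raise ValueError(
            f"K_M={K_M} too small for k1={k1}, k_cat={k_cat}: increase k1"
        )
    params = KineticParameters(k1=k1, k2=k2, k_cat=k_cat, E_total=E_total_uM)
    init = MMState(S=cond.substrate_conc_uM, E=E_total_uM, C=0.0, P=0.0)
    return simulate_mm(params, init, times)


def generate_experiment_set(
    law: Dict[str, GroundTruthLaw] | GroundTruthLaw,
    grid_spec: Optional[GridSpec] = None,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    noise_rel: float = 0.05,
    master_seed: int = 0,
    *,
    duration_s: float = 60.0,
    n_points: int = 121,
    E_total_uM: float = 0.02,
    k1: float = 10.0,
) -> ExperimentSet:
    """Generate the full synthetic study.

    For each condition on the grid: evaluate the ground-truth law, simulate
    the MM progress curve with cosubstrate in excess, and synthesize the
    noisy current trace via the calibration model. ``noise_rel`` is the
    current-noise standard deviation as a fraction of the trace's full-scale
    response |ΔI| (amperometric noise scales with the signal), so assays
    spanning decades of activity carry comparable relative noise. E_total is
    small relative to substrate (quasi-steady-state regime) and k1 fast
    enough that initial rates match the closed-form MM rate.
    """
    grid_spec = grid_spec or GridSpec()
    laws = law if isinstance(law, dict) else {e: law for e in grid_spec.enzymes}
    times = np.linspace(0.0, duration_s, n_points)
    conditions: List[ExperimentCondition] = []
    traces: List[CurrentTrace] = []
    truth_rows = []
    for idx, cond in enumerate(grid_spec.conditions()):
        seed = condition_seed(master_seed, idx)
        cond = ExperimentCondition(
            enzyme=cond.enzyme,
            pH=cond.pH,
            temperature_C=cond.temperature_C,
            substrate=cond.substrate,
            substrate_conc_uM=cond.substrate_conc_uM,
            cosubstrate_conc_uM=cond.cosubstrate_conc_uM,
            V_g_mV=cond.V_g_mV,
            V_ds_mV=cond.V_ds_mV,
            seed=seed,
        )
        K_M, k_cat = ground_truth(laws[cond.enzyme], cond)
        traj = _simulate_condition_product(K_M, k_cat, cond, times, E_total_uM, k1)
        full_scale = abs(cal.slope) * float(np.max(traj["P"]))
        trace = concentration_to_current(
            traj["P"],
            cal,
            noise_sd=noise_rel * full_scale,
            seed=seed,
            times=times,
            V_g_mV=cond.V_g_mV,
            V_ds_mV=cond.V_ds_mV,
            condition_id=cond.condition_id,
        )
        conditions.append(cond)
        traces.append(trace)
        truth_rows.append(
            {"condition_id": cond.condition_id, "K_M_uM": K_M, "kcat_per_s": k_cat}
        )
    return ExperimentSet(
        conditions=conditions,
        traces=traces,
        truth=pd.DataFrame(truth_rows),
        master_seed=master_seed,
    )


#: Bleaching-prone defaults for the inactivation scenarios (synthetic, not
#: measured): fast compound-I formation, efficient reduction by the
#: cosubstrate, and a compound-III shunt slow enough that the cosubstrate
#: wins the competition for compound II while it lasts — the mechanism by
#: which excess reducing substrate mitigates suicide inactivation.
DEFAULT_PEROXIDASE_PARAMS = PeroxidaseNetworkParameters(
    k_p1=0.01, k_p2=0.05, k_p3=0.02, k_p5=5e-4, k_p6=0.05
)


def generate_inactivation_scenarios(
    params: PeroxidaseNetworkParameters = DEFAULT_PEROXIDASE_PARAMS,
    aa_levels: Sequence[float] = (0.0, 75.0, 500.0),
    h2o2: float = 50.0,
    E_total_uM: float = 1.0,
    duration_s: float = 600.0,
    n_points: int = 241,
) -> pd.DataFrame:
    """Suicide-inactivation scenarios at varying cosubstrate (AA) levels.

    Defaults mirror the study design: 50 μM H2O2 with 0, 75 ("insufficient")
    or 500 μM ("sufficient") ascorbic acid. Returns one row per AA level with
    the final active-enzyme fraction and the full trajectory attached.
    """
    if any(a < 0 for a in aa_levels):
        raise ValueError("aa_levels must be non-negative")
    times = np.linspace(0.0, duration_s, n_points)
    rows = []
    for aa in aa_levels:
        init = PeroxidaseState(
            E=E_total_uM, CpdI=0.0, CpdII=0.0, CpdIII=0.0, E_inact=0.0,
            H2O2=h2o2, AH2=aa, Prod=0.0,
        )
        traj = simulate_peroxidase(params, init, times)
        E_tot = E_total_uM
        active = (
            traj["E"] + traj["CpdI"] + traj["CpdII"] + traj["CpdIII"]
        ) / E_tot
        rows.append(
            {
                "AH2_uM": float(aa),
                "H2O2_uM": float(h2o2),
                "final_active_fraction": float(active[-1]),
                "final_product_uM": float(traj["Prod"][-1]),
                "trajectory": traj,
            }
        )
    return pd.DataFrame(rows)
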