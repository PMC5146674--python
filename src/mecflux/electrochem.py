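"""Performance metrics of a fed-batch MEC cycle.

All quantities follow the usual bioelectrochemical conventions: charge is the
trapezoidal integral of the recorded current, coulombic efficiency compares
that charge with the theoretical electrons from complete donor oxidation
(γ·F per mole donor), current density and H₂ rate are normalised to the
anode liquid volume, and gas amounts convert through the ideal-gas law at
the stated measurement conditions.

Units: time in seconds inside traces, current in amperes, volumes in m³,
concentrations in mM (≡ mol/m³), durations in days where rates are daily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stoichiometry import FARADAY

__all__ = [
    "CurrentTrace",
    "GasSample",
    "BatchCycleRecord",
    "PerformanceMetrics",
    "integrate_charge",
    "peak_current",
    "coulombic_efficiency",
    "volumetric_current_density",
    "h2_production_rate",
    "h2_yield",
    "h2_yield_ceiling",
    "substrate_removal",
    "linear_removal_rate",
    "gas_moles",
    "gas_volume",
]

#: Ideal gas constant in L·atm/(mol·K); gas volumes arrive in mL at ~1 atm.
R_L_ATM = 0.0820573661

#: Default gas measurement conditions: 30 °C room, ambient pressure.
DEFAULT_TEMPERATURE_K = 303.15
DEFAULT_PRESSURE_ATM = 1.0


@dataclass(frozen=True)
class CurrentTrace:
    """An ordered current-vs-time telemetry trace.

    ``times_s`` strictly increasing, ``currents_A`` same length.  Slightly
    negative samples are tolerated (sensor noise) but a trace whose mean
    current is negative is rejected as miswired.
    """

    times_s: np.ndarray
    currents_A: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        i = np.asarray(self.currents_A, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "currents_A", i)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("times and currents must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a current trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if i.mean() < 0:
            raise ValueError("mean current is negative; check electrode polarity")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class GasSample:
    """One headspace phase: total volume with mole fractions of H₂/CH₄/CO₂."""

    phase: str  # "anode" | "cathode"
    volume_mL: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    pressure_atm: float = DEFAULT_PRESSURE_ATM
    x_h2: float = 0.0
    x_ch4: float = 0.0
    x_co2: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in ("anode", "cathode"):
            raise ValueError(f"unknown gas phase {self.phase!r}")
        if self.volume_mL < 0:
            raise ValueError("gas volume must be non-negative")
        for x in (self.x_h2, self.x_ch4, self.x_co2):
            if not 0.0 <= x <= 1.0:
                raise ValueError("mole fractions must lie in [0, 1]")
        if self.x_h2 + self.x_ch4 + self.x_co2 > 1.0 + 1e-9:
            raise ValueError("mole fractions sum above 1")

    def moles(self, species: str) -> float:
        """Moles of ``"h2" | "ch4" | "co2"`` in this phase (ideal gas)."""
        x = {"h2": self.x_h2, "ch4": self.x_ch4, "co2": self.x_co2}[species]
        return x * gas_moles(self.volume_mL, self.temperature_K, self.pressure_atm)


@dataclass
class BatchCycleRecord:
    """Everything measured over one fed-batch cycle.

    ``initial_mM`` / ``final_mM`` map compound name → concentration;
    ``charge_C`` may be given directly or left None with a trace to
    integrate.  ``set_potential_V`` is vs SHE.
    """

    anode_volume_m3: float
    cycle_days: float
    set_potential_V: float
    initial_mM: dict[str, float]
    final_mM: dict[str, float]
    gas: list[GasSample] = field(default_factory=list)
    trace: CurrentTrace | None = None
    charge_C: float | None = None
    donor: str = "propionate"

    def __post_init__(self) -> None:
        if self.anode_volume_m3 <= 0:
            raise ValueError("anode volume must be positive")
        if self.cycle_days <= 0:
            raise ValueError("cycle duration must be positive")
        d = self.donor
        if d in self.initial_mM and d in self.final_mM:
            if self.final_mM[d] > self.initial_mM[d] + 1e-9:
                warnings.warn(
                    f"final {d} exceeds initial; negative removal will be reported",
                    stacklevel=2,
                )

    def resolve_charge(self) -> float:
        """Charge in coulombs: the explicit value, else the integrated trace."""
        if self.charge_C is not None:
            return float(self.charge_C)
        if self.trace is None:
            raise ValueError("record carries neither charge nor a current trace")
        return integrate_charge(self.trace)

    def donor_consumed_mol(self) -> float:
        """Moles of donor consumed (mM ≡ mol/m³ times anode volume)."""
        delta = self.initial_mM[self.donor] - self.final_mM[self.donor]
        return delta * self.anode_volume_m3

    def gas_species_mol(self, species: str, phases=("anode", "cathode")) -> float:
        return sum(g.moles(species) for g in self.gas if g.phase in phases)


@dataclass(frozen=True)
class PerformanceMetrics:
    """The headline per-cycle numbers, named with their units."""

    I_V_A_per_m3: float
    CE_percent: float
    Q_H2_m3_per_m3_day: float
    Y_H2_mol_per_mol: float
    removal_percent: float
    removal_rate_mM_per_day: float


def integrate_charge(trace: CurrentTrace) -> float:
    """Trapezoidal charge (C) over a telemetry trace.

    Exact for piecewise-linear current, which is what sampled telemetry is.
    """
    return float(np.trapezoid(trace.currents_A, trace.times_s))


def peak_current(trace: CurrentTrace, window: int = 3) -> float:
    """Maximum of the moving-median-smoothed trace (A).

    Raw 10-minute samples can spike; a short moving median (default window 3)
    suppresses single-sample outliers before taking the cycle maximum.
    """
    i = trace.currents_A
    if window <= 1 or i.size < window:
        return float(i.max())
    half = window // 2
    padded = np.pad(i, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    return float(np.median(windows, axis=1).max())


def coulombic_efficiency(charge_C: float, donor_consumed_mol: float, gamma: int) -> float:
    """CE (%): electrons recovered as charge over theoretical donor electrons.

    CE = 100 · charge / (F · γ · n_donor).  Values above 100 % are possible
    with measurement error and are flagged with a warning, not rejected.
    """
    if donor_consumed_mol <= 0:
        raise ValueError("donor consumed must be positive")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    ce = 100.0 * charge_C / (FARADAY * gamma * donor_consumed_mol)
    if ce > 100.0:
        warnings.warn(f"coulombic efficiency {ce:.1f}% exceeds 100%", stacklevel=2)
    return ce


def volumetric_current_density(peak_current_A: float, anode_volume_m3: float) -> float:
    """I_V (A/m³): peak current normalised to the anode liquid volume."""
    if anode_volume_m3 <= 0:
        raise ValueError("anode volume must be positive")
    return peak_current_A / anode_volume_m3


def h2_production_rate(
    v_h2_m3: float, duration_days: float, anode_volume_m3: float
) -> float:
    """Q (m³ H₂ / m³ reactor / day) from cathode-collected H₂ volume."""
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    if anode_volume_m3 <= 0:
        raise ValueError("anode volume must be positive")
    return v_h2_m3 / (anode_volume_m3 * duration_days)


def h2_yield(h2_mol: float, donor_consumed_mol: float) -> float:
    """Y_H2 (mol H₂ per mol donor consumed)."""
    if donor_consumed_mol <= 0:
        raise ValueError("donor consumed must be positive")
    return h2_mol / donor_consumed_mol


def h2_yield_ceiling(gamma_donor: int, gamma_h2: int = 2) -> float:
    """Stoichiometric maximum yield γ_donor/γ_H₂ (7.0 for propionate)."""
    return gamma_donor / gamma_h2


def substrate_removal(
    initial_mM: float, final_mM: float, duration_days: float
) -> tuple[float, float]:
    """(% removed, removal rate in mM/day).

    ``final > initial`` yields a warning and a negative removal — useful for
    flagging refill or dilution artefacts without halting a batch report.
    """
    if initial_mM <= 0:
        raise ValueError("initial concentration must be positive")
    if final_mM < 0:
        raise ValueError("final concentration must be non-negative")
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    if final_mM > initial_mM:
        warnings.warn("final concentration exceeds initial", stacklevel=2)
    removed = initial_mM - final_mM
    return 100.0 * removed / initial_mM, removed / duration_days


def linear_removal_rate(
    times_h: np.ndarray, conc_mM: np.ndarray, tail_mM: float = 2.0
) -> float:
    """Zero-order removal rate (mM/day) from the near-linear phase.

    Fed-batch donor consumption is near-linear until the substrate runs
    low; fitting only points above ``tail_mM`` recovers the zero-order
    rate without bias from the depletion tail.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_mM, dtype=float)
    mask = c > tail_mM
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points above the tail threshold")
    slope_per_h = np.polyfit(t[mask], c[mask], 1)[0]
    return float(-slope_per_h * 24.0)


def gas_moles(volume_mL: float, temperature_K: float, pressure_atm: float) -> float:
    """Ideal-gas moles from volume at the stated measurement conditions."""
    if volume_mL < 0:
        raise ValueError("volume must be non-negative")
    if temperature_K <= 0 or pressure_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    return pressure_atm * (volume_mL / 1000.0) / (R_L_ATM * temperature_K)


def gas_volume(mol: float, temperature_K: float, pressure_atm: float) -> float:
    """Inverse of :func:`gas_moles`: volume in mL of *mol* ideal gas."""
    if temperature_K <= 0 or pressure_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    return mol * R_L_ATM * temperature_K / pressure_atm * 1000.0


def cycle_metrics(record: BatchCycleRecord, gamma_donor: int) -> PerformanceMetrics:
    """Assemble all headline metrics for one batch cycle."""
    charge = record.resolve_charge()
    consumed = record.donor_consumed_mol()
    if record.trace is not None:
        ipk = peak_current(record.trace)
    else:
        # without a trace the mean current stands in for the peak
        ipk = charge / (record.cycle_days * 86400.0)
    h2_mol = record.gas_species_mol("h2", phases=("cathode",))
    v_h2_m3 = gas_volume(h2_mol, DEFAULT_TEMPERATURE_K, DEFAULT_PRESSURE_ATM) * 1e-6
    removal, rate = substrate_removal(
        record.initial_mM[record.donor],
        record.final_mM[record.donor],
        record.cycle_days,
    )
    return PerformanceMetrics(
        I_V_A_per_m3=volumetric_current_density(ipk, record.anode_volume_m3),
        CE_percent=coulombic_efficiency(charge, consumed, gamma_donor),
        Q_H2_m3_per_m3_day=h2_production_rate(
            v_h2_m3, record.cycle_days, record.anode_volume_m3
        ),
        Y_H2_mol_per_mol=h2_yield(h2_mol, consumed),
        removal_percent=removal,
        removal_rate_mM_per_day=rate,
    )
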