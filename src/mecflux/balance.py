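"""The electron ledger: distributing donor electrons over measured sinks.

Every sink is expressed in milli electron equivalents (m e⁻eq) — millimoles
of electrons — and as a percentage of the electrons released by the donor
consumed over the cycle.  Whatever is not captured by a measured sink
(biomass, soluble microbial products, unmeasured losses) lands in the
closure term "undefined", so the ledger always sums to 100 % exactly:

    e⁻(undefined) = e⁻(donor) − e⁻(current) − e⁻(residual donor)
                    − e⁻(acetate) − e⁻(formate) − e⁻(H₂) − e⁻(CH₄)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrochem import BatchCycleRecord
from .stoichiometry import FARADAY, REGISTRY, Compound

__all__ = [
    "SinkBalance",
    "TimeCourseFractions",
    "sink_equivalents",
    "charge_equivalents",
    "electron_balance",
    "undefined_from_percentages",
    "time_course_fractions",
    "pathway_fraction",
]

#: Ledger row order (Table-1 layout); "undefined" is always last.
SINK_ORDER = (
    "current",
    "methane",
    "hydrogen",
    "propionate",
    "acetate",
    "formate",
    "undefined",
)


def sink_equivalents(amount_mol: float, compound: Compound | str) -> float:
    """Electron equivalents (mol e⁻) held in *amount_mol* of a compound."""
    if amount_mol < 0:
        raise ValueError("amount must be non-negative")
    if isinstance(compound, str):
        try:
            compound = REGISTRY[compound]
        except KeyError:
            raise KeyError(f"unknown compound {compound!r}") from None
    return amount_mol * compound.gamma


def charge_equivalents(charge_C: float) -> float:
    """Electron equivalents (mol e⁻) carried by a charge in coulombs."""
    return charge_C / FARADAY


@dataclass(frozen=True)
class SinkBalance:
    """Per-sink electron equivalents and percentages, closed to 100 %.

    ``milli_eq`` and ``percent`` map sink name → value; ``donor_meq`` is the
    total donor m e⁻eq consumed.  ``over_closed`` flags a negative undefined
    term (measured sinks exceeding the donor electrons).
    """

    donor_meq: float
    milli_eq: dict[str, float] = field(hash=False)
    percent: dict[str, float] = field(hash=False)
    over_closed: bool = False

    def __post_init__(self) -> None:
        total = sum(self.milli_eq.values())
        if not np.isclose(total, self.donor_meq, rtol=1e-9, atol=1e-12):
            raise AssertionError(
                f"ledger does not close: sinks {total} vs donor {self.donor_meq}"
            )

    def as_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Table-1-style frame: rows are sinks, m e⁻eq and % columns."""
        rows = [s for s in SINK_ORDER if s in self.milli_eq]
        return pd.DataFrame(
            {
                "milli_e_eq": [round(self.milli_eq[s], 4) for s in rows],
                "percent": [round(self.percent[s], decimals) for s in rows],
            },
            index=pd.Index(rows, name="sink"),
        )


def electron_balance(
    record: BatchCycleRecord,
    charge_C: float | None = None,
    basis: str = "fed",
    methane_phases: tuple[str, ...] = ("anode", "cathode"),
    hydrogen_phases: tuple[str, ...] = ("anode",),
) -> SinkBalance:
    """Build the end-of-cycle electron ledger for one batch record.

    With ``basis="fed"`` (the Table-1 convention) the 100 % reference is
    the electrons in all donor fed at the start of the cycle, and unused
    donor appears as its own sink.  With ``basis="consumed"`` the reference
    is the electrons actually released (fed minus residual) and the
    residual-donor sink is identically zero; the two agree whenever the
    donor is fully consumed.

    Methane is counted from anode and cathode headspaces combined by
    default; the hydrogen *sink* counts anode-side residual H₂ only, since
    cathodic H₂ is the electrolysis product of the current already booked.
    Dissolved residues of the donor and its intermediates are taken from
    the final concentrations.  ``charge_C`` overrides the record's own
    charge/trace when given.
    """
    if basis not in ("fed", "consumed"):
        raise ValueError(f"unknown basis {basis!r}")
    consumed = record.donor_consumed_mol()
    if consumed <= 0:
        raise ValueError("donor consumed must be positive for a ledger")
    donor_gamma = REGISTRY[record.donor].gamma
    if basis == "fed":
        donor_mol = record.initial_mM[record.donor] * record.anode_volume_m3
    else:
        donor_mol = consumed
    donor_meq = 1000.0 * donor_mol * donor_gamma

    charge = charge_C if charge_C is not None else record.resolve_charge()

    meq: dict[str, float] = {}
    meq["current"] = 1000.0 * charge_equivalents(charge)
    meq["methane"] = 1000.0 * sink_equivalents(
        record.gas_species_mol("ch4", phases=methane_phases), "methane"
    )
    meq["hydrogen"] = 1000.0 * sink_equivalents(
        record.gas_species_mol("h2", phases=hydrogen_phases), "hydrogen"
    )
    # dissolved residues: residual donor (fed basis only) and intermediates
    for name in ("propionate", "acetate", "formate"):
        if name == record.donor:
            residual = record.final_mM.get(name, 0.0) if basis == "fed" else 0.0
        else:
            residual = record.final_mM.get(name, 0.0) - record.initial_mM.get(name, 0.0)
            residual = max(residual, 0.0)
        meq[name] = 1000.0 * sink_equivalents(
            residual * record.anode_volume_m3, name
        )

    undefined = donor_meq - sum(meq.values())
    meq["undefined"] = undefined

    percent = {k: 100.0 * v / donor_meq for k, v in meq.items()}
    # tolerance keeps float cancellation from flagging a perfect closure
    over_closed = undefined < -1e-9 * donor_meq
    if over_closed:
        warnings.warn(
            "measured sinks exceed donor electrons (undefined < 0)", stacklevel=2
        )
    if any(v > 100.0 + 1e-9 for k, v in percent.items() if k != "undefined"):
        warnings.warn("a measured sink exceeds 100% of donor electrons", stacklevel=2)
    return SinkBalance(
        donor_meq=donor_meq, milli_eq=meq, percent=percent, over_closed=over_closed
    )


def undefined_from_percentages(measured_percent: dict[str, float]) -> float:
    """Closure of a ledger stated directly in percent: 100 − Σ measured."""
    return 100.0 - sum(measured_percent.values())


@dataclass(frozen=True)
class TimeCourseFractions:
    """Percent-of-donor-electron series for soluble intermediates."""

    times_h: np.ndarray
    percent: pd.DataFrame  # columns = intermediates, index = times_h


def time_course_fractions(
    hplc: pd.DataFrame,
    donor_initial_mM: float,
    donor: str = "propionate",
) -> TimeCourseFractions:
    """Electron fraction held by each intermediate over a batch cycle.

    percent_i(t) = 100 · γ_i · C_i(t) / (γ_donor · C_donor,0), with the
    initial donor electrons as the fixed 100 % reference.  ``hplc`` needs a
    ``time_h`` column plus one ``<compound>_mM`` column per species.
    """
    if donor_initial_mM <= 0:
        raise ValueError("initial donor concentration must be positive")
    if "time_h" not in hplc.columns:
        raise ValueError("HPLC frame needs a 'time_h' column")
    basis = REGISTRY[donor].gamma * donor_initial_mM
    out: dict[str, np.ndarray] = {}
    for col in hplc.columns:
        if not col.endswith("_mM"):
            continue
        name = col[:-3]
        if name == donor:
            continue
        out[name] = 100.0 * REGISTRY[name].gamma * hplc[col].to_numpy() / basis
    times = hplc["time_h"].to_numpy(dtype=float)
    return TimeCourseFractions(
        times_h=times, percent=pd.DataFrame(out, index=pd.Index(times, name="time_h"))
    )


def pathway_fraction(
    pathway: list[tuple[str, float]],
    donor: str = "propionate",
    atol: float = 1e-9,
) -> tuple[dict[str, float], bool]:
    """Electron share of each intermediate in a degradation pathway.

    ``pathway`` lists (intermediate, mol per mol donor).  Each fraction is
    100·ν_i·γ_i/γ_donor.  Returns (fractions, complete) where ``complete``
    says the fractions account for all donor electrons; fractions summing
    above 100 indicate an over-stoichiometric pathway and raise.

    Example: propionate → 1 acetate + 3 H₂ gives acetate 8/14 = 57.1 % and
    H₂ 6/14 = 42.9 %, summing to 100.
    """
    gd = REGISTRY[donor].gamma
    fractions = {
        name: 100.0 * nu * REGISTRY[name].gamma / gd for name, nu in pathway
    }
    total = sum(fractions.values())
    if total > 100.0 + atol:
        raise ValueError(f"pathway routes {total:.2f}% of donor electrons (>100%)")
    return fractions, bool(abs(total - 100.0) <= 1e-6)
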