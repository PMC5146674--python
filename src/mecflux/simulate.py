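"""Synthetic fed-batch cycles and OTU tables with known ground truth.

The batch-cycle simulator emulates a propionate-fed two-chamber MEC under a
set anode potential: ~36 mM donor consumed near-linearly (zero-order at the
configured removal rate) with a first-order tail below a threshold so the
current decays smoothly to ~0 at cycle end.  Electrons released by the
consumed donor are routed instant-by-instant to configurable sinks —
electrical current, methane, residual (anodic) hydrogen, and an undefined
remainder — so the pre-noise ledger closes exactly by construction:

    I(t) = f_current · γ_donor · F · (−dC/dt) · V_anode

Cathodic H₂ follows Faraday's law on the routed charge times a recovery
fraction.  Multiplicative Gaussian noise (truncated at zero) is applied to
the observables only; the exact routed totals are kept as ground truth.

The OTU-table generator draws multinomial reads from log-normal community
profiles, with a configurable dominant taxon for anode-like samples
(a Geobacter-dominated biofilm) and a Bacteria/Archaea mix with
methanogens for suspension-like samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .electrochem import (
    DEFAULT_PRESSURE_ATM,
    DEFAULT_TEMPERATURE_K,
    BatchCycleRecord,
    CurrentTrace,
    GasSample,
    gas_volume,
)
from .stoichiometry import FARADAY, REGISTRY

__all__ = [
    "SimConfig",
    "SimOutput",
    "SampleSpec",
    "simulate_batch_cycle",
    "simulate_otu_table",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated fed-batch cycle.

    Defaults are the experimental conditions being emulated: a 40 mL anode
    chamber fed 36 mM propionate removed at 10.5 mM/day, telemetry every
    10 min over a 4-day cycle, 2 % instrument noise, and a 0 V-like routing
    of donor electrons (71 % current, 22.9 % CH₄, 0.03 % residual H₂,
    remainder undefined).
    """

    seed: int = 0
    anode_volume_m3: float = 4.0e-5
    c0_mM: float = 36.0
    removal_rate_mM_per_day: float = 10.5
    f_current: float = 0.71
    f_ch4: float = 0.229
    f_h2_residual: float = 0.0003
    f_undefined: float = 0.0607
    cathodic_h2_recovery: float = 0.9
    set_potential_V: float = 0.0
    sampling_interval_s: float = 600.0
    hplc_interval_h: float = 6.0
    cycle_days: float = 4.0
    tail_threshold_mM: float = 2.0
    # open-circuit-like scenarios show a transient acetate pulse peaking
    # near donor depletion; SAP-like scenarios keep it at zero
    acetate_pulse_peak_mM: float = 0.0
    noise_cv_current: float = 0.02
    noise_cv_concentration: float = 0.02
    noise_cv_gas: float = 0.02
    temperature_K: float = DEFAULT_TEMPERATURE_K
    pressure_atm: float = DEFAULT_PRESSURE_ATM

    def __post_init__(self) -> None:
        total = self.f_current + self.f_ch4 + self.f_h2_residual + self.f_undefined
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"sink fractions sum to {total!r}, not 1")
        for name in ("noise_cv_current", "noise_cv_concentration", "noise_cv_gas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c0_mM <= 0 or self.removal_rate_mM_per_day <= 0:
            raise ValueError("c0 and removal rate must be positive")
        if self.anode_volume_m3 <= 0 or self.cycle_days <= 0:
            raise ValueError("volume and cycle length must be positive")

    def noiseless(self) -> "SimConfig":
        return replace(
            self, noise_cv_current=0.0, noise_cv_concentration=0.0, noise_cv_gas=0.0
        )

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "current": self.f_current,
            "methane": self.f_ch4,
            "hydrogen": self.f_h2_residual,
            "undefined": self.f_undefined,
        }


@dataclass
class SimOutput:
    """One simulated cycle: observables plus exact pre-noise ground truth."""

    trace: CurrentTrace
    hplc: pd.DataFrame  # time_h, propionate_mM, acetate_mM, formate_mM
    gas: list[GasSample]
    record: BatchCycleRecord
    ground_truth: dict[str, float] = field(default_factory=dict)


def _donor_profile(cfg: SimConfig, t_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic C(t) in mM and −dC/dt in mM/s on the given time grid.

    Zero-order decline at the configured rate down to the tail threshold,
    then first-order decay with the rate constant matched for slope
    continuity (k = rate / C_threshold).
    """
    r = cfg.removal_rate_mM_per_day / SECONDS_PER_DAY  # mM/s
    c_th = min(cfg.tail_threshold_mM, cfg.c0_mM)
    t_th = (cfg.c0_mM - c_th) / r
    k = r / c_th  # 1/s, slope-continuous at the threshold
    linear = t_s <= t_th
    c = np.where(linear, cfg.c0_mM - r * t_s, c_th * np.exp(-k * (t_s - t_th)))
    rate = np.where(linear, r, k * c)
    return c, rate


def _acetate_pulse(cfg: SimConfig, t_h: np.ndarray) -> np.ndarray:
    """Triangular acetate transient: peak at donor depletion, gone by cycle
    end.  Zero everywhere when the configured peak is zero (SAP-like)."""
    if cfg.acetate_pulse_peak_mM <= 0:
        return np.zeros_like(t_h)
    r = cfg.removal_rate_mM_per_day
    t_peak_h = (cfg.c0_mM - min(cfg.tail_threshold_mM, cfg.c0_mM)) / r * 24.0
    t_end_h = cfg.cycle_days * 24.0
    up = np.clip(t_h / t_peak_h, 0.0, 1.0)
    down = np.clip((t_end_h - t_h) / max(t_end_h - t_peak_h, 1e-9), 0.0, 1.0)
    return cfg.acetate_pulse_peak_mM * np.minimum(up, down)


def _apply_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.asarray(values, dtype=float).copy()
    noisy = values * rng.normal(1.0, cv, size=np.shape(values))
    return np.maximum(noisy, 0.0)


def simulate_batch_cycle(config: SimConfig) -> SimOutput:
    """Generate one fed-batch cycle with exact electron bookkeeping.

    The pre-noise ledger closes by construction and is asserted before
    noise is applied; everything is driven by ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gamma = REGISTRY["propionate"].gamma
    t_end = cfg.cycle_days * SECONDS_PER_DAY

    # telemetry grid
    t_s = np.arange(0.0, t_end + cfg.sampling_interval_s / 2, cfg.sampling_interval_s)
    c_mM, rate_mM_s = _donor_profile(cfg, t_s)

    # instantaneous current from the routed electron flux (mM ≡ mol/m³)
    current_true = (
        cfg.f_current * gamma * FARADAY * rate_mM_s * cfg.anode_volume_m3
    )

    # exact totals over [0, t_end]
    c_final = float(c_mM[-1])
    consumed_mol = (cfg.c0_mM - c_final) * cfg.anode_volume_m3
    eq_total = gamma * consumed_mol  # mol e⁻
    charge_true = cfg.f_current * eq_total * FARADAY
    ch4_mol = cfg.f_ch4 * eq_total / REGISTRY["methane"].gamma
    h2_residual_mol = cfg.f_h2_residual * eq_total / REGISTRY["hydrogen"].gamma
    h2_cathode_mol = cfg.cathodic_h2_recovery * charge_true / (2.0 * FARADAY)

    # pre-noise closure: routed sinks must account for all consumed electrons
    routed = (
        charge_true / FARADAY
        + ch4_mol * REGISTRY["methane"].gamma
        + h2_residual_mol * REGISTRY["hydrogen"].gamma
        + cfg.f_undefined * eq_total
    )
    assert math.isclose(routed, eq_total, rel_tol=1e-12), "electron conservation"

    ground_truth = {
        "f_current": cfg.f_current,
        "f_ch4": cfg.f_ch4,
        "f_h2_residual": cfg.f_h2_residual,
        "f_undefined": cfg.f_undefined,
        "donor_consumed_mol": consumed_mol,
        "donor_e_eq_mol": eq_total,
        "charge_C": charge_true,
        "ch4_mol": ch4_mol,
        "h2_residual_mol": h2_residual_mol,
        "h2_cathode_mol": h2_cathode_mol,
        "ce_percent": 100.0 * cfg.f_current,
        "removal_rate_mM_per_day": (cfg.c0_mM - c_final) / cfg.cycle_days,
        "seed": float(cfg.seed),
    }

    # observables, noise applied independently per stream
    trace = CurrentTrace(t_s, _apply_noise(rng, current_true, cfg.noise_cv_current))

    hplc_t = np.arange(0.0, cfg.cycle_days * 24.0 + 1e-9, cfg.hplc_interval_h)
    c_hplc, _ = _donor_profile(cfg, hplc_t * 3600.0)
    acetate = _acetate_pulse(cfg, hplc_t)
    hplc = pd.DataFrame(
        {
            "time_h": hplc_t,
            "propionate_mM": _apply_noise(rng, c_hplc, cfg.noise_cv_concentration),
            "acetate_mM": _apply_noise(rng, acetate, cfg.noise_cv_concentration),
            "formate_mM": np.zeros_like(hplc_t),
        }
    )

    # headspace assembly: anode holds CH4 + residual H2 + CO2 filler,
    # cathode holds the Faradaic H2.  The filler never enters the ledger.
    co2_anode_mol = 0.5 * ch4_mol
    anode_mol = ch4_mol + h2_residual_mol + co2_anode_mol
    v_anode = gas_volume(anode_mol, cfg.temperature_K, cfg.pressure_atm)
    v_cathode = gas_volume(h2_cathode_mol, cfg.temperature_K, cfg.pressure_atm)
    gas = [
        GasSample(
            phase="anode",
            volume_mL=float(_apply_noise(rng, np.array(v_anode), cfg.noise_cv_gas)),
            temperature_K=cfg.temperature_K,
            pressure_atm=cfg.pressure_atm,
            x_h2=h2_residual_mol / anode_mol if anode_mol > 0 else 0.0,
            x_ch4=ch4_mol / anode_mol if anode_mol > 0 else 0.0,
            x_co2=co2_anode_mol / anode_mol if anode_mol > 0 else 0.0,
        ),
        GasSample(
            phase="cathode",
            volume_mL=float(_apply_noise(rng, np.array(v_cathode), cfg.noise_cv_gas)),
            temperature_K=cfg.temperature_K,
            pressure_atm=cfg.pressure_atm,
            x_h2=1.0,
        ),
    ]

    record = BatchCycleRecord(
        anode_volume_m3=cfg.anode_volume_m3,
        cycle_days=cfg.cycle_days,
        set_potential_V=cfg.set_potential_V,
        initial_mM={"propionate": cfg.c0_mM, "acetate": 0.0, "formate": 0.0},
        final_mM={
            "propionate": float(hplc["propionate_mM"].iloc[-1]),
            "acetate": float(hplc["acetate_mM"].iloc[-1]),
            "formate": float(hplc["formate_mM"].iloc[-1]),
        },
        gas=gas,
        trace=trace,
    )
    return SimOutput(
        trace=trace, hplc=hplc, gas=gas, record=record, ground_truth=ground_truth
    )


@dataclass(frozen=True)
class SampleSpec:
    """One simulated community sample.

    ``kind`` selects the profile shape: ``"anode"`` puts ``dominant_weight``
    of the reads on a single exoelectrogen-like taxon; ``"suspension"``
    spreads reads over a diverse Bacteria/Archaea mix with
    ``archaea_weight`` of the expected reads on archaeal (methanogen) taxa.
    """

    name: str
    kind: str = "anode"
    depth: int = 50_000
    dominant_weight: float = 0.55
    archaea_weight: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("anode", "suspension"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.depth < 1:
            raise ValueError("sampling depth must be >= 1")
        if not 0.0 <= self.dominant_weight < 1.0:
            raise ValueError("dominant_weight must lie in [0, 1)")
        if not 0.0 <= self.archaea_weight < 1.0:
            raise ValueError("archaea_weight must lie in [0, 1)")


def _lineages(n_taxa: int, n_archaea: int) -> list[str]:
    lineages = []
    for i in range(n_taxa):
        if i == 0:
            lineages.append(
                "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;"
                "Geobacteraceae;Geobacter"
            )
        elif i < n_taxa - n_archaea:
            lineages.append(f"Bacteria;Phylum_{i % 7};Class_{i % 11};o;f;Genus_{i}")
        else:
            lineages.append(
                f"Archaea;Euryarchaeota;Methanomicrobia;o;f;Methanogen_{i}"
            )
    return lineages


def simulate_otu_table(
    n_taxa: int,
    samples: list[SampleSpec],
    seed: int = 0,
    archaeal_fraction_of_taxa: float = 0.1,
) -> "OtuTable":
    """Multinomial OTU tables from log-normal community profiles.

    One shared taxon pool: taxon 0 is the anode-dominant exoelectrogen, the
    last ``archaeal_fraction_of_taxa`` of taxa are methanogen-like Archaea.
    Per sample, expected relative abundances come from a seeded log-normal
    profile reshaped by the sample spec, and reads are drawn multinomially
    at the requested depth.
    """
    from .community import OtuTable

    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not samples:
        raise ValueError("at least one sample spec required")
    rng = np.random.default_rng(seed)
    n_archaea = max(1, int(round(archaeal_fraction_of_taxa * n_taxa)))
    taxa = [f"OTU_{i:04d}" for i in range(n_taxa)]
    lineages = _lineages(n_taxa, n_archaea)
    is_archaea = np.array([lin.startswith("Archaea") for lin in lineages])

    cols: dict[str, np.ndarray] = {}
    for spec in samples:
        base = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
        base[0] = 0.0
        if spec.kind == "anode":
            # biofilm: dominant exoelectrogen, almost no Archaea
            base[is_archaea] *= 0.02
            p = base / base.sum() * (1.0 - spec.dominant_weight)
            p[0] = spec.dominant_weight
        else:
            arch = base * is_archaea
            bact = base * ~is_archaea
            p = (
                spec.archaea_weight * arch / arch.sum()
                + (1.0 - spec.archaea_weight) * bact / bact.sum()
            )
        p = p / p.sum()
        cols[spec.name] = rng.multinomial(spec.depth, p)

    counts = pd.DataFrame(cols, index=pd.Index(taxa, name="#OTU ID"))
    taxonomy = pd.Series(lineages, index=counts.index, name="taxonomy")
    return OtuTable(counts=counts, taxonomy=taxonomy)
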