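"""File dialects, run configuration, and the end-to-end pipeline.

Dialects (all plain delimited text):

* trace CSV — header ``time_s,current_A``
* HPLC CSV — header ``time_h,propionate_mM,acetate_mM,formate_mM``
* gas CSV — header ``phase,volume_mL,temp_K,pressure_atm,x_H2,x_CH4,x_CO2``
  with phase in {anode, cathode}
* OTU TSV — first header cell ``#OTU ID``, one column per sample, optional
  trailing ``taxonomy`` column with semicolon-separated ranks (a separate
  two-column taxonomy TSV is also accepted)

Malformed rows are reported with their line number and column name.
Potentials are stored vs SHE throughout; an input flag converts from
Ag/AgCl (+0.210 V vs SHE).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .balance import SinkBalance, electron_balance
from .bioenergetics import donor_couples, favorability_matrix
from .community import OtuTable, abundance_table, alpha_diversity, domain_ratio, venn3
from .electrochem import (
    BatchCycleRecord,
    CurrentTrace,
    GasSample,
    PerformanceMetrics,
    cycle_metrics,
)
from .simulate import SimOutput
from .stoichiometry import REGISTRY

__all__ = [
    "AG_AGCL_OFFSET_V",
    "RunConfig",
    "read_trace",
    "read_hplc",
    "read_gas",
    "read_otu_table",
    "write_sim_output",
    "run_pipeline",
]

#: Ag/AgCl reference electrode offset vs SHE (V).
AG_AGCL_OFFSET_V = 0.210


def _read_csv_strict(path: str | Path, required: list[str], sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    numeric = [c for c in required if not c.startswith(("phase",))]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    return df


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a ``time_s,current_A`` CSV into a validated trace."""
    df = _read_csv_strict(path, ["time_s", "current_A"])
    return CurrentTrace(df["time_s"].to_numpy(), df["current_A"].to_numpy())


def read_hplc(path: str | Path) -> pd.DataFrame:
    """Read a concentration time-series CSV (mM vs hours)."""
    return _read_csv_strict(
        path, ["time_h", "propionate_mM", "acetate_mM", "formate_mM"]
    )


def read_gas(path: str | Path) -> list[GasSample]:
    """Read per-phase headspace compositions into gas samples."""
    df = _read_csv_strict(
        path,
        ["phase", "volume_mL", "temp_K", "pressure_atm", "x_H2", "x_CH4", "x_CO2"],
    )
    return [
        GasSample(
            phase=str(row["phase"]),
            volume_mL=float(row["volume_mL"]),
            temperature_K=float(row["temp_K"]),
            pressure_atm=float(row["pressure_atm"]),
            x_h2=float(row["x_H2"]),
            x_ch4=float(row["x_CH4"]),
            x_co2=float(row["x_CO2"]),
        )
        for _, row in df.iterrows()
    ]


def read_otu_table(path: str | Path, taxonomy_path: str | Path | None = None) -> OtuTable:
    """Read a tab-separated OTU table, attaching taxonomy when present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "#OTU ID":
        raise ValueError(f"{path.name}: first header cell must be '#OTU ID'")
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy")
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy = tax.iloc[:, 0]
    return OtuTable(counts=df, taxonomy=taxonomy)


def write_sim_output(sim: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cycle as the full CSV set plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace": out / "trace.csv",
        "hplc": out / "hplc.csv",
        "gas": out / "gas.csv",
        "ground_truth": out / "ground_truth.json",
    }
    pd.DataFrame(
        {"time_s": sim.trace.times_s, "current_A": sim.trace.currents_A}
    ).to_csv(paths["trace"], index=False)
    sim.hplc.to_csv(paths["hplc"], index=False)
    pd.DataFrame(
        [
            {
                "phase": g.phase,
                "volume_mL": g.volume_mL,
                "temp_K": g.temperature_K,
                "pressure_atm": g.pressure_atm,
                "x_H2": g.x_h2,
                "x_CH4": g.x_ch4,
                "x_CO2": g.x_co2,
            }
            for g in sim.gas
        ]
    ).to_csv(paths["gas"], index=False)
    paths["ground_truth"].write_text(
        json.dumps(sim.ground_truth, indent=2, sort_keys=True)
    )
    return paths


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    File paths may be None (stages needing them are skipped with a
    warning).  ``potentials_V`` feeds the thermodynamic favorability
    matrix; ``vs_ag_agcl`` converts them from Ag/AgCl to SHE on load.
    """

    trace_path: Path | None = None
    hplc_path: Path | None = None
    gas_path: Path | None = None
    otu_path: Path | None = None
    anode_volume_m3: float = 4.0e-5
    cycle_days: float = 4.0
    set_potential_V: float = 0.0
    c0_mM: float = 36.0
    donor: str = "propionate"
    constants_profile: str = "paper"
    potentials_V: tuple[float, ...] = (-0.25, 0.0, 0.25)
    vs_ag_agcl: bool = False
    rarefaction_depth: int | None = None
    shannon_base: float = 2
    rank: str = "genus"
    others_threshold_percent: float = 1.0
    seed: int = 0
    decimals: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        for name in ("trace_path", "hplc_path", "gas_path", "otu_path"):
            value = getattr(cfg, name)
            if value is not None:
                p = Path(value)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
                setattr(cfg, name, p)
        return cfg

    def potentials_vs_she(self) -> tuple[float, ...]:
        if self.vs_ag_agcl:
            return tuple(v + AG_AGCL_OFFSET_V for v in self.potentials_V)
        return self.potentials_V


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage the inputs allow and assemble one report bundle.

    Always computes the thermodynamic favorability matrix; computes
    performance metrics and the electron ledger when trace + HPLC (+ gas)
    inputs are present, and the community block when an OTU table is
    present.  Writes ``metrics.tsv``, ``balance.tsv``, ``thermo.tsv``,
    ``diversity.tsv`` and ``report.json`` into *out_dir* when given.
    Deterministic for a fixed config and seed (sorted JSON keys).
    """
    report: dict = {"config": {"seed": config.seed, "profile": config.constants_profile}}

    thermo = favorability_matrix(
        list(config.potentials_vs_she()),
        couples=donor_couples(config.constants_profile),
    )
    report["thermo"] = thermo.to_dict(orient="records")

    record: BatchCycleRecord | None = None
    metrics: PerformanceMetrics | None = None
    sinks: SinkBalance | None = None
    if config.trace_path is not None and config.hplc_path is not None:
        trace = read_trace(config.trace_path)
        hplc = read_hplc(config.hplc_path)
        gas = read_gas(config.gas_path) if config.gas_path is not None else []
        record = BatchCycleRecord(
            anode_volume_m3=config.anode_volume_m3,
            cycle_days=config.cycle_days,
            set_potential_V=config.set_potential_V,
            initial_mM={config.donor: config.c0_mM},
            final_mM={
                name: float(hplc[f"{name}_mM"].iloc[-1])
                for name in ("propionate", "acetate", "formate")
                if f"{name}_mM" in hplc.columns
            },
            gas=gas,
            trace=trace,
            donor=config.donor,
        )
        record.initial_mM.setdefault("acetate", float(hplc["acetate_mM"].iloc[0]))
        record.initial_mM.setdefault("formate", float(hplc["formate_mM"].iloc[0]))
        metrics = cycle_metrics(record, REGISTRY[config.donor].gamma)
        report["metrics"] = {
            k: round(v, 4) for k, v in metrics.__dict__.items()
        }
        if gas:
            sinks = electron_balance(record)
            report["balance_percent"] = {
                k: round(v, config.decimals) for k, v in sinks.percent.items()
            }
        else:
            warnings.warn("no gas file: electron ledger skipped", stacklevel=2)
    else:
        warnings.warn("no trace/HPLC inputs: metrics stage skipped", stacklevel=2)

    diversity = None
    if config.otu_path is not None:
        table = read_otu_table(config.otu_path)
        if config.rarefaction_depth is not None:
            from .community import rarefy

            table = rarefy(table, config.rarefaction_depth, config.seed)
        diversity = alpha_diversity(table, shannon_base=config.shannon_base)
        report["diversity"] = {
            sample: {k: round(float(v), 4) for k, v in row.items()}
            for sample, row in diversity.frame.iterrows()
        }
        if table.taxonomy is not None:
            report["archaea_bacteria_ratio"] = {
                k: (round(v, 4) if v != float("inf") else "inf")
                for k, v in domain_ratio(table).items()
            }
            report["abundance"] = abundance_table(
                table, config.rank, config.others_threshold_percent
            ).round(config.decimals).to_dict()
        if len(table.samples) >= 3:
            sets = [table.observed_taxa(s) for s in table.samples[:3]]
            counts, percents = venn3(*sets)
            report["venn3"] = {"counts": counts, "percent_of_union": percents}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        thermo.to_csv(out / "thermo.tsv", sep="\t", index=False)
        if metrics is not None:
            pd.Series(metrics.__dict__).to_csv(
                out / "metrics.tsv", sep="\t", header=False
            )
        if sinks is not None:
            sinks.as_frame(config.decimals).to_csv(out / "balance.tsv", sep="\t")
        if diversity is not None:
            diversity.frame.to_csv(out / "diversity.tsv", sep="\t")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
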