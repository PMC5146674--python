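"""Compute per-cycle performance metrics for every simulated condition.

Reads the raw files written by 01_simulate_cycles.py, rebuilds each batch
record, and reports volumetric current density, coulombic efficiency, H2
production rate and yield, and propionate removal — the same panel a
reactor study reports per condition.  Writes results/metrics.tsv.
"""

from pathlib import Path

import pandas as pd

from mecflux import (
    BatchCycleRecord,
    REGISTRY,
    cycle_metrics,
    linear_removal_rate,
)
from mecflux.io import read_gas, read_hplc, read_trace

ROOT = Path(__file__).resolve().parents[1]
CYCLES = ROOT / "results" / "cycles"


def main() -> None:
    rows = {}
    for cycle_dir in sorted(CYCLES.iterdir()):
        if not (cycle_dir / "trace.csv").exists():
            continue
        trace = read_trace(cycle_dir / "trace.csv")
        hplc = read_hplc(cycle_dir / "hplc.csv")
        gas = read_gas(cycle_dir / "gas.csv")
        cycle_days = float(trace.times_s[-1]) / 86400.0
        record = BatchCycleRecord(
            anode_volume_m3=4.0e-5,
            cycle_days=cycle_days,
            set_potential_V=0.0,
            initial_mM={"propionate": float(hplc["propionate_mM"].iloc[0])},
            final_mM={c: float(hplc[f"{c}_mM"].iloc[-1])
                      for c in ("propionate", "acetate", "formate")},
            gas=gas,
            trace=trace,
        )
        m = cycle_metrics(record, REGISTRY["propionate"].gamma)
        row = {k: round(v, 3) for k, v in m.__dict__.items()}
        row["linear_removal_mM_per_day"] = round(
            linear_removal_rate(hplc["time_h"].to_numpy(),
                                hplc["propionate_mM"].to_numpy()), 2)
        rows[cycle_dir.name] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "condition"
    out = ROOT / "results" / "metrics.tsv"
    table.to_csv(out, sep="\t")
    print(table.to_string())
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
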