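"""Close the electron ledger for every simulated condition.

Builds the end-of-cycle sink balance (current, methane, residual hydrogen,
dissolved residues, undefined remainder) per condition and compares the
recovered percentages with the simulator's configured ground truth — the
per-condition analogue of an end-of-batch electron-distribution table.
Writes results/balance.tsv (rows = sinks, columns = conditions).
"""

import json
from pathlib import Path

import pandas as pd

from mecflux import BatchCycleRecord, electron_balance
from mecflux.io import read_gas, read_hplc, read_trace

ROOT = Path(__file__).resolve().parents[1]
CYCLES = ROOT / "results" / "cycles"


def main() -> None:
    columns = {}
    recovery = []
    for cycle_dir in sorted(CYCLES.iterdir()):
        if not (cycle_dir / "trace.csv").exists():
            continue
        trace = read_trace(cycle_dir / "trace.csv")
        hplc = read_hplc(cycle_dir / "hplc.csv")
        gas = read_gas(cycle_dir / "gas.csv")
        truth = json.loads((cycle_dir / "ground_truth.json").read_text())
        record = BatchCycleRecord(
            anode_volume_m3=4.0e-5,
            cycle_days=float(trace.times_s[-1]) / 86400.0,
            set_potential_V=0.0,
            initial_mM={"propionate": float(hplc["propionate_mM"].iloc[0])},
            final_mM={c: float(hplc[f"{c}_mM"].iloc[-1])
                      for c in ("propionate", "acetate", "formate")},
            gas=gas,
            trace=trace,
        )
        sinks = electron_balance(record, basis="consumed")
        columns[cycle_dir.name] = {k: round(v, 2) for k, v in sinks.percent.items()}
        for sink, key in (("current", "f_current"), ("methane", "f_ch4"),
                          ("hydrogen", "f_h2_residual"), ("undefined", "f_undefined")):
            recovery.append(abs(sinks.percent[sink] - 100.0 * truth[key]))

    table = pd.DataFrame(columns)
    table.index.name = "sink"
    out = ROOT / "results" / "balance.tsv"
    table.to_csv(out, sep="\t")
    print(table.to_string())
    print(f"\nmean |recovered - configured| over all sinks: "
          f"{sum(recovery)/len(recovery):.3f} percentage points")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
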