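"""Rank anode respiration against methanogenesis across set potentials.

Evaluates the anode energy-gain model dG = -nF(E_anode - E0') for the
acetate, H2 and formate couples at -0.25, 0 and 0.25 V vs SHE, pairs each
with the competing methanogenic reaction dG from the formation-energy
table, and prints which sink wins the donor thermodynamically at each
potential.  Writes results/thermo.tsv.
"""

from pathlib import Path

from mecflux import favorability_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = favorability_matrix([-0.25, 0.0, 0.25])
    out = ROOT / "results" / "thermo.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    switches = table[table["preferred"] == "methane"]
    at = sorted(switches["e_anode_V"].unique())
    print(f"\nmethanogenesis preferred in {len(switches)} of {len(table)} "
          f"(potential, donor) pairs, only at E_anode = {at} V")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
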