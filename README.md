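# mecflux

Electron-flux accounting and bioenergetics for propionate-fed microbial
electrolysis cells (MECs), with formula-level microbial-community metrics
and a ground-truth synthetic-data generator.

## The problem

In an MEC fed a fermentable substrate such as propionate, the electrons
released by substrate oxidation split between competing sinks: electrical
current collected at a poised anode, methane made by methanogens, residual
dissolved intermediates, and an "undefined" remainder (biomass, soluble
microbial products). Which sink wins depends on the set anode potential
(SAP), because the energy a microbe gains by respiring on the anode is

    ΔG°′ = −n·F·(E_anode − E°′)      [per mol donor]

with *n* the electrons transferred, *F* = 96,485 C/mol e⁻, and *E°′* the
standard biological redox potential of the donor couple. This package
implements, as a tested library plus a short analysis pipeline:

- **stoichiometry** — electron equivalents γ = 4C + H − 2O − 3N − z
  (γ = 14 for propionate, 8 for acetate/CH₄, 2 for H₂/formate) and
  balanced oxidation half-reactions;
- **electrochem** — per-cycle performance metrics: trapezoidal charge,
  coulombic efficiency CE = 100·Q/(F·γ·Δn), volumetric current density,
  H₂ production rate and yield, substrate removal;
- **balance** — the end-of-cycle electron ledger over all sinks, closed
  exactly to 100 % through the undefined term, plus electron time-course
  fractions and generic pathway fractions;
- **bioenergetics** — the anode energy-gain model above and full-reaction
  ΔG°′ from Thauer-convention (pH 7) formation free energies, ranked per
  donor and potential against the competing methanogenic reactions;
- **community** — observed OTUs, bias-corrected Chao1, Shannon, the
  Gini–Simpson index, Good's coverage, seeded hypergeometric rarefaction,
  three-sample Venn sharing, Archaea:Bacteria ratios, and rank-level
  abundance tables with <1 % taxa pooled as "others";
- **simulate** — fed-batch cycles with exact electron bookkeeping (the
  pre-noise ledger closes by construction) and multinomial OTU tables, so
  every stage is testable end-to-end against known ground truth.

## Worked example

```python
from mecflux import SimConfig, simulate_batch_cycle, electron_balance

sim = simulate_batch_cycle(SimConfig(seed=7))   # 36 mM propionate, 40 mL anode
sinks = electron_balance(sim.record, basis="consumed")
print(sinks.as_frame())
```

prints (seed 7, 2 % instrument noise):

```
            milli_e_eq  percent
sink
current        14.2632    70.82
methane         4.6658    23.17
hydrogen        0.0061     0.03
propionate      0.0000     0.00
acetate         0.0000     0.00
formate         0.0000     0.00
undefined       1.2040     5.98
```

The simulated cycle routed 71 / 22.9 / 0.03 / 6.07 % of the consumed donor
electrons to current / CH₄ / residual H₂ / undefined; the pipeline recovers
those fractions from the noisy observables to well within a percentage
point, and the ledger rows sum to the donor electron equivalents exactly.

```python
from mecflux import favorability_matrix
print(favorability_matrix([-0.25, 0.0, 0.25]))
```

shows acetate oxidation to current at −214.6 kJ/mol (0 V) and −407.6 kJ/mol
(0.25 V) against acetoclastic methanogenesis at −31.0 kJ/mol — current wins
at the positive potentials, methane at −0.25 V (−21.6 vs −31.0 kJ/mol).

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on simulated data and
write tables under `results/`:

1. `01_simulate_cycles.py` — one fed-batch cycle per condition (three SAPs
   and an open-circuit control), raw CSVs plus ground truth;
2. `02_performance_metrics.py` — the per-condition metrics panel;
3. `03_electron_ledger.py` — the sink balance per condition, checked
   against the configured ground truth;
4. `04_thermodynamics.py` — the ΔG grid and sink ranking;
5. `05_community.py` — diversity, OTU sharing, domain ratios and abundance
   tables over simulated anode/suspension communities.

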