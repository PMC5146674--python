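# Methods

## Electron-equivalent accounting

All bookkeeping runs in electron equivalents: the moles of electrons
released by complete oxidation of a compound to HCO₃⁻, H₂O and NH₄⁺. For
C_c H_h O_o N_n with formal charge z,

    γ = 4c + h − 2o − 3n − z.

Nitrogen is referenced to NH₄⁺ (−3 per N); no nitrogenous donor appears in
the propionate system, but the formula handles them. Because the −z term
absorbs the dissociation proton, the acid and anion conventions give the
same γ (asserted in the tests). The same number falls out of explicitly
balancing the oxidation half-reaction

    C_c H_h O_o N_n^z + (3c−o) H₂O → c HCO₃⁻ + n NH₄⁺ + p H⁺ + γ e⁻

by element and charge count; the package computes γ both ways and the test
suite cross-checks them over random compositions. Charge converts at
F = 96,485 C/mol e⁻. Key values: propionate 14, acetate 8, CH₄ 8,
H₂ 2, formate 2, CO₂/HCO₃⁻ 0.

## The electron ledger

The end-of-cycle sink balance distributes donor electrons over measured
sinks — integrated current, CH₄ (anode + cathode headspace combined),
residual anodic H₂, dissolved residues of the donor and its
intermediates — and closes with an undefined remainder (biomass, soluble
products, unmeasured losses), so percentages sum to 100 exactly. Cathodic
H₂ is the Faradaic product of the current already booked and is therefore
*not* a donor sink; only anode-phase H₂ counts as one. Membrane crossover
is ignored (it is below half a percent in the two-chamber geometry this
emulates); subtracting a crossover estimate is left to the caller.

Two reference bases are provided. `basis="fed"` (default) takes the
electrons in all donor fed at cycle start as 100 % and books unused donor
as a sink; `basis="consumed"` references the electrons actually released.
They coincide whenever the donor is fully consumed. The consumed basis is
the natural one for simulator-recovery checks, since the generator routes
fractions of consumed electrons.

An over-closed ledger (measured sinks exceeding donor electrons) is legal
but flagged; a relative tolerance of 1e-9 on the closure term keeps float
cancellation from raising the flag on perfect data.

## Performance metrics

Charge is the trapezoidal integral of the current trace — exact for the
piecewise-linear telemetry a potentiostat logs, which is why Simpson's rule
buys nothing here. CE (%) = 100·Q/(F·γ·Δn_donor); values above 100 warn but
do not raise. Peak current is the maximum of a 3-sample moving median
(single-sample telemetry spikes otherwise inflate it). Current density and
the H₂ rate normalise to the anode liquid volume (40 mL default), the one
volume used consistently throughout. Gas amounts convert by the ideal-gas
law at the measurement conditions (default 303.15 K, 1 atm — a 30 °C
room); the H₂ rate uses cathode-collected gas (headspace plus bag summed
into one phase entry). The whole-cycle removal rate (Δc over duration) and
the zero-order linear-phase rate (slope fit above a 2 mM tail threshold)
are both reported, because a cycle that runs past depletion dilutes the
former.

## Anode energetics and reaction ΔG°′

The anode energy gain ΔG°′ = −nF(E_anode − E°′) is affine in the set
potential with slope −nF. Two constants profiles ship for the donor
couples:

| donor    | n | paper E°′ (V) | literature E°′ (V) |
|----------|---|---------------|---------------------|
| acetate  | 8 | −0.278        | −0.290              |
| H₂       | 2 | −0.413        | −0.414              |
| formate  | 2 | −0.489        | −0.432              |

The "paper" profile is back-derived from a published ΔG grid so that grid
reproduces exactly to one decimal; the "literature" profile carries the
textbook potentials. The formate discrepancy (−0.489 vs −0.432 V) is real
and unresolved — both profiles are selectable, the paper profile is the
default. One printed 0 V value in the source grid's H₂/formate sentence
(−214.6) contradicts the same paragraph's H₂ value (−79.7) and is treated
as a typographical slip; the internally consistent grid is used.

Full-reaction ΔG°′ sums ν·ΔGf°′ over a balance-checked stoichiometry using
Thauer-convention pH-7 formation energies (kJ/mol): HCO₃⁻ −586.85, H₂O
−237.18, CH₄ −50.75, H⁺ −39.87, H₂ 0, acetate −369.41, formate −351.04,
propionate −361.08. This yields hydrogenotrophic methanogenesis
(4 H₂ + HCO₃⁻ + H⁺ → CH₄ + 3 H₂O) at −135.6, acetoclastic
(acetate + H₂O → CH₄ + HCO₃⁻) at −31.0, and the formate route at −130.1.
Conditions are standard-biochemical only (1 M / 1 atm, 298 K, pH 7); a
reaction-quotient correction ΔG = ΔG°′ + RT ln Q exists as a helper but is
not used anywhere in the shipped analyses. Outputs round to one decimal.

The favorability matrix compares, per donor and potential, the anode gain
(per mol donor) with the methanogenic reaction ΔG normalised per mol donor
(the hydrogenotrophic reaction consumes 4 H₂ per CH₄, so its per-donor
value is a quarter of the reaction value). Ranking is strict by ΔG with
exact ties reported as ties.

## Community metrics

All indices are computed from first principles and cross-checked against
scikit-bio in the tests. Shannon defaults to base 2 (base e selectable;
the change-of-base identity is property-tested). Simpson is reported as
the Gini–Simpson index 1 − Σp², which is high for diverse samples. Chao1
uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) by default — it is
finite when doubletons are absent — with the classic F₁²/(2F₂) form behind
a flag. Good's coverage is 100·(1 − F₁/N). Rarefaction subsamples without
replacement by exact multivariate hypergeometric draws (numpy Generator),
seeded; samples shallower than the requested depth are dropped with a
warning. Venn regions are exact set algebra; abundance tables aggregate at
a chosen rank and pool labels that stay under the threshold (default 1 %)
in *every* sample into "others", keeping one consistent row set across
samples; taxa sort lexicographically for deterministic output.

## The synthetic-data generator

`simulate_batch_cycle` emulates one fed-batch cycle under study-like
conditions: 36 mM propionate in a 4.0e-5 m³ anode chamber, zero-order
removal at 10.5 mM/day switching to first-order below 2 mM with the rate
constant matched for slope continuity (k = rate/threshold), telemetry
every 600 s, concentrations every 6 h, a 4-day cycle (5 days and
9.02 mM/day for the open-circuit-like scenario in the analysis drivers).
Consumed electrons are routed instant-by-instant by the configured
fractions; the default routing (0.71 current / 0.229 CH₄ / 0.0003 residual
H₂ / 0.0607 undefined) mirrors a 0 V-like condition. The instantaneous
current is f_current·γ·F·(−dC/dt)·V; CH₄ accrues at 1 mol per 8 e⁻eq and
residual H₂ at 1 mol per 2 e⁻eq; cathodic H₂ is 0.9·Q/2F (a 90 % cathodic
recovery). Anode headspace is CH₄ + residual H₂ plus a CO₂ filler (half
the CH₄ moles — the filler never enters the ledger); cathode headspace is
pure H₂.

Noise is multiplicative Gaussian with CV 0.02 per stream (current,
concentration, gas volume), truncated at zero — instrument error scales
with signal. Ground truth is stored pre-noise and the simulator asserts
exact electron conservation before noising. Everything derives from one
seed.

What the generator does **not** emulate: mechanistic microbial kinetics
(routing fractions are imposed, not emergent from competition), dissolved
gas partitioning, acetate/formate transients in SAP-like scenarios (they
stay at zero, as observed; an open-circuit-style acetate pulse is a config
option), pH drift, and inter-replicate biological variance. Passing the
recovery tests therefore shows the *accounting pipeline* is unbiased and
precise at instrument-level noise — not that real reactors obey the
routing model.

`simulate_otu_table` draws multinomial reads from log-normal (σ = 1.5)
expected-abundance profiles over a shared taxon pool: anode-like samples
put a configurable weight (0.45–0.65 typical) on a single
exoelectrogen-like taxon and suppress Archaea ×0.02; suspension-like
samples mix a configurable archaeal (methanogen) expected fraction into a
diverse bacterial background. Depths of 5e4–1e5 reads reproduce the
sampling regime of amplicon surveys at desk scale.

## Numerical and design choices

- Units are encoded in field names (`times_s`, `removal_rate_mM_per_day`);
  concentrations are mM throughout, which equals mol/m³ and multiplies
  directly with the anode volume in m³.
- Potentials are stored vs SHE; an input flag converts from Ag/AgCl by
  +0.210 V.
- Ledger percentages print to 2 decimals, ΔG to one decimal, matching how
  such tables are conventionally reported.
- Problem sizes in the tests (20-seed recovery runs, 1,000-draw rarefaction
  checks, 3,000-taxon community simulations) were chosen as the smallest
  sizes at which the Monte-Carlo error bounds in the assertions are
  meaningful.
- The analysis drivers seed per scenario (base seed + scenario index) so
  conditions are independent but the whole pipeline is reproducible.

## Known limitations

- The theoretical pathway-split numbers for specific degradation routes
  depend on supplementary stoichiometries not reproduced here; the generic
  `pathway_fraction` operation covers the calculation, and only the generic
  arithmetic is asserted.
- Diversity-index magnitudes from real amplicon pipelines depend on
  denoising/OTU-picking choices upstream of this package; no attempt is
  made to reproduce any particular pipeline's absolute index values.
- No temperature dependence of ΔG (van 't Hoff), no ionic-strength or
  activity corrections, no electrode kinetics.
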