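# Methods

## Scope and assumptions

The package models *proto-cells*: cells stripped to the components strictly
required for self-reproduction. Growth is treated as a stationary-state
doubling process — every component count `N_j` and the total mass `M_tot`
are exactly duplicated over the doubling time `t_d`, all catalysts work at
constant apparent rates `k_j`, all processes run in parallel and are
precisely balanced. Under these assumptions there are no dynamics: each
model is a *determined algebraic system* (as many independent equations as
output parameters once one driver is fixed), with a unique positive
solution. There is no regulation, no kinetics, no stochasticity, no cell
cycle and no environmental dependence (pH, temperature); reactions are
strictly unidirectional (no exchange fluxes).

## Balance archetypes

* **Polymer doubling.** For each polymer class (protein, RNA, DNA, lipid)
  with polymerase `pol`: `t_d = Σ N_j n_j / (N_pol k_pol)`. The protein
  class is always polymerized by the ribosome/RPC; RNA by the RNA-polymerase
  complex; lipids by the lipid-synthesis enzyme (one "monomer" per lipid).
* **Pathway flux.** Each pathway PW1–PW5 is a linear chain of identical
  unidirectional reactions. Per-step fluxes all equal the downstream demand
  `J`, per-step enzyme counts equal `J / k_enz`, so the pathway total is
  `N_enz = l_PW · J / k_enz`. Demands: PW2 ← translation (`N_rs k_rs`), PW4
  ← transcription, PW3 ← replication, PW5 ← lipid synthesis, PW1 ← the sum
  of all monomer demands times `substrates_per_monomer`.
* **DNA replication.** A single genome (both strands, `n_dna`
  deoxyribonucleotides) is copied once per doubling by a fixed pair of
  replisomes: the dNTP demand is `n_dna / t_d` and the required per-replisome
  rate `n_dna / (2 t_d)` must not exceed the cap `k_rc`; exceeding it is
  reported as a typed infeasibility, never clamped. Genome and replisome
  counts do not scale with ribosomes — this is what makes DNA a
  "second-group" component.
* **Energy and transport.** Membrane ETC complexes produce exactly the ATP
  consumed by polymerization (per-monomer costs), pathway reactions
  (per-reaction cost × length × flux) and transport (per-imported-molecule
  cost). Transporters import exactly the demand: on minimal medium the PW1
  substrate plus the substrate the ETC oxidizes (`J_ATP /
  atp_per_substrate_oxidized`); on rich medium all monomers arrive through a
  dedicated monomer-transporter class while a separate transporter imports
  the energy substrate. ETC and transporter counts are therefore outputs,
  almost proportional to `N_rs`.
* **Membrane area.** The surface is tiled exactly: `A = N_etc a_etc +
  N_tp a_tp + N_mtp a_mtp + N_lip a_lip / 2`. Lipids form two leaflets of
  equal area (hence the factor 2 per bilayer patch); membrane proteins span
  the bilayer and are counted once. The lipid count is whatever area the
  proteins leave — negative leftover area defines the growth boundary.
* **Mass and volume.** Dry mass sums `N_j × mass_j` (protein mass from
  amino-acid content × 110 Da, RNA × 324 Da/nt, DNA × 308 Da/dnt, lipids
  750 Da); `M_tot = dry / (1 − water_mass_fraction)`;
  `V = M_tot / density`.

### mRNA allocation

mRNA is not an independent species: each protein species holds mRNA copies
proportional to its share of translation (`N_j n_j / Σ N n`), normalized so
the total mRNA count is `mrna_per_ribosome × N_rs`, with coding-region
lengths of 3 nt per codon. The resulting total nucleotide load is
`3 μ Σ N_j n_j² / (t_d k_rs)` — linear in the counts, and stoichiometrically
tied to `N_rs`, which keeps compositions without second-group components on
flat doubling-time lines.

## Geometry

The cell is an ideal cylinder with hemispherical caps. Two conventions
relate area to volume:

* **fixed_shape (canonical).** The aspect ratio γ = total length/diameter
  is constant and the cell scales isotropically:
  `A = 4πγ r²`, `V = πr³(2γ − 2/3)`, so `A ∝ V^(2/3)` and surface/volume
  vanishes in large cells. This is required for the documented asymptotics:
  lipid-membrane compositions approach the doubling time of the same
  composition without membranes as the cell grows, and membrane-protein
  compositions always hit a finite boundary (their area demand grows like
  `V` against a supply growing like `V^(2/3)`).
* **fixed_radius.** Radius constant, cylinder length varying, spherical
  fallback below the minimal spherocylinder volume; `A(V)` is continuous at
  the switch and asymptotically linear. Kept as an alternative because it
  is the natural convention when rod width is treated as conserved; under
  it the large-cell asymptote includes a residual lipid term and the
  asymptotic equalities above do not hold.

Default γ = 3 (a typical rod; e.g. 2.4 µm long at 0.4 µm radius).

## The ten models and their grouping

Group 1 (flat `t_d(N_rs)`, no size limit): bare replicator; + amino-acid
pathway; + RNA machinery. Group 2 (hockey-stick, size-limited): the
unspecified-protein pool (limit still molecular — the pool is a free input,
so no intrinsic size bound is reported); lipid membranes (bounded only by
the vanishing relative cost of the membrane, see "asymptotic maxima");
DNA (same, via the fixed genome); membrane proteins (hard boundary at
membrane exhaustion, for the membrane-protein model and both complete
systems). Models are declarative `ModelSpec` records and the compiler is
shared, so user-defined combinations (e.g. the test fixtures) are
first-class.

## Solver

At fixed `(t_d, V)` every balance is **linear in the counts** (the mRNA
share rule included), so the solver assembles one dense system (≤ 14
unknowns) and solves it directly. Membrane models close the volume with a
scalar fixed point `V = M_tot(counts(V)) / ρ`, bracketed by geometric
expansion from 10⁻¹² µm³ and solved with Brent's method at relative
tolerance 10⁻¹⁵. Driving a size-pinned model by `N_rs` instead of `t_d`
inverts the monotone map `t_d ↦ N_rs` with an outer Brent root; the bracket
walk keeps only states with positive ribosome counts and bisects back up
when a step lands below the flat stoichiometric floor (where the algebraic
continuation turns unphysical). This bracket policy is what selects the
physical branch; no initial guesses or variable transforms are needed, and
the computation is deterministic to the bit.

Growth boundaries are roots of `N_lip(t_d) = 0` (the solver continues
smoothly into the negative-lipid branch, so the boundary is a clean sign
change), bisected to 10⁻⁶ s. Solutions are verified against every compiled
balance residual at 10⁻⁸ relative before being returned; infeasible states
(negative lipid area, replication above the replisome cap) are returned
with `feasible=False` and explicit reasons — sweeps record them and
continue, since infeasibility near a boundary is itself the result.

**Degenerate inputs.** Zero pathway length or zero demand gives zero
enzymes; an empty protein pool reduces the pool model to the pathway model
exactly; zero volume is rejected; a singular count system (possible only
for drivers outside a model's options) raises with the equation census.

## Parameters

Units are fixed package-wide: seconds, molecules/cell, Da, nm² (footprints),
µm/µm³ (cell dimensions), grams (cell mass). Counts and pathway lengths are
continuous — the framework is stoichiometric, not discrete.

Values that are well established for E. coli K-12 are fixed inputs and
labeled by conformance (`specific`, `approximate`, `average`, `generic`):
ribosome rate 20.26 aa/s, RNA-polymerase rate 50 nt/s and complex size
3498 aa, assembled rRNA 4566 nt (5S+16S+23S at 1:1:1), tRNA 76 nt, genome
9,283,304 dnt (4,641,652 bp, both strands), replisome 10,000 aa, generic
enzyme 300 aa at 100 reactions/s, lipid 750 Da at 0.6 nm²/leaflet, water
70 % of `M_tot`, density 1.1 g/cm³, mean polymerized monomer masses
110/324/308 Da (aa/nt/dnt), tRNA:ribosome 8, mRNA:ribosome 0.2, ATP costs
4.3/aa and 2.3/nt polymerized, 7/lipid, 1/transport event, 0.02/pathway
reaction, 26 ATP per substrate oxidized, ETC at 300 ATP/s. The replisome
cap is set at a non-binding 6000 nt/s (`generic`): the published boundary
points imply per-replisome rates up to ~5000 nt/s for a single genome with
one replisome pair, so the cap is reported but must not bind canonically;
the feasibility machinery is exercised by the genome fixture with a binding
cap.

The remaining inputs cannot be fixed from molecular data alone and are
**calibrated** against the published doubling-time anchors, in a staged,
deterministic back-fit (`scripts/fit_canonical.py`): the RPC amino-acid
content from the bare-replicator time (362.10 s × 20.26 aa/s = 7336.146 aa);
PW2 length from the amino-acid-pathway time (600 s / 3 s per reaction =
200); PW4 length from the RNA-composition time; the lipid-synthesis rate
from the lipid-model worked point; PW1 length and the ETC footprint from
the membrane-protein boundary; the dNTP polymerization cost and PW3 length
from the minimal-medium anchors (least squares — with the replisome
composition held realistic only two independent knobs remain for three
anchors, leaving a 0.03 % residual on the minimal doubling time); the
monomer-transporter rate and footprint from the rich-medium boundary.
Calibrated entries are labeled `calibrated` in the canonical file. The
oversized pathway lengths (200–400 reactions vs. tens in real biosynthesis)
are a feature of this model family: a long generic pathway stands in for
the many unmodeled enzyme species a real cell devotes ribosome time to.

Two published worked points are mutually inconsistent under this balance
structure (the genome-only model's slow-growth ribosome count vs. the
complete minimal-medium system's); the calibration follows the
complete-system point, and the genome-only model then gives `N_rs ≈ 5.8`
(not 3.4) at `t_d = 10⁴ s` while reproducing its total mass (1.65 ×10⁻¹⁴ g)
within 1.5 %.

## Asymptotic maxima convention

For size-dependent models *without* membrane proteins the minimal doubling
time is an asymptote, so any finite "maximal size" encodes a tolerance
choice. The package reports the smallest `N_rs` whose doubling time is
within ε = 0.005 s (half the printed two-decimal precision) of the
asymptote, labels it `tolerance_defined`, and excludes it from comparison
tables — it is a documented convention, not a reproduction claim.

## Fixtures: what they emulate and what they do not

`toy_analytic`, `toy_membrane` and `toy_dna` are hand-sized parameter sets
whose solutions follow from a few lines of arithmetic or an independent
fine-grid scan; they exercise every balance archetype (including a binding
replisome cap and a membrane boundary cross-checked against a brute-force
oracle) without the canonical file. They emulate the *structure* of the
models, not realistic biology: passing tests on them demonstrates that the
algebra, the feasibility logic and the boundary search are correct, not
that any parameter value describes a living cell. Equally, the canonical
results describe idealized proto-cells — perfectly balanced, always-active
catalysts, average monomers, two compartments — and cannot be read as
predictions for real strains.

## Known limitations

* Stationary-state stoichiometry only; no mechanism for slow growth of
  large cells beyond the doubling balances.
* One metabolic type (simplified heterotrophy); membrane mechanics, osmotic
  effects and explicit metabolite pools are out of scope (intermediates are
  flux-balanced only).
* Calibrated parameters are anchor-consistent, not uniquely identified:
  other combinations could match the same anchors.
* The minimal-medium boundary retains a 0.03 % calibration residual (see
  above); all other anchors are matched to solver precision.
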