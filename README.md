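# protocell

Stoichiometric models of self-reproducing proto-cells: how fast can a
cellular subsystem copy itself, and what limits that speed?

Ribosomes are the only cell components that can (nearly) reproduce
themselves; everything else — enzymes, polymerases, RNA, the genome, the
membrane — must be duplicated *by* them within one doubling time. This
package implements a family of ten coarse-grained proto-cell models (from a
bare ribosomal protein complex up to complete self-reproduction systems on
minimal or rich media) as determined systems of algebraic balance equations,
solves them exactly, and extracts the doubling-time limits each composition
implies.

## Who this is for

Researchers in whole-cell modeling, minimal-cell/bottom-up cell design and
bacterial growth physiology who want a reproducible, parameter-explicit
implementation of ribosome-centric doubling-time limit calculations — and a
compiler for their own component combinations beyond the built-in ten.

## The model

Every biopolymer pool must double in one doubling time `t_d`; for each
polymer class with polymerase `pol`,

```
t_d = Σ_j N_j · n_j / (N_pol · k_pol)
```

where `N_j` is the per-cell count of component `j`, `n_j` its monomer
content, and `k_pol` the polymerase's apparent working rate (for protein,
the ribosome with `k_rs ≈ 20.26 aa/s`). Monomers come from linear pathways
PW1–PW5 whose per-step fluxes all equal the downstream demand, so enzyme
counts follow `N_enz = l_PW · J / k_enz`. Membrane-bound ETC complexes
produce exactly the ATP consumed; transporters import exactly the substrate
demanded. The cell is a spherocylinder: surface area is tiled by ETC,
transporters and a lipid bilayer, and volume follows from total mass through
the wet density.

Components stoichiometrically tied to the ribosome count `N_rs` (enzymes,
polymerases, RNA, membrane proteins) leave `t_d` independent of cell size
— flat lines, no size limit. Components that are *not* tied to `N_rs` (the
single genome with its replisome pair; membrane lipids, whose count is set
by the leftover surface area) make `t_d` rise steeply in small cells
(hockey-stick curves), and when membrane proteins compete for surface the
growth boundary is reached where the lipid area is exhausted: that point
defines the minimal `t_d` and the maximal `N_rs` of the composition.

For the simplest models the solution is closed-form; e.g. the bare
replicator gives `t_d = n_rpc / k_rs` and adding the amino-acid pathway adds
`n_enz · l_PW2 / k_enz`. Everything else is solved exactly: at fixed
`(t_d, V)` the balances are linear in the counts, the volume closes through
a scalar fixed point, and drivers are inverted with bracketed root finding.
No randomness anywhere; identical inputs give identical outputs.

Canonical parameters follow E. coli K-12 conventions where a well-known
value exists; the remaining inputs are calibrated against the published
doubling-time anchors and labeled `calibrated` (see `protocell params show`
and `docs/methods.md`).

## Worked example

```bash
protocell limits
```

prints one row per model (minimal doubling time, maximal ribosome count,
limit type, slower-growth factors):

```
sspcm-rs                     t_d_min=    362.10 s  N_rs_max=   unlimited  molecular_properties  [-]
sspcm-rs+aa                  t_d_min=    962.10 s  N_rs_max=   unlimited  molecular_properties  [-]
sspcm-rs+aa+rna              t_d_min=   1127.15 s  N_rs_max=   unlimited  molecular_properties  [-]
sspcm-rs+aa+rna+lip          t_d_min=   1127.15 s  N_rs_max=   2.418e+13  molecular_properties  [cell_geometry]
sspcm-rs+aa+rna+lip+mprot    t_d_min=   2462.68 s  N_rs_max=       36699  membrane_surface_area  [cell_geometry]
sspcm-srs-m                  t_d_min=   2474.89 s  N_rs_max=       36992  membrane_surface_area  [cell_geometry, dna_replication]
sspcm-srs-r                  t_d_min=    936.40 s  N_rs_max=       24681  membrane_surface_area  [cell_geometry, dna_replication]
...
```

Reading the table: a proto-cell of ribosomes alone doubles in 362.10 s at
any size; adding amino-acid synthesis costs another 600 s; adding RNA and
its machinery brings the floor to 1127.15 s. Lipid membranes and DNA leave
those floors untouched but bound the attainable size; membrane proteins
(ETC, transporters) both roughly double the floor *and* cap the cell at a
few ×10⁴ ribosomes, because they crowd lipids off the membrane. The
complete rich-medium system (no biosynthesis pathways, monomers imported)
grows 2.6× faster than the minimal-medium one — the model's version of
rich-media growth advantage. `unlimited` marks compositions with no size
bound; the finite maxima of the `molecular_properties` rows are
tolerance-convention reports (smallest size within 0.005 s of the flat
asymptote), not physical boundaries.

From Python:

```python
import protocell as pc

p = pc.canonical_parameters()
state = pc.solve("sspcm-srs-m", p, t_d=2500.0)
print(state.n_rs)                       # 14707.75 ribosomes/cell
print(state.m_tot_g)                    # 6.78e-13 g (E. coli scale)
print(state.mass_fractions["ribosomal"])  # 0.275 of dry mass
```

A minimal-medium proto-cell doubling in 2500 s carries ~1.5 ×10⁴ ribosomes,
weighs 0.68 pg with water, and spends 27.5 % of its dry mass on ribosomes.

`protocell sweep --model sspcm-srs-m --driver t_d_srs --grid 2480:10000:40:log
--out sweep.csv --plot fig.png` writes the hockey-stick curve and the
lipid-per-ribosome curve; `protocell reproduce-table1` prints the computed
limit table side by side with the published values and their deltas.

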