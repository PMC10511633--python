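schema_version: 1
source_note: Canonical parameter set. Molecular compositions and working rates follow
  E. coli K-12 conventions where a well-established value exists (provenance average/specific/precise/approximate);
  pathway lengths and the remaining membrane/energy constants are calibrated against
  the published doubling-time anchors (provenance calibrated).
species:
  rpc:
    role: self_replicator
    n_monomers: 7336.146000000001
    monomer_kind: aa
    k_rate: 20.26
    provenance: calibrated
  rp:
    role: polymerase
    n_monomers: 3498.0
    monomer_kind: aa
    k_rate: 50.0
    provenance: approximate
  rc:
    role: polymerase
    n_monomers: 10000.0
    monomer_kind: aa
    k_rate: 6000.0
    provenance: generic
  lpe:
    role: enzyme
    n_monomers: 300.0
    monomer_kind: aa
    k_rate: 1.6132969433612963
    provenance: calibrated
  enz:
    role: enzyme
    n_monomers: 300.0
    monomer_kind: aa
    k_rate: 100.0
    provenance: generic
  rrna:
    role: rna
    n_monomers: 4566.0
    monomer_kind: nt
    provenance: specific
  trna:
    role: rna
    n_monomers: 76.0
    monomer_kind: nt
    provenance: average
  lip:
    role: lipid
    mass_da: 750.0
    localization: membrane
    footprint_nm2: 0.6
    provenance: approximate
  etc:
    role: membrane_protein
    n_monomers: 10000.0
    monomer_kind: aa
    k_rate: 300.0
    localization: membrane
    footprint_nm2: 178.17390204698694
    provenance: calibrated
  tp:
    role: membrane_protein
    n_monomers: 1500.0
    monomer_kind: aa
    k_rate: 200.0
    localization: membrane
    footprint_nm2: 8.0
    provenance: generic
  mtp:
    role: membrane_protein
    n_monomers: 1500.0
    monomer_kind: aa
    k_rate: 7.48515396895521
    localization: membrane
    footprint_nm2: 20.717156701227285
    provenance: calibrated
  dna:
    role: genome
    n_monomers: 9283304.0
    monomer_kind: dnt
    provenance: specific
pathways:
  PW1:
    length_reactions: 248.01546939440033
    enzyme: enz
    product_monomer: metabolic_intermediate
    atp_per_reaction: 0.02
  PW2:
    length_reactions: 200.0
    enzyme: enz
    product_monomer: aa
    atp_per_reaction: 0.02
  PW3:
    length_reactions: 398.30106339331314
    enzyme: enz
    product_monomer: dnt
    atp_per_reaction: 0.02
  PW4:
    length_reactions: 162.93469324131294
    enzyme: enz
    product_monomer: nt
    atp_per_reaction: 0.02
  PW5:
    length_reactions: 20.0
    enzyme: enz
    product_monomer: lipid_precursor
    atp_per_reaction: 0.02
geometry:
  mode: fixed_shape
  aspect_ratio: 3.0
  radius_um: 0.4
  area_per_lipid_nm2: 0.6
  leaflets: 2
  water_mass_fraction: 0.7
  density_g_per_cm3: 1.1
energy:
  atp_per_aa_polymerized: 4.3
  atp_per_nt_polymerized: 2.3
  atp_per_dnt_polymerized: 7.404767898006703
  atp_per_lipid: 7.0
  atp_per_transport: 1.0
  etc_atp_rate: 300.0
  substrates_per_monomer: 1.0
  atp_per_substrate_oxidized: 26.0
couplings:
  trna_per_ribosome: 8.0
  mrna_per_ribosome: 0.2
  rrna_per_ribosome: 1.0
  rc_per_genome: 2.0
  genomes_per_cell: 1.0
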