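"""The ten proto-cell models and the shared equation-system compiler.

Models are data, not code: each simplified single-cell proto-cell model
(SSPCM) is a :class:`ModelSpec` naming the species, pathways and structural
flags it includes, and one shared compiler (:func:`build_model`) turns any
spec plus a parameter set into a determined system of balance equations.
User-defined component combinations beyond the published ten work the same
way (the toy fixtures used for testing are exactly that).

Model taxonomy
--------------
Components whose counts are stoichiometrically fixed to the ribosome count
(enzymes, polymerases, RNA, membrane proteins) leave the doubling time
independent of cell size; models made only of those have flat t_d(N_rs)
lines and no size limit.  Components that are *not* fixed to N_rs — the
single genome with its replisome pair, and the membrane lipids whose count
follows the surface area — introduce size dependence (the hockey-stick
curves) and, when membrane proteins compete for surface, a hard growth
boundary where the lipid area is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import balances as bal
from .balances import AssemblyError, BalanceEquation, SolutionState
from .geometry import area_um2
from .parameters import ParameterSet, validate_couplings


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one proto-cell model."""

    id: str
    description: str
    included_species: frozenset[str]
    included_pathways: frozenset[str]
    has_membrane: bool = False
    has_dna: bool = False
    has_energy: bool = False
    has_rna: bool = False
    medium: str = "n/a"  # minimal | rich | n/a
    driver_options: tuple[str, ...] = ("N_rs",)
    #: unspecified-protein pool, polymerized amino acids (rs+aa+prot only)
    n_aa_prot: float = 0.0

    def __post_init__(self) -> None:
        if "rpc" not in self.included_species:
            raise AssemblyError(f"{self.id}: every model contains the RPC/ribosome")
        if self.has_membrane != ("lip" in self.included_species):
            raise AssemblyError(f"{self.id}: has_membrane must match lipid inclusion")
        mprot = bool({"etc", "tp", "mtp"} & self.included_species)
        if self.has_energy != mprot:
            raise AssemblyError(
                f"{self.id}: has_energy must match membrane-protein inclusion"
            )

    @property
    def scale_free(self) -> bool:
        """True when nothing pins the absolute size (flat t_d vs N_rs)."""
        return not (self.has_membrane or self.has_dna or self.n_aa_prot > 0)


def _spec(**kw) -> ModelSpec:
    kw.setdefault("included_pathways", frozenset())
    kw["included_species"] = frozenset(kw["included_species"])
    kw["included_pathways"] = frozenset(kw["included_pathways"])
    return ModelSpec(**kw)


MODELS: dict[str, ModelSpec] = {
    m.id: m
    for m in [
        _spec(
            id="sspcm-rs",
            description="ribosomal protein complex only; the absolute minimal replicator",
            included_species={"rpc"},
        ),
        _spec(
            id="sspcm-rs+aa",
            description="RPC plus the amino-acid synthesis pathway PW2",
            included_species={"rpc", "enz"},
            included_pathways={"PW2"},
        ),
        _spec(
            id="sspcm-rs+aa+prot",
            description="RPC, PW2 and an unspecified protein pool",
            included_species={"rpc", "enz"},
            included_pathways={"PW2"},
            driver_options=("N_rs", "t_d_srs"),
            n_aa_prot=5.0e4,
        ),
        _spec(
            id="sspcm-rs+aa+rna",
            description="functional ribosomes, RNA polymerase, all RNA, PW2 and PW4",
            included_species={"rpc", "rp", "rrna", "trna", "enz"},
            included_pathways={"PW2", "PW4"},
            has_rna=True,
        ),
        _spec(
            id="sspcm-rs+aa+rna+lip",
            description="adds the lipid membrane: LPE, lipids and PW5",
            included_species={"rpc", "rp", "rrna", "trna", "enz", "lpe", "lip"},
            included_pathways={"PW2", "PW4", "PW5"},
            has_rna=True,
            has_membrane=True,
            driver_options=("t_d_srs", "N_rs"),
        ),
        _spec(
            id="sspcm-rs+lip",
            description="RPC, LPE and membrane lipids only",
            included_species={"rpc", "lpe", "lip"},
            has_membrane=True,
            driver_options=("t_d_srs", "N_rs"),
        ),
        _spec(
            id="sspcm-rs+aa+rna+lip+mprot",
            description="adds membrane proteins (ETC, transporter) and PW1",
            included_species={
                "rpc", "rp", "rrna", "trna", "enz", "lpe", "lip", "etc", "tp",
            },
            included_pathways={"PW1", "PW2", "PW4", "PW5"},
            has_rna=True,
            has_membrane=True,
            has_energy=True,
            medium="minimal",
            driver_options=("t_d_srs", "N_rs"),
        ),
        _spec(
            id="sspcm-srs-m",
            description="complete self-reproduction system on minimal medium",
            included_species={
                "rpc", "rp", "rc", "rrna", "trna", "enz", "lpe", "lip",
                "etc", "tp", "dna",
            },
            included_pathways={"PW1", "PW2", "PW3", "PW4", "PW5"},
            has_rna=True,
            has_membrane=True,
            has_energy=True,
            has_dna=True,
            medium="minimal",
            driver_options=("t_d_srs", "N_rs"),
        ),
        _spec(
            id="sspcm-rs+dna",
            description="RPC, replisome pair, genome and PW3",
            included_species={"rpc", "rc", "enz", "dna"},
            included_pathways={"PW3"},
            has_dna=True,
            driver_options=("t_d_srs", "N_rs"),
        ),
        _spec(
            id="sspcm-srs-r",
            description="complete self-reproduction system on rich medium "
            "(monomers imported, no biosynthesis pathways)",
            included_species={
                "rpc", "rp", "rc", "rrna", "trna", "lpe", "lip",
                "etc", "tp", "mtp", "dna",
            },
            has_rna=True,
            has_membrane=True,
            has_energy=True,
            has_dna=True,
            medium="rich",
            driver_options=("t_d_srs", "N_rs"),
        ),
    ]
}


def get_model_spec(model_id: str) -> ModelSpec:
    if isinstance(model_id, ModelSpec):
        return model_id
    if model_id not in MODELS:
        raise AssemblyError(
            f"unknown model {model_id!r}; valid ids: {sorted(MODELS)}"
        )
    return MODELS[model_id]


# ---------------------------------------------------------------------------
# equation system
# ---------------------------------------------------------------------------


@dataclass
class EquationSystem:
    """A compiled, determined system for one model at one driver setting."""

    model: ModelSpec
    params: ParameterSet
    driver: tuple[str, float]
    unknowns: list[str]
    equations: list[BalanceEquation]
    dna_feasibility: Optional[Callable[[SolutionState], tuple[float, bool]]] = None
    n_aa_prot: float = 0.0

    def residuals(self, state: SolutionState) -> dict[str, float]:
        return {eq.name: eq(state, self.params) for eq in self.equations}

    @property
    def provenance(self) -> dict[str, str]:
        return {eq.name: eq.provenance for eq in self.equations}


@dataclass(frozen=True)
class DofReport:
    model_id: str
    n_unknowns: int
    n_equations: int
    driver: str
    determined: bool
    unknowns: tuple[str, ...]
    equations: tuple[str, ...]


def degrees_of_freedom_report(system: EquationSystem) -> DofReport:
    """Census of unknowns vs equations after fixing the driver."""
    return DofReport(
        model_id=system.model.id,
        n_unknowns=len(system.unknowns),
        n_equations=len(system.equations),
        driver=system.driver[0],
        determined=len(system.unknowns) == len(system.equations),
        unknowns=tuple(system.unknowns),
        equations=tuple(eq.name for eq in system.equations),
    )


def _protein_species(spec: ModelSpec) -> list[str]:
    """Protein species with counts among the unknowns, in canonical order."""
    order = ["rpc", "rp", "lpe", "etc", "tp", "mtp"]
    return [s for s in order if s in spec.included_species]


def build_model(
    model_id: str | ModelSpec,
    params: ParameterSet,
    driver: tuple[str, float],
    n_aa_prot: Optional[float] = None,
) -> EquationSystem:
    """Compile a model into its determined balance-equation system.

    ``driver`` is (name, value) with name in the model's driver options;
    fixing it makes the system square (checked by the census).
    """
    spec = get_model_spec(model_id)
    failures = [c for c in validate_couplings(params, spec) if not c.passed]
    if failures:
        raise AssemblyError(
            f"{spec.id}: missing dependencies: "
            + "; ".join(c.message for c in failures)
        )
    if driver[0] not in spec.driver_options:
        raise AssemblyError(
            f"{spec.id}: driver {driver[0]!r} not in {spec.driver_options}"
        )
    pool = spec.n_aa_prot if n_aa_prot is None else n_aa_prot

    sp = params.species
    eqs: list[BalanceEquation] = []
    unknowns: list[str] = []

    def unk(name: str) -> None:
        unknowns.append(name)

    if driver[0] == "N_rs":
        unk("t_d_srs")
    else:
        unk("n:rpc")

    # protein doubling (ribosome as polymerase), Eq.-(4) archetype
    members: list[tuple[str, float | None]] = [
        (s, sp[s].n_monomers) for s in _protein_species(spec)
    ]
    for pw in sorted(spec.included_pathways):
        members.append((f"enz_{pw}", sp[params.pathways[pw].enzyme].n_monomers))
        unk(f"n:enz_{pw}")
    if spec.has_dna:
        members.append(("rc", sp["rc"].n_monomers))
    if pool > 0:
        members.append(("aa_prot", 1.0))
    eqs.append(
        bal.polymer_doubling_balance("protein", members, "rpc", sp["rpc"].k_rate)
    )
    for s in _protein_species(spec):
        if s != "rpc":
            unk(f"n:{s}")

    if spec.has_rna:
        tau = params.coupling("trna_per_ribosome")
        rna_members: list[tuple[str, float | None]] = [
            ("rrna", sp["rrna"].n_monomers),
            ("trna", sp["trna"].n_monomers),
            ("mrna_nt", None),
        ]
        eqs.append(
            bal.polymer_doubling_balance("rna", rna_members, "rp", sp["rp"].k_rate)
        )
        eqs.append(bal.coupling_balance("trna", "trna", tau))
        eqs.append(_mrna_coupling(spec, params, pool))
        unk("n:trna")
        unk("n:mrna_nt")

    for pw_id in sorted(spec.included_pathways):
        pw = params.pathways[pw_id]
        eqs.extend(
            bal.pathway_flux_balance(
                pw_id,
                f"enz_{pw_id}",
                pw.length_reactions,
                sp[pw.enzyme].k_rate,
                _pathway_demand(pw_id, spec, params),
            )
        )

    dna_feas = None
    if spec.has_dna:
        n_dna_total = params.coupling("genomes_per_cell") * sp["dna"].n_monomers
        rc_count = params.coupling("rc_per_genome") * params.coupling(
            "genomes_per_cell"
        )
        eq, dna_feas = bal.dna_replication_balance(
            n_dna_total, rc_count, sp["rc"].k_rate
        )
        eqs.append(eq)
        unk("flux:replication_dnt")

    if spec.has_membrane:
        if params.geometry is None:
            raise AssemblyError(f"{spec.id}: geometry parameters required")
        eqs.append(
            bal.polymer_doubling_balance(
                "lipid", [("lip", 1.0)], "lpe", sp["lpe"].k_rate
            )
        )
        footprints = {
            s: sp[s].footprint_nm2
            for s in spec.included_species
            if sp[s].footprint_nm2 is not None and s != "lip"
        }
        eqs.append(
            bal.membrane_area_balance(footprints, params.geometry.area_per_lipid_nm2)
        )
        eqs.append(_shape_equation())
        unk("n:lip")
        unk("area_um2")
        unk("volume_um3")

    if spec.has_energy:
        if params.energy is None:
            raise AssemblyError(f"{spec.id}: energy parameters required")
        eqs.extend(_energy_equations(spec, params))

    eqs.extend(bal.mass_volume_balance(lambda s: component_masses_da(s, params)))
    # the volume equation is only active for membrane models
    if not spec.has_membrane:
        eqs = [e for e in eqs if e.name != "mass:volume"]
    unk("dry_mass_g")
    unk("m_tot_g")

    system = EquationSystem(
        model=spec, params=params, driver=tuple(driver), unknowns=unknowns,
        equations=eqs, dna_feasibility=dna_feas, n_aa_prot=pool,
    )
    report = degrees_of_freedom_report(system)
    if not report.determined:
        raise AssemblyError(
            f"{spec.id}: system not determined: {report.n_unknowns} unknowns "
            f"vs {report.n_equations} equations\nunknowns: {report.unknowns}"
            f"\nequations: {report.equations}"
        )
    return system


def _shape_equation() -> BalanceEquation:
    def residual(state: SolutionState, params: ParameterSet) -> float:
        if state.volume_um3 is None or state.area_um2 is None:
            return 0.0
        return state.area_um2 - area_um2(state.volume_um3, params.geometry)

    return BalanceEquation(
        "geometry:shape", "area", residual,
        provenance="surface area follows the spherocylinder shape at the cell volume",
    )


def _mrna_coupling(
    spec: ModelSpec, params: ParameterSet, pool: float
) -> BalanceEquation:
    """Total mRNA nucleotides from per-species translation shares.

    Each protein species j holds mRNA copies proportional to its share of
    translation (N_j n_j / sum N n), normalized so that the total mRNA
    count is mrna_per_ribosome * N_rs; coding regions are 3 nt per codon.
    The resulting nucleotide total is 3 * mu * sum(N_j n_j^2) / (t k_rs).
    """
    mu = params.coupling("mrna_per_ribosome")
    sp = params.species

    def residual(state: SolutionState, p: ParameterSet) -> float:
        ssq = 0.0
        for s in _protein_species(spec):
            ssq += state.counts.get(s, 0.0) * sp[s].n_monomers ** 2
        for pw in spec.included_pathways:
            n_enz = sp[params.pathways[pw].enzyme].n_monomers
            ssq += state.counts.get(f"enz_{pw}", 0.0) * n_enz**2
        if spec.has_dna:
            rc_count = p.coupling("rc_per_genome") * p.coupling("genomes_per_cell")
            ssq += rc_count * sp["rc"].n_monomers ** 2
        expected = 3.0 * mu * ssq / (state.t_d_srs * sp["rpc"].k_rate)
        return state.counts.get("mrna_nt", 0.0) - expected

    return BalanceEquation(
        "coupling:mrna", "coupling", residual,
        provenance="mRNA copies follow translation shares, "
        "normalized per ribosome",
    )


def _pathway_demand(
    pw_id: str, spec: ModelSpec, params: ParameterSet
) -> Callable[[SolutionState], float]:
    """Downstream consumption flux that a pathway must match."""
    sp = params.species

    def translation(state: SolutionState) -> float:
        return state.counts["rpc"] * sp["rpc"].k_rate

    def transcription(state: SolutionState) -> float:
        return state.counts.get("rp", 0.0) * sp["rp"].k_rate

    def replication(state: SolutionState) -> float:
        return state.fluxes.get("replication_dnt", 0.0)

    def lipid(state: SolutionState) -> float:
        return state.counts.get("lip", 0.0) / state.t_d_srs

    if pw_id == "PW2":
        return translation
    if pw_id == "PW4":
        return transcription
    if pw_id == "PW3":
        return replication
    if pw_id == "PW5":
        return lipid
    if pw_id == "PW1":
        s1 = (
            params.energy.substrates_per_monomer
            if params.energy is not None
            else 1.0
        )

        def central(state: SolutionState) -> float:
            return s1 * (
                translation(state)
                + transcription(state)
                + replication(state)
                + lipid(state)
            )

        return central
    raise AssemblyError(f"unknown pathway {pw_id!r}")


def _energy_equations(spec: ModelSpec, params: ParameterSet) -> list[BalanceEquation]:
    e = params.energy
    sp = params.species

    def atp_consumption(state: SolutionState) -> float:
        f = state.fluxes
        atp = e.atp_per_aa_polymerized * f.get("translation_aa", 0.0)
        atp += e.atp_per_nt_polymerized * f.get("transcription_nt", 0.0)
        atp += e.atp_per_dnt_polymerized * f.get("replication_dnt", 0.0)
        atp += e.atp_per_lipid * f.get("lipid_synthesis", 0.0)
        for pw_id in spec.included_pathways:
            pw = params.pathways[pw_id]
            atp += pw.atp_per_reaction * pw.length_reactions * f.get(
                f"flux_{pw_id}", 0.0
            )
        atp += e.atp_per_transport * (
            f.get("substrate_import", 0.0) + f.get("monomer_import", 0.0)
        )
        return atp

    def energy_substrate(state: SolutionState) -> float:
        return (
            state.counts.get("etc", 0.0)
            * e.etc_atp_rate
            / e.atp_per_substrate_oxidized
        )

    eqs: list[BalanceEquation] = []
    if spec.medium == "rich":

        def monomer_demand(state: SolutionState) -> float:
            f = state.fluxes
            return (
                f.get("translation_aa", 0.0)
                + f.get("transcription_nt", 0.0)
                + f.get("replication_dnt", 0.0)
                + f.get("lipid_synthesis", 0.0)
            )

        eqs.extend(
            bal.energy_and_transport_balance(
                atp_consumption, energy_substrate, e.etc_atp_rate,
                "tp", sp["tp"].k_rate,
            )
        )
        # second transporter class: monomers from the rich medium
        def mtp_residual(state: SolutionState, p: ParameterSet) -> float:
            return state.counts.get("mtp", 0.0) * sp["mtp"].k_rate - monomer_demand(
                state
            )

        eqs.append(
            BalanceEquation(
                "transport:mtp", "transport", mtp_residual,
                provenance="monomer transporters sized to total monomer demand",
            )
        )
    else:

        def substrate_demand(state: SolutionState) -> float:
            return state.fluxes.get("flux_PW1", 0.0) + energy_substrate(state)

        eqs.extend(
            bal.energy_and_transport_balance(
                atp_consumption, substrate_demand, e.etc_atp_rate,
                "tp", sp["tp"].k_rate,
            )
        )
    return eqs


def component_masses_da(state: SolutionState, params: ParameterSet) -> dict[str, float]:
    """Dry-mass contributions (Da) per component, from a state's counts."""
    masses: dict[str, float] = {}
    aa = params.monomer_mass_da["aa"]
    nt = params.monomer_mass_da["nt"]
    for sid, count in state.counts.items():
        if sid == "mrna_nt":
            masses["mrna"] = count * nt
        elif sid == "aa_prot":
            masses["aa_prot"] = count * aa
        elif sid.startswith("enz_"):
            pw = sid.removeprefix("enz_")
            enzyme = params.pathways[pw].enzyme
            masses[sid] = count * params.species_mass_da(enzyme)
        else:
            masses[sid] = count * params.species_mass_da(sid)
    return masses


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

_ANALYTIC_MODELS = (
    "sspcm-rs",
    "sspcm-rs+aa",
    "sspcm-rs+aa+prot",
    "sspcm-rs+aa+rna",
)


def closed_form_doubling_time(
    model_id: str,
    params: ParameterSet,
    n_rs: Optional[float] = None,
    n_aa_prot: Optional[float] = None,
) -> Optional[float]:
    """Analytic doubling time where one exists, else None.

    Available for the four flat-line models.  The bare-replicator value is
    n_rpc/k_rs; adding PW2 adds the pathway time coefficient n_enz*l/k_enz;
    the unspecified-protein pool adds N_aa_prot/(N_rs*k_rs); the RNA model
    reduces to a cubic polynomial in t_d whose unique physical root is
    returned.
    """
    spec = get_model_spec(model_id)
    if spec.id not in _ANALYTIC_MODELS:
        return None
    sp = params.species
    k_rs = sp["rpc"].k_rate
    t_rs = sp["rpc"].n_monomers / k_rs
    if spec.id == "sspcm-rs":
        return t_rs
    pw2 = params.pathways["PW2"]
    enz = sp[pw2.enzyme]
    t_rs_aa = t_rs + enz.n_monomers * pw2.length_reactions / enz.k_rate
    if spec.id == "sspcm-rs+aa":
        return t_rs_aa
    if spec.id == "sspcm-rs+aa+prot":
        pool = spec.n_aa_prot if n_aa_prot is None else n_aa_prot
        if pool == 0:
            return t_rs_aa
        if n_rs is None:
            raise ValueError("sspcm-rs+aa+prot needs N_rs for its closed form")
        return t_rs_aa + pool / (n_rs * k_rs)
    return _rna_model_closed_form(params)


def _rna_model_closed_form(params: ParameterSet) -> float:
    """Unique physical root of the cubic for sspcm-rs+aa+rna.

    Eliminating the RNA-polymerase ratio x = N_rp/N_rs and the mRNA
    nucleotide total from the protein-doubling, RNA-doubling and mRNA-share
    equations leaves a cubic in t_d; the physical branch is the real root
    with x > 0, i.e. t_d > (n_rpc + PW2 enzymes)/k_rs.
    """
    sp = params.species
    k_rs = sp["rpc"].k_rate
    k_rp = sp["rp"].k_rate
    pw2, pw4 = params.pathways["PW2"], params.pathways["PW4"]
    enz2, enz4 = sp[pw2.enzyme], sp[pw4.enzyme]
    n_rpc, n_rp = sp["rpc"].n_monomers, sp["rp"].n_monomers
    tau = params.coupling("trna_per_ribosome")
    mu = params.coupling("mrna_per_ribosome")

    a2 = pw2.length_reactions * k_rs / enz2.k_rate  # PW2 enzymes per ribosome
    b4 = pw4.length_reactions * k_rp / enz4.k_rate  # PW4 enzymes per unit x
    c0 = n_rpc + a2 * enz2.n_monomers
    c1 = n_rp + b4 * enz4.n_monomers
    d0 = n_rpc**2 + a2 * enz2.n_monomers**2
    d1 = n_rp**2 + b4 * enz4.n_monomers**2
    r0 = sp["rrna"].n_monomers + tau * sp["trna"].n_monomers

    coeffs = [
        k_rp * k_rs**2,
        -k_rp * k_rs * c0,
        -k_rs * (c1 * r0 + 3.0 * mu * d1),
        -3.0 * mu * (c1 * d0 - c0 * d1),
    ]
    roots = np.roots(coeffs)
    physical = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and r.real * k_rs > c0
    ]
    if len(physical) != 1:
        raise AssemblyError(
            f"expected one physical root of the RNA-model cubic, got {physical}"
        )
    return physical[0]


def pw2_length_for_doubling_time(t_target: float, params: ParameterSet) -> float:
    """Pathway length l_PW2 that yields a given sspcm-rs+aa doubling time."""
    sp = params.species
    t_rs = sp["rpc"].n_monomers / sp["rpc"].k_rate
    pw2 = params.pathways["PW2"]
    enz = sp[pw2.enzyme]
    return (t_target - t_rs) * enz.k_rate / enz.n_monomers


def pw2_enzyme_count(n_rs: float, length_reactions: float, params: ParameterSet) -> float:
    """PW2 enzyme total at a given ribosome count and pathway length."""
    sp = params.species
    pw2 = params.pathways["PW2"]
    return length_reactions * n_rs * sp["rpc"].k_rate / sp[pw2.enzyme].k_rate
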