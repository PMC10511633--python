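"""Balance residuals and the solution container.

Every model is a determined algebraic system built from a handful of
balance archetypes:

* polymer doubling  — every biopolymer pool is synthesized once over the
  doubling time by its polymerase:  t_d = sum(N_j * n_j) / (N_pol * k_pol)
* pathway flux      — each linear pathway carries one flux; per-step enzyme
  counts equal demand / k_enz, totals equal length x per-step count
* DNA replication   — one genome copy per doubling; the required per-
  replisome rate must not exceed the replisome working-rate cap
* energy            — ETC ATP production equals total ATP consumption
* transport         — imported substrate/monomers equal total demand
* membrane area     — component footprints tile the geometric surface,
  lipids filling whatever the membrane proteins leave
* mass/volume       — dry mass sums component masses; total mass adds
  water; volume converts mass through the wet density

The residual functions here recompute each balance by direct arithmetic
over a :class:`SolutionState`; they are used to verify solver output and
to document the provenance of each equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .geometry import ShapeRecord
from .parameters import ParameterSet
from .units import GRAMS_PER_DALTON, NM2_PER_UM2


@dataclass
class SolutionState:
    """All output cell parameters at one operating point.

    ``counts`` maps species ids to molecules cell^-1 and additionally holds
    ``mrna_nt`` (total mRNA nucleotides) and, where applicable, ``aa_prot``
    (polymerized amino acids of the unspecified-protein pool).  ``fluxes``
    are events s^-1 cell^-1 keyed by process name.
    """

    model_id: str
    t_d_srs: float
    counts: dict[str, float]
    fluxes: dict[str, float]
    driver: tuple[str, float] | None = None
    dry_mass_g: float = 0.0
    m_tot_g: float = 0.0
    volume_um3: Optional[float] = None
    area_um2: Optional[float] = None
    lipid_area_um2: Optional[float] = None
    shape: Optional[ShapeRecord] = None
    mass_fractions: dict[str, float] = field(default_factory=dict)
    feasible: bool = True
    infeasibility: list[str] = field(default_factory=list)

    @property
    def n_rs(self) -> float:
        return self.counts["rpc"]

    @property
    def lip_per_rs(self) -> Optional[float]:
        if "lip" not in self.counts:
            return None
        return self.counts["lip"] / self.counts["rpc"]

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "t_d_srs": self.t_d_srs,
            "driver": list(self.driver) if self.driver else None,
            "counts": dict(self.counts),
            "fluxes": dict(self.fluxes),
            "dry_mass_g": self.dry_mass_g,
            "m_tot_g": self.m_tot_g,
            "volume_um3": self.volume_um3,
            "area_um2": self.area_um2,
            "lipid_area_um2": self.lipid_area_um2,
            "mass_fractions": dict(self.mass_fractions),
            "lip_per_rs": self.lip_per_rs,
            "feasible": self.feasible,
            "infeasibility": list(self.infeasibility),
        }
        return d


Residual = Callable[[SolutionState, ParameterSet], float]


@dataclass(frozen=True)
class BalanceEquation:
    """A named residual that must vanish at any valid solution."""

    name: str
    kind: str  # polymer_doubling | flux_balance | replication | energy |
    #          transport | area | mass_volume | coupling
    residual: Residual
    provenance: str = ""

    def __call__(self, state: SolutionState, params: ParameterSet) -> float:
        return self.residual(state, params)


class AssemblyError(ValueError):
    """A model cannot be assembled from the given parameters."""


# ---------------------------------------------------------------------------
# balance builders
# ---------------------------------------------------------------------------


def _count(state: SolutionState, sid: str) -> float:
    return state.counts.get(sid, 0.0)


def polymer_doubling_balance(
    polymer_class: str,
    members: Sequence[tuple[str, float | None]],
    polymerase: str,
    polymerase_rate: float,
) -> BalanceEquation:
    """Doubling balance for one polymer class.

    ``members`` lists (count key, monomers per molecule); a monomer count
    of ``None`` means the count entry is already in monomers (the mRNA
    nucleotide total).  Residual: t_d - sum(N*n) / (N_pol * k_pol).
    """
    if not members:
        raise AssemblyError(f"{polymer_class}: polymer class has no members")
    if polymerase_rate <= 0:
        raise AssemblyError(f"{polymer_class}: polymerase {polymerase!r} not catalytic")

    def residual(state: SolutionState, params: ParameterSet) -> float:
        total = 0.0
        for key, n in members:
            total += _count(state, key) * (1.0 if n is None else n)
        n_pol = _count(state, polymerase)
        return state.t_d_srs - total / (n_pol * polymerase_rate)

    return BalanceEquation(
        name=f"doubling:{polymer_class}",
        kind="polymer_doubling",
        residual=residual,
        provenance=f"doubling of all {polymer_class} by {polymerase}",
    )


def pathway_flux_balance(
    pathway_id: str,
    enzyme_count_key: str,
    length_reactions: float,
    k_enz: float,
    demand_flux: Callable[[SolutionState], float],
) -> list[BalanceEquation]:
    """Flux balance of a linear pathway and its enzyme-count coupling.

    All steps of the chain carry the same flux (the downstream demand) and
    the per-step enzyme count is demand / k_enz, so the pathway total is
    length * demand / k_enz.
    """
    if k_enz <= 0:
        raise AssemblyError(f"{pathway_id}: enzyme working rate must be positive")

    def residual(state: SolutionState, params: ParameterSet) -> float:
        demand = demand_flux(state)
        return _count(state, enzyme_count_key) * k_enz - length_reactions * demand

    return [
        BalanceEquation(
            name=f"flux:{pathway_id}",
            kind="flux_balance",
            residual=residual,
            provenance=f"{pathway_id} per-step fluxes equal; enzymes sized to demand",
        )
    ]


def dna_replication_balance(
    n_dna_total: float, rc_count: float, k_rc: float
) -> tuple[BalanceEquation, Callable[[SolutionState], tuple[float, bool]]]:
    """Replication flux balance plus the replisome-rate feasibility check.

    One genome copy (both strands, ``n_dna_total`` deoxyribonucleotides) is
    made per doubling, so the dNTP demand flux is n_dna / t_d.  The check
    returns (required per-replisome rate, feasible?) where feasibility
    means the required rate does not exceed the replisome cap k_rc.
    """

    def residual(state: SolutionState, params: ParameterSet) -> float:
        return state.fluxes.get("replication_dnt", 0.0) - n_dna_total / state.t_d_srs

    def feasibility(state: SolutionState) -> tuple[float, bool]:
        required = n_dna_total / (rc_count * state.t_d_srs)
        return required, required <= k_rc * (1 + 1e-12)

    eq = BalanceEquation(
        name="replication:dna",
        kind="replication",
        residual=residual,
        provenance="single genome copied once per doubling by the replisome pair",
    )
    return eq, feasibility


def energy_and_transport_balance(
    atp_consumption: Callable[[SolutionState], float],
    import_demand: Callable[[SolutionState], float],
    etc_rate: float,
    transporter_key: str,
    transporter_rate: float,
) -> list[BalanceEquation]:
    """ETC production = ATP consumption; transporter import = demand."""

    def energy_residual(state: SolutionState, params: ParameterSet) -> float:
        return _count(state, "etc") * etc_rate - atp_consumption(state)

    def transport_residual(state: SolutionState, params: ParameterSet) -> float:
        return _count(state, transporter_key) * transporter_rate - import_demand(state)

    return [
        BalanceEquation(
            "energy:atp", "energy", energy_residual,
            provenance="membrane ETC produces exactly the ATP consumed",
        ),
        BalanceEquation(
            f"transport:{transporter_key}", "transport", transport_residual,
            provenance="membrane transporter imports exactly the demand",
        ),
    ]


def membrane_area_balance(
    footprints: Mapping[str, float], area_per_lipid_nm2: float
) -> BalanceEquation:
    """Footprints of membrane components tile the geometric surface.

    Lipids form two leaflets of equal area, so a bilayer patch of area a
    holds 2a / area_per_lipid molecules; membrane proteins span the bilayer
    and are counted once.
    """

    def residual(state: SolutionState, params: ParameterSet) -> float:
        area_nm2 = (state.area_um2 or 0.0) * NM2_PER_UM2
        used = _count(state, "lip") * area_per_lipid_nm2 / 2.0
        for sid, a in footprints.items():
            used += _count(state, sid) * a
        return area_nm2 - used

    return BalanceEquation(
        "area:membrane", "area", residual,
        provenance="cell surface = sum of membrane component surface areas",
    )


def mass_volume_balance(
    component_masses_da: Callable[[SolutionState], dict[str, float]],
) -> list[BalanceEquation]:
    """Dry-mass summation, water bookkeeping and mass-to-volume conversion."""

    def dry_residual(state: SolutionState, params: ParameterSet) -> float:
        dry = sum(component_masses_da(state).values()) * GRAMS_PER_DALTON
        return state.dry_mass_g - dry

    def mtot_residual(state: SolutionState, params: ParameterSet) -> float:
        w = params.geometry.water_mass_fraction if params.geometry else 0.0
        return state.m_tot_g - state.dry_mass_g / (1.0 - w)

    def volume_residual(state: SolutionState, params: ParameterSet) -> float:
        if state.volume_um3 is None or params.geometry is None:
            return 0.0
        from .units import UM3_PER_CM3

        return state.volume_um3 - (
            state.m_tot_g / params.geometry.density_g_per_cm3 * UM3_PER_CM3
        )

    return [
        BalanceEquation("mass:dry", "mass_volume", dry_residual,
                        provenance="dry mass is the sum of component masses"),
        BalanceEquation("mass:total", "mass_volume", mtot_residual,
                        provenance="total mass includes cell water"),
        BalanceEquation("mass:volume", "mass_volume", volume_residual,
                        provenance="volume from total mass via wet density"),
    ]


def coupling_balance(
    name: str, count_key: str, per_rs: float
) -> BalanceEquation:
    """A component count stoichiometrically fixed to the ribosome count."""

    def residual(state: SolutionState, params: ParameterSet) -> float:
        return _count(state, count_key) - per_rs * _count(state, "rpc")

    return BalanceEquation(
        f"coupling:{name}", "coupling", residual,
        provenance=f"{count_key} fixed to N_rs at {per_rs} per ribosome",
    )
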