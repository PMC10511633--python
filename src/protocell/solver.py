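"""Deterministic solver for compiled proto-cell models.

Strategy
--------
Every model becomes *linear in the component counts* once the doubling time
t_d and (for membrane models) the cell volume V are held fixed: doubling
balances, pathway couplings, mRNA shares, energy and transport balances are
all linear forms in the counts.  The solver exploits this:

1. given (t_d, V) solve one small dense linear system for all counts;
2. membrane models close V through a scalar fixed point
   V = M_tot(counts(V)) / density, bracketed and solved with Brent's
   method;
3. a driver value for the non-natural variable (N_rs for size-pinned
   models, t_d never for scale-free ones) is inverted by an outer Brent
   root on the monotone map t_d -> N_rs.

There is no randomness anywhere: brackets grow geometrically from fixed
starting points and identical inputs give identical outputs.  Solutions are
verified against every compiled balance residual before being returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .balances import SolutionState
from .geometry import area_um2, cell_dimensions
from .models import (
    EquationSystem,
    ModelSpec,
    build_model,
    component_masses_da,
    get_model_spec,
)
from .parameters import ParameterSet
from .units import GRAMS_PER_DALTON, NM2_PER_UM2, UM3_PER_CM3

logger = logging.getLogger(__name__)

#: relative tolerance for verifying balance residuals of returned solutions
RESIDUAL_RTOL = 1e-8

#: negative-count slack (relative to the largest count) treated as zero
_NEG_TOL = 1e-9


class SolverError(RuntimeError):
    """No positive solution found; carries diagnostic context."""


class _LinearForm:
    """A linear expression c . x + b over the active count unknowns."""

    __slots__ = ("coeffs", "const")

    def __init__(self, coeffs: Optional[dict[str, float]] = None, const: float = 0.0):
        self.coeffs = dict(coeffs or {})
        self.const = const

    def add(self, other: "_LinearForm", scale: float = 1.0) -> "_LinearForm":
        for k, v in other.coeffs.items():
            self.coeffs[k] = self.coeffs.get(k, 0.0) + scale * v
        self.const += scale * other.const
        return self

    def value(self, sol: dict[str, float]) -> float:
        return self.const + sum(c * sol[k] for k, c in self.coeffs.items())


@dataclass
class _Assembled:
    """Rows of the count-linear system at fixed (t_d, area)."""

    variables: list[str]
    rows: list[tuple[str, dict[str, float], float]]  # (name, coeffs, rhs)
    fluxes: dict[str, _LinearForm]
    protein_row: Optional[tuple[dict[str, float], float]] = None  # scale-free only


class _ModelSolver:
    """Shared machinery binding one ModelSpec to one ParameterSet."""

    def __init__(self, spec: ModelSpec, params: ParameterSet, pool: float):
        self.spec = spec
        self.params = params
        self.pool = pool
        sp = params.species
        self.k_rs = sp["rpc"].k_rate
        self.n_rpc = sp["rpc"].n_monomers
        self.has_dna = spec.has_dna
        if spec.has_dna:
            self.n_dna_total = params.coupling("genomes_per_cell") * sp["dna"].n_monomers
            self.rc_count = params.coupling("rc_per_genome") * params.coupling(
                "genomes_per_cell"
            )
            self.n_rc = sp["rc"].n_monomers
        else:
            self.n_dna_total = 0.0
            self.rc_count = 0.0
            self.n_rc = 0.0

    # -- assembly ----------------------------------------------------------

    def _protein_vars(self) -> list[str]:
        order = ["rp", "lpe", "etc", "tp", "mtp"]
        out = [s for s in order if s in self.spec.included_species]
        out += [f"enz_{pw}" for pw in sorted(self.spec.included_pathways)]
        return out

    def assemble(
        self,
        t: float,
        area_nm2: Optional[float],
        n_rs_fixed: Optional[float],
    ) -> _Assembled:
        """Build the linear system in counts at fixed t (and area).

        With ``n_rs_fixed`` given (scale-free models) the ribosome count is
        a constant and the protein-doubling equation becomes the returned
        leftover row whose residual the outer root in t drives to zero.
        """
        spec, params = self.spec, self.params
        sp = params.species
        scale_free = n_rs_fixed is not None

        variables: list[str] = [] if scale_free else ["rpc"]
        variables += self._protein_vars()
        if spec.has_rna:
            variables += ["trna", "mrna_nt"]
        if spec.has_membrane:
            variables += ["lip"]

        def form(**coeffs: float) -> _LinearForm:
            return _LinearForm(coeffs)

        def nrs_form(coeff: float) -> _LinearForm:
            if scale_free:
                return _LinearForm({}, coeff * n_rs_fixed)
            return _LinearForm({"rpc": coeff})

        # flux linear forms -------------------------------------------------
        fluxes: dict[str, _LinearForm] = {}
        fluxes["translation_aa"] = nrs_form(self.k_rs)
        if spec.has_rna:
            fluxes["transcription_nt"] = form(rp=sp["rp"].k_rate)
        if spec.has_dna:
            fluxes["replication_dnt"] = _LinearForm({}, self.n_dna_total / t)
        if spec.has_membrane:
            fluxes["lipid_synthesis"] = form(lip=1.0 / t)
        for pw_id in sorted(spec.included_pathways):
            fluxes[f"flux_{pw_id}"] = self._pathway_flux(pw_id, fluxes, t)

        rows: list[tuple[str, dict[str, float], float]] = []

        def add_row(name: str, lhs: _LinearForm, rhs: float = 0.0) -> None:
            rows.append((name, lhs.coeffs, rhs - lhs.const))

        # protein doubling: sum(N_j n_j) - t k_rs N_rs = -(const members)
        protein = _LinearForm()
        protein.add(nrs_form(self.n_rpc - t * self.k_rs))
        for v in self._protein_vars():
            protein.coeffs[v] = protein.coeffs.get(v, 0.0) + self._n_monomers(v)
        protein.const += self.rc_count * self.n_rc + self.pool

        protein_row = None
        if scale_free:
            protein_row = (protein.coeffs, -protein.const)
        else:
            add_row("doubling:protein", protein)

        if spec.has_rna:
            rna = _LinearForm()
            rna.add(nrs_form(sp["rrna"].n_monomers))
            rna.coeffs["trna"] = sp["trna"].n_monomers
            rna.coeffs["mrna_nt"] = 1.0
            rna.coeffs["rp"] = rna.coeffs.get("rp", 0.0) - t * sp["rp"].k_rate
            add_row("doubling:rna", rna)

            trna = _LinearForm({"trna": 1.0})
            trna.add(nrs_form(-params.coupling("trna_per_ribosome")))
            add_row("coupling:trna", trna)

            mu = params.coupling("mrna_per_ribosome")
            mrna = _LinearForm({"mrna_nt": 1.0})
            fac = -3.0 * mu / (t * self.k_rs)
            mrna.add(nrs_form(fac * self.n_rpc**2))
            for v in self._protein_vars():
                n = self._n_monomers(v)
                mrna.coeffs[v] = mrna.coeffs.get(v, 0.0) + fac * n * n
            mrna.const += fac * self.rc_count * self.n_rc**2
            add_row("coupling:mrna", mrna)

        for pw_id in sorted(spec.included_pathways):
            pw = params.pathways[pw_id]
            k_enz = sp[pw.enzyme].k_rate
            row = _LinearForm({f"enz_{pw_id}": k_enz})
            row.add(fluxes[f"flux_{pw_id}"], -pw.length_reactions)
            add_row(f"flux:{pw_id}", row)

        if spec.has_membrane:
            lip_balance = _LinearForm(
                {"lip": 1.0, "lpe": -t * sp["lpe"].k_rate}
            )
            add_row("doubling:lipid", lip_balance)

            area = _LinearForm(
                {"lip": params.geometry.area_per_lipid_nm2 / 2.0}
            )
            for s in sorted(spec.included_species):
                if s != "lip" and sp[s].footprint_nm2 is not None:
                    area.coeffs[s] = area.coeffs.get(s, 0.0) + sp[s].footprint_nm2
            add_row("area:membrane", area, rhs=float(area_nm2))

        if spec.has_energy:
            self._energy_rows(t, fluxes, add_row)

        return _Assembled(variables, rows, fluxes, protein_row)

    def _n_monomers(self, var: str) -> float:
        sp = self.params.species
        if var.startswith("enz_"):
            pw = self.params.pathways[var.removeprefix("enz_")]
            return sp[pw.enzyme].n_monomers
        return sp[var].n_monomers

    def _pathway_flux(
        self, pw_id: str, fluxes: dict[str, _LinearForm], t: float
    ) -> _LinearForm:
        out = _LinearForm()
        if pw_id == "PW2":
            out.add(fluxes["translation_aa"])
        elif pw_id == "PW4":
            out.add(fluxes["transcription_nt"])
        elif pw_id == "PW3":
            out.add(fluxes["replication_dnt"])
        elif pw_id == "PW5":
            out.add(fluxes["lipid_synthesis"])
        elif pw_id == "PW1":
            s1 = self.params.energy.substrates_per_monomer if self.params.energy else 1.0
            for name in (
                "translation_aa",
                "transcription_nt",
                "replication_dnt",
                "lipid_synthesis",
            ):
                if name in fluxes:
                    out.add(fluxes[name], s1)
        return out

    def _energy_rows(self, t, fluxes, add_row) -> None:
        spec, params = self.spec, self.params
        e = params.energy
        sp = params.species
        k_etc = e.etc_atp_rate

        atp = _LinearForm()
        atp.add(fluxes["translation_aa"], e.atp_per_aa_polymerized)
        if "transcription_nt" in fluxes:
            atp.add(fluxes["transcription_nt"], e.atp_per_nt_polymerized)
        if "replication_dnt" in fluxes:
            atp.add(fluxes["replication_dnt"], e.atp_per_dnt_polymerized)
        if "lipid_synthesis" in fluxes:
            atp.add(fluxes["lipid_synthesis"], e.atp_per_lipid)
        for pw_id in sorted(spec.included_pathways):
            pw = params.pathways[pw_id]
            atp.add(fluxes[f"flux_{pw_id}"], pw.atp_per_reaction * pw.length_reactions)

        # substrate burned by the ETC, imported through the membrane
        energy_substrate = _LinearForm({"etc": k_etc / e.atp_per_substrate_oxidized})

        if spec.medium == "rich":
            monomers = _LinearForm()
            for name in (
                "translation_aa",
                "transcription_nt",
                "replication_dnt",
                "lipid_synthesis",
            ):
                if name in fluxes:
                    monomers.add(fluxes[name])
            imports = _LinearForm().add(monomers).add(energy_substrate)
            fluxes["monomer_import"] = monomers
            fluxes["substrate_import"] = energy_substrate
            atp.add(imports, e.atp_per_transport)
            energy = _LinearForm({"etc": k_etc}).add(atp, -1.0)
            add_row("energy:atp", energy)
            mtp_row = _LinearForm({"mtp": sp["mtp"].k_rate}).add(monomers, -1.0)
            add_row("transport:mtp", mtp_row)
            tp_row = _LinearForm({"tp": sp["tp"].k_rate}).add(energy_substrate, -1.0)
            add_row("transport:tp", tp_row)
        else:
            carbon = _LinearForm()
            if "flux_PW1" in fluxes:
                carbon.add(fluxes["flux_PW1"])
            imports = _LinearForm().add(carbon).add(energy_substrate)
            fluxes["substrate_import"] = imports
            atp.add(imports, e.atp_per_transport)
            energy = _LinearForm({"etc": k_etc}).add(atp, -1.0)
            add_row("energy:atp", energy)
            tp_row = _LinearForm({"tp": sp["tp"].k_rate}).add(imports, -1.0)
            add_row("transport:tp", tp_row)

    # -- linear solve at fixed (t, area) ------------------------------------

    def counts_at(
        self,
        t: float,
        area_nm2: Optional[float] = None,
        n_rs_fixed: Optional[float] = None,
    ) -> tuple[dict[str, float], dict[str, float], Optional[float]]:
        """Solve counts; returns (solution, flux values, protein residual)."""
        asm = self.assemble(t, area_nm2, n_rs_fixed)
        n = len(asm.variables)
        if n:
            idx = {v: i for i, v in enumerate(asm.variables)}
            a = np.zeros((n, n))
            b = np.zeros(n)
            if len(asm.rows) != n:
                raise SolverError(
                    f"{self.spec.id}: {len(asm.rows)} equations for {n} unknowns"
                )
            for i, (_, coeffs, rhs) in enumerate(asm.rows):
                for k, c in coeffs.items():
                    a[i, idx[k]] = c
                b[i] = rhs
            try:
                x = np.linalg.solve(a, b)
            except np.linalg.LinAlgError as exc:
                raise SolverError(f"{self.spec.id}: singular system at t={t}") from exc
            sol = {v: float(x[idx[v]]) for v in asm.variables}
        else:
            sol = {}
        if n_rs_fixed is not None:
            sol["rpc"] = n_rs_fixed
        flux_values = {name: f.value(sol) for name, f in asm.fluxes.items()}
        resid = None
        if asm.protein_row is not None:
            coeffs, rhs = asm.protein_row
            resid = sum(c * sol[k] for k, c in coeffs.items()) - rhs
        return sol, flux_values, resid

    # -- volume fixed point --------------------------------------------------

    def _dry_mass_da(self, sol: dict[str, float]) -> float:
        state = self._raw_state(sol, {}, t=1.0)
        return sum(component_masses_da(state, self.params).values())

    def solve_fixed_t(self, t: float) -> SolutionState:
        """Solve a size-pinned model at a fixed doubling time."""
        if not self.spec.has_membrane:
            sol, fluxes, _ = self.counts_at(t)
            return self._finalize(t, sol, fluxes, volume=None)
        geometry = self.params.geometry

        def implied_volume(v: float) -> float:
            a_nm2 = area_um2(v, geometry) * NM2_PER_UM2
            sol, _, _ = self.counts_at(t, area_nm2=a_nm2)
            dry_g = self._dry_mass_da(sol) * GRAMS_PER_DALTON
            m_tot = dry_g / (1.0 - geometry.water_mass_fraction)
            return m_tot / geometry.density_g_per_cm3 * UM3_PER_CM3

        def g(v: float) -> float:
            return implied_volume(v) - v

        v_lo, v_hi = _bracket_fixed_point(g, self.spec.id, t)
        v_star = brentq(g, v_lo, v_hi, xtol=1e-300, rtol=1e-15, maxiter=200)
        a_nm2 = area_um2(v_star, geometry) * NM2_PER_UM2
        sol, fluxes, _ = self.counts_at(t, area_nm2=a_nm2)
        return self._finalize(t, sol, fluxes, volume=v_star)

    def solve_scale_free(self, n_rs: float) -> SolutionState:
        """Solve a flat-line model at a given ribosome count (root in t).

        The leftover protein-doubling residual f(t) = sum(N n) - t k_rs N_rs
        is positive just above the bare-replicator time whenever any extra
        burden exists and decreases monotonically, so Brent's method on a
        geometrically expanded bracket finds the unique root.
        """

        def f(t: float) -> float:
            _, _, resid = self.counts_at(t, n_rs_fixed=n_rs)
            return resid

        t_lo = self.n_rpc / self.k_rs
        if f(t_lo) <= 0.0:  # no burden beyond the replicator itself
            return self._finalize_scale_free(t_lo, n_rs)
        t_hi = t_lo
        for _ in range(200):
            t_hi *= 2.0
            if f(t_hi) < 0:
                break
        else:
            raise SolverError(f"{self.spec.id}: no upper bracket for t_d")
        t = brentq(f, t_lo, t_hi, xtol=1e-300, rtol=1e-15, maxiter=200)
        return self._finalize_scale_free(t, n_rs)

    def _finalize_scale_free(self, t: float, n_rs: float) -> SolutionState:
        sol, fluxes, _ = self.counts_at(t, n_rs_fixed=n_rs)
        return self._finalize(t, sol, fluxes, volume=None)

    # -- state assembly ------------------------------------------------------

    def _raw_state(
        self, sol: dict[str, float], fluxes: dict[str, float], t: float
    ) -> SolutionState:
        counts = dict(sol)
        if self.spec.has_rna:
            counts["rrna"] = counts["rpc"] * self.params.coupling("rrna_per_ribosome")
        if self.spec.has_dna:
            counts["rc"] = self.rc_count
            counts["dna"] = self.params.coupling("genomes_per_cell")
        if self.pool > 0:
            counts["aa_prot"] = self.pool
        return SolutionState(
            model_id=self.spec.id, t_d_srs=t, counts=counts, fluxes=dict(fluxes)
        )

    def _finalize(
        self,
        t: float,
        sol: dict[str, float],
        fluxes: dict[str, float],
        volume: Optional[float],
    ) -> SolutionState:
        state = self._raw_state(sol, fluxes, t)
        if self.spec.has_energy and "etc" in sol:
            state.fluxes["atp_production"] = (
                sol["etc"] * self.params.energy.etc_atp_rate
            )
        masses = component_masses_da(state, self.params)
        dry_da = sum(masses.values())
        state.dry_mass_g = dry_da * GRAMS_PER_DALTON
        w = (
            self.params.geometry.water_mass_fraction
            if self.params.geometry is not None
            else 0.0
        )
        state.m_tot_g = state.dry_mass_g / (1.0 - w)
        if volume is not None:
            state.volume_um3 = volume
            state.shape = cell_dimensions(volume, self.params.geometry)
            state.area_um2 = state.shape.area_um2
            state.lipid_area_um2 = (
                sol.get("lip", 0.0)
                * self.params.geometry.area_per_lipid_nm2
                / 2.0
                / NM2_PER_UM2
            )
        state.mass_fractions = _mass_fractions(masses)
        _check_feasibility(state, self)
        return state


def _mass_fractions(masses_da: dict[str, float]) -> dict[str, float]:
    groups = {
        "ribosomal": ("rpc", "rrna"),
        "rna_other": ("trna", "mrna"),
        "polymerases": ("rp",),
        "enzymes": ("enz_PW1", "enz_PW2", "enz_PW4", "enz_PW5", "lpe"),
        "dna_associated": ("dna", "rc", "enz_PW3"),
        "membrane_protein": ("etc", "tp", "mtp"),
        "membrane_lipid": ("lip",),
        "unspecified_protein": ("aa_prot",),
    }
    total = sum(masses_da.values())
    if total <= 0:
        return {}
    out = {}
    for group, keys in groups.items():
        m = sum(masses_da.get(k, 0.0) for k in keys)
        if m:
            out[group] = m / total
    return out


def _check_feasibility(state: SolutionState, solver: _ModelSolver) -> None:
    scale = max((abs(v) for v in state.counts.values()), default=1.0)
    for key, value in state.counts.items():
        if value < -_NEG_TOL * max(1.0, scale):
            state.feasible = False
            if key == "lip":
                state.infeasibility.append(
                    "membrane surface exhausted: negative lipid area"
                )
            else:
                state.infeasibility.append(f"negative count for {key}")
    if solver.has_dna:
        required = solver.n_dna_total / (solver.rc_count * state.t_d_srs)
        state.fluxes["replication_rate_per_rc"] = required
        if required > solver.params.species["rc"].k_rate * (1 + 1e-12):
            state.feasible = False
            state.infeasibility.append(
                f"replication needs {required:.1f} nt/s per replisome, above the "
                f"k_rc cap {solver.params.species['rc'].k_rate}"
            )


def _bracket_fixed_point(g, model_id: str, t: float) -> tuple[float, float]:
    """Bracket the volume fixed point g(V)=0 with geometric expansion."""
    v = 1e-12
    g_lo = g(v)
    if g_lo <= 0:  # shrink further; the implied volume is tiny
        for _ in range(100):
            v /= 8.0
            if g(v) > 0:
                return v, v * 8.0
        raise SolverError(f"{model_id}: no lower volume bracket at t={t}")
    v_hi = v
    for _ in range(300):
        v_hi *= 4.0
        if g(v_hi) < 0:
            return v_hi / 4.0, v_hi
    raise SolverError(f"{model_id}: no upper volume bracket at t={t}")


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------


def solve(
    model_id: str | ModelSpec,
    params: ParameterSet,
    *,
    t_d: Optional[float] = None,
    n_rs: Optional[float] = None,
    n_aa_prot: Optional[float] = None,
    _verify: bool = True,
) -> SolutionState:
    """Solve one model at one operating point.

    Exactly one of ``t_d`` (doubling time, s) and ``n_rs`` (ribosome count)
    is given as the driver.  Returns a :class:`SolutionState`; physically
    impossible operating points (exhausted membrane, replication above the
    replisome cap) come back with ``feasible=False`` and explicit reasons —
    never silently clamped.
    """
    if (t_d is None) == (n_rs is None):
        raise ValueError("give exactly one of t_d or n_rs")
    spec = get_model_spec(model_id)
    pool = spec.n_aa_prot if n_aa_prot is None else n_aa_prot
    ms = _ModelSolver(spec, params, pool)
    # an explicitly zero protein pool turns the PROT model scale-free
    scale_free = spec.scale_free or (spec.n_aa_prot > 0 and pool == 0)

    if scale_free:
        if t_d is not None:
            raise ValueError(
                f"{spec.id}: doubling time is an output for scale-free models; "
                "drive with n_rs"
            )
        state = ms.solve_scale_free(n_rs)
        state.driver = ("N_rs", n_rs)
    elif t_d is not None:
        state = ms.solve_fixed_t(t_d)
        state.driver = ("t_d_srs", t_d)
    elif not spec.has_membrane:
        # genome/pool models without geometry: the system minus the protein
        # balance is square at fixed N_rs, so root the protein residual in t
        state = ms.solve_scale_free(n_rs)
        state.driver = ("N_rs", n_rs)
    else:
        state = _invert_driver(ms, n_rs)
        state.driver = ("N_rs", n_rs)

    if _verify and state.feasible:
        system = build_model(spec, params, state.driver, n_aa_prot=pool)
        _verify_residuals(system, state)
    return state


def solve_at(system: EquationSystem) -> SolutionState:
    """Solve a compiled EquationSystem at its driver setting."""
    name, value = system.driver
    kw = {"t_d": value} if name == "t_d_srs" else {"n_rs": value}
    return solve(system.model, system.params, n_aa_prot=system.n_aa_prot, **kw)


def _invert_driver(ms: _ModelSolver, n_rs_target: float) -> SolutionState:
    """Outer root: find the t_d at which a size-pinned model has N_rs.

    On the physical branch N_rs(t_d) decreases monotonically with t_d and
    diverges toward the flat stoichiometric floor (or ends at the membrane
    boundary).  The downward walk keeps only states with N_rs > 0 and
    bisects back up when a step lands below the floor, mirroring the
    growth-boundary search.
    """

    def state_at(t: float) -> Optional[SolutionState]:
        try:
            st = ms.solve_fixed_t(t)
        except SolverError:
            return None
        return st if st.n_rs > 0 else None

    t_hi = 1e7
    st = state_at(t_hi)
    if st is None:
        raise SolverError(f"{ms.spec.id}: no valid state at t_d={t_hi:g}")
    for _ in range(60):  # targets smaller than N_rs(1e7 s): expand upward
        if st.n_rs <= n_rs_target:
            break
        t_hi *= 4.0
        st = state_at(t_hi)
        if st is None:
            raise SolverError(
                f"{ms.spec.id}: N_rs={n_rs_target} out of range (large t_d)"
            )
    else:
        raise SolverError(f"{ms.spec.id}: N_rs={n_rs_target} out of range")

    bracket_lo = None
    t_prev = t_hi
    for _ in range(400):
        t = t_prev * 0.9
        st = state_at(t)
        if st is not None and st.n_rs >= n_rs_target:
            bracket_lo = t
            break
        if st is not None:
            t_prev = t
            continue
        lo, hi = t, t_prev  # invalid below, valid above: bisect into window
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            st = state_at(mid)
            if st is not None and st.n_rs >= n_rs_target:
                bracket_lo = mid
                break
            if st is not None:
                hi = mid
                t_prev = mid
            else:
                lo = mid
            if hi - lo < 1e-12 * hi:
                break
        break
    if bracket_lo is None:
        raise SolverError(
            f"{ms.spec.id}: no doubling time reaches N_rs={n_rs_target}; "
            "the value may exceed the growth boundary"
        )

    def h(t: float) -> float:
        return ms.solve_fixed_t(t).n_rs - n_rs_target

    t = brentq(h, bracket_lo, t_prev, xtol=1e-300, rtol=1e-15, maxiter=200)
    return ms.solve_fixed_t(t)


def _verify_residuals(system: EquationSystem, state: SolutionState) -> None:
    scales = {
        "polymer_doubling": state.t_d_srs,
        "flux_balance": max(state.fluxes.values(), default=1.0),
        "replication": state.fluxes.get("replication_dnt", 1.0),
        "energy": state.fluxes.get("atp_production", 1.0),
        "transport": max(state.fluxes.values(), default=1.0),
        "area": (state.area_um2 or 1.0) * NM2_PER_UM2,
        "mass_volume": max(state.m_tot_g, state.volume_um3 or 0.0, 1e-30),
        "coupling": max((abs(v) for v in state.counts.values()), default=1.0),
    }
    for eq in system.equations:
        res = eq(state, system.params)
        scale = max(abs(scales.get(eq.kind, 1.0)), 1e-300)
        if eq.name == "area:membrane" and not state.feasible:
            continue
        if abs(res) > RESIDUAL_RTOL * scale:
            raise SolverError(
                f"{system.model.id}: residual {eq.name} = {res:.3e} "
                f"exceeds {RESIDUAL_RTOL:.0e} x {scale:.3e}"
            )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Solutions over a driver grid (the substrate of the t_d/N_rs figures)."""

    model_id: str
    driver_name: str
    grid: np.ndarray
    states: list[SolutionState]
    params_note: str = ""

    def to_records(self) -> list[dict]:
        recs = []
        for value, st in zip(self.grid, self.states):
            rec = {
                "model_id": self.model_id,
                self.driver_name: value,
                "t_d_srs": st.t_d_srs if st is not None else math.nan,
                "feasible": bool(st is not None and st.feasible),
            }
            if st is not None:
                rec.update(
                    {
                        "N_rs": st.n_rs,
                        "m_tot_g": st.m_tot_g,
                        "dry_mass_g": st.dry_mass_g,
                        "volume_um3": st.volume_um3,
                        "area_um2": st.area_um2,
                        "lip_per_rs": st.lip_per_rs,
                        "n_lip": st.counts.get("lip"),
                        "infeasibility": "; ".join(st.infeasibility),
                    }
                )
            recs.append(rec)
        return recs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.to_records())


def sweep(
    model_id: str | ModelSpec,
    params: ParameterSet,
    driver_name: str,
    grid: Sequence[float],
    n_aa_prot: Optional[float] = None,
) -> SweepResult:
    """Solve a model across a driver grid; infeasible points are recorded,
    never fatal (infeasibility near a boundary is itself the result)."""
    spec = get_model_spec(model_id)
    grid = np.asarray(list(grid), dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and non-empty")
    states: list[Optional[SolutionState]] = []
    for value in grid:
        kw = {"t_d": value} if driver_name == "t_d_srs" else {"n_rs": value}
        try:
            states.append(solve(spec, params, n_aa_prot=n_aa_prot, **kw))
        except SolverError as exc:
            logger.warning("%s at %s=%g: %s", spec.id, driver_name, value, exc)
            states.append(None)
    return SweepResult(
        model_id=spec.id, driver_name=driver_name, grid=grid, states=states
    )
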