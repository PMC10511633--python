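"""Doubling-time limits: boundary roots, asymptotes and classification.

Three situations arise:

* **membrane-protein models** (minimal/rich complete systems and the
  membrane-protein model): growing cells need ever more ETC and transporter
  area per volume while the surface-to-volume ratio falls, so the lipid
  area hits zero at a finite size.  The minimal doubling time is the root
  of N_lip(t_d) = 0 — membrane exhaustion, found by bracketed bisection on
  the feasible/infeasible transition.
* **size-dependent models without membrane proteins** (lipid-only
  membranes, the genome model, the unspecified-protein pool): t_d decays
  toward the doubling time of the corresponding cytosol-only composition;
  the minimum is that asymptote and any finite "maximal N_rs" encodes a
  tolerance convention (smallest N_rs within ``epsilon`` seconds of the
  asymptote), reported as such and never claimed as a reproduction.
* **flat-line models**: t_d is independent of N_rs; no size limit exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .balances import SolutionState
from .models import ModelSpec, closed_form_doubling_time, get_model_spec
from .parameters import ParameterSet
from .solver import SolverError, SweepResult, _ModelSolver, solve

#: convergence tolerance (s) defining the conventional finite maximal N_rs
#: of asymptotic models: half of the printed two-decimal precision
DEFAULT_ASYMPTOTE_EPSILON_S = 0.005

#: absolute tolerance (s) of the boundary bisection on t_d
BOUNDARY_XTOL_S = 1e-6


@dataclass(frozen=True)
class LimitReport:
    """One row of the doubling-time-limit table."""

    model_id: str
    t_d_min: float
    t_d_min_method: str  # closed_form | boundary_root | asymptote_estimate
    n_rs_max: float  # math.inf when unlimited
    n_rs_max_method: str  # at_boundary | tolerance_defined | infinite
    limit_type: str  # membrane_surface_area | molecular_properties
    slower_growth: tuple[str, ...]  # subset of {cell_geometry, dna_replication,
    #                                 unspecified_protein}
    epsilon_s: Optional[float] = None
    boundary_state: Optional[SolutionState] = None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "t_d_min": self.t_d_min,
            "t_d_min_method": self.t_d_min_method,
            "n_rs_max": None if math.isinf(self.n_rs_max) else self.n_rs_max,
            "n_rs_max_method": self.n_rs_max_method,
            "limit_type": self.limit_type,
            "slower_growth": list(self.slower_growth),
            "epsilon_s": self.epsilon_s,
        }


def _cytosol_only_spec(spec: ModelSpec) -> ModelSpec:
    """The same composition with membrane, genome and pool stripped.

    Its flat doubling time is the asymptote that the size-dependent model
    approaches at large N_rs, because the second-group components' share of
    the cell vanishes there.
    """
    species = set(spec.included_species) - {"lip", "lpe", "etc", "tp", "mtp", "dna", "rc"}
    pathways = set(spec.included_pathways) - {"PW1", "PW3", "PW5"}
    return replace(
        spec,
        id=spec.id + "#cytosol",
        included_species=frozenset(species),
        included_pathways=frozenset(pathways),
        has_membrane=False,
        has_dna=False,
        has_energy=False,
        medium="n/a",
        driver_options=("N_rs",),
        n_aa_prot=0.0,
    )


def asymptotic_doubling_time(model_id: str | ModelSpec, params: ParameterSet) -> float:
    """Large-size limit of t_d: the cytosol-only flat value."""
    spec = get_model_spec(model_id)
    reduced = spec if spec.scale_free else _cytosol_only_spec(spec)
    return solve(reduced, params, n_rs=1.0, n_aa_prot=0.0).t_d_srs


def find_growth_boundary(
    model_id: str | ModelSpec,
    params: ParameterSet,
    epsilon_s: float = DEFAULT_ASYMPTOTE_EPSILON_S,
) -> LimitReport:
    """Minimal t_d and maximal N_rs of one model, with provenance labels."""
    spec = get_model_spec(model_id)

    if spec.scale_free and spec.n_aa_prot == 0:
        t_min = solve(spec, params, n_rs=1.0).t_d_srs
        method = (
            "closed_form"
            if closed_form_doubling_time(spec, params, n_rs=1.0) is not None
            else "asymptote_estimate"
        )
        return classify_limit(
            spec, t_min, method, math.inf, "infinite", boundary_state=None
        )

    if spec.has_energy and spec.has_membrane:
        t_min, state = _membrane_boundary_root(spec, params)
        return classify_limit(
            spec, t_min, "boundary_root", state.n_rs, "at_boundary",
            boundary_state=state,
        )

    # asymptotic size-dependent models (lipid-only membrane, genome, pool)
    t_asym = asymptotic_doubling_time(spec, params)
    if spec.n_aa_prot > 0 and not spec.has_membrane and not spec.has_dna:
        # the pool size is a free input, not a structure of the cell:
        # no intrinsic size limit is defined
        return classify_limit(
            spec, t_asym, "asymptote_estimate", math.inf, "infinite",
            boundary_state=None,
        )
    ms = _ModelSolver(spec, params, spec.n_aa_prot)
    state = ms.solve_fixed_t(t_asym + epsilon_s)
    return classify_limit(
        spec, t_asym, "asymptote_estimate", state.n_rs, "tolerance_defined",
        epsilon_s=epsilon_s, boundary_state=state,
    )


def _membrane_boundary_root(
    spec: ModelSpec, params: ParameterSet, t_start: float = 1.0e6
) -> tuple[float, SolutionState]:
    """Root of N_lip(t_d) = 0: the membrane-exhaustion boundary.

    N_lip(t_d) is positive at slow growth and turns negative on the
    continued (infeasible) branch just above the flat stoichiometric
    doubling-time floor, where the ribosome count diverges and then flips
    sign.  The bracket therefore contracts geometrically while N_rs stays
    positive; once a step lands below the floor (negative N_rs) it bisects
    back up into the narrow window with N_rs > 0 and N_lip < 0, and Brent's
    method polishes the boundary root there.
    """
    ms = _ModelSolver(spec, params, spec.n_aa_prot)

    def probe(t: float) -> tuple[float, float]:
        st = ms.solve_fixed_t(t)
        return st.counts["lip"], st.n_rs

    def n_lip(t: float) -> float:
        return probe(t)[0]

    t_hi = t_start
    lip_hi, rs_hi = probe(t_hi)
    if lip_hi <= 0 or rs_hi <= 0:
        raise SolverError(
            f"{spec.id}: no feasible starting point at t_d={t_hi:g} s"
        )
    def safe_probe(t: float) -> tuple[float, float]:
        try:
            return probe(t)
        except SolverError:
            return 1.0, -1.0  # behaves like "below the stoichiometric floor"

    bracket_lo = None
    for _ in range(400):
        t_next = t_hi * 0.8
        lip, rs = safe_probe(t_next)
        if rs > 0 and lip < 0:
            bracket_lo = t_next
            break
        if rs > 0:  # still feasible; keep walking down
            t_hi = t_next
            continue
        # overshot below the stoichiometric floor: bisect back up into the
        # window where N_rs > 0 but the membrane is exhausted
        lo, hi = t_next, t_hi
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            lip, rs = safe_probe(mid)
            if rs > 0 and lip < 0:
                bracket_lo = mid
                break
            if rs > 0:  # feasible: boundary is below mid
                hi = mid
                t_hi = mid
            else:
                lo = mid
            if hi - lo < 1e-12 * hi:
                break
        break
    if bracket_lo is None:
        raise SolverError(
            f"{spec.id}: no membrane-exhaustion sign change found "
            f"(searched down from t_d={t_start:g} s)"
        )
    t_min = brentq(
        n_lip, bracket_lo, t_hi, xtol=BOUNDARY_XTOL_S, rtol=1e-15, maxiter=200
    )
    # report the state on the feasible side of the root
    state = ms.solve_fixed_t(max(t_min, t_min * (1 + 1e-14)))
    if not state.feasible:
        state = ms.solve_fixed_t(t_min + BOUNDARY_XTOL_S)
    return t_min, state


def classify_limit(
    model_id: str | ModelSpec,
    t_d_min: float,
    t_d_min_method: str,
    n_rs_max: float,
    n_rs_max_method: str,
    epsilon_s: Optional[float] = None,
    boundary_state: Optional[SolutionState] = None,
) -> LimitReport:
    """Attach the limit-type and slower-growth labels to a limit search."""
    spec = get_model_spec(model_id)
    limit_type = (
        "membrane_surface_area"
        if n_rs_max_method == "at_boundary"
        else "molecular_properties"
    )
    slower: list[str] = []
    if spec.has_membrane:
        slower.append("cell_geometry")
    if spec.has_dna:
        slower.append("dna_replication")
    if spec.n_aa_prot > 0:
        slower.append("unspecified_protein")
    return LimitReport(
        model_id=spec.id,
        t_d_min=t_d_min,
        t_d_min_method=t_d_min_method,
        n_rs_max=n_rs_max,
        n_rs_max_method=n_rs_max_method,
        limit_type=limit_type,
        slower_growth=tuple(slower),
        epsilon_s=epsilon_s,
        boundary_state=boundary_state,
    )


# ---------------------------------------------------------------------------
# composition and physiological windows
# ---------------------------------------------------------------------------


def composition_report(state: SolutionState) -> dict:
    """Dry-mass fractions by component group plus the lipid/ribosome ratio."""
    return {
        "model_id": state.model_id,
        "t_d_srs": state.t_d_srs,
        "mass_fractions": dict(state.mass_fractions),
        "lip_per_rs": state.lip_per_rs,
        "dry_mass_g": state.dry_mass_g,
        "m_tot_g": state.m_tot_g,
    }


@dataclass(frozen=True)
class PhysiologicalWindow:
    """Driver range over which the total cell mass is physiological."""

    model_id: str
    m_tot_bounds_g: tuple[float, float]
    t_d_range_s: Optional[tuple[float, float]]
    n_rs_range: Optional[tuple[float, float]]
    partial: bool  # bounds extend beyond the sweep


def physiological_window(
    sweep_result: SweepResult,
    m_tot_bounds_g: tuple[float, float] = (1.0e-13, 1.0e-12),
) -> PhysiologicalWindow:
    """Interpolate the t_d and N_rs ranges where M_tot is inside bounds.

    The default bounds are the experimentally observed whole-cell mass
    window of E. coli.  Interpolation is log-log along the sweep; an empty
    window is returned when the bounds exclude the whole sweep.
    """
    lo, hi = m_tot_bounds_g
    rows = [
        (float(v), st)
        for v, st in zip(sweep_result.grid, sweep_result.states)
        if st is not None and st.feasible and st.m_tot_g > 0
    ]
    if not rows:
        return PhysiologicalWindow(
            sweep_result.model_id, m_tot_bounds_g, None, None, True
        )
    m = np.array([st.m_tot_g for _, st in rows])
    t = np.array([st.t_d_srs for _, st in rows])
    n = np.array([st.n_rs for _, st in rows])
    order = np.argsort(m)
    m, t, n = m[order], t[order], n[order]
    if hi < m[0] or lo > m[-1]:
        return PhysiologicalWindow(
            sweep_result.model_id, m_tot_bounds_g, None, None, True
        )
    partial = lo < m[0] or hi > m[-1]
    lo_c, hi_c = max(lo, m[0]), min(hi, m[-1])

    def interp(mass: float, values: np.ndarray) -> float:
        return float(
            np.exp(np.interp(np.log(mass), np.log(m), np.log(np.abs(values))))
        )

    t_at = sorted((interp(lo_c, t), interp(hi_c, t)))
    n_at = sorted((interp(lo_c, n), interp(hi_c, n)))
    return PhysiologicalWindow(
        sweep_result.model_id,
        m_tot_bounds_g,
        (t_at[0], t_at[1]),
        (n_at[0], n_at[1]),
        partial,
    )
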