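"""Growth boundaries, limit classification, composition, windows."""

import math

import numpy as np
import pytest

import protocell as pc
from protocell.limits import (
    asymptotic_doubling_time,
    composition_report,
    find_growth_boundary,
    physiological_window,
)
from protocell.solver import SolverError


@pytest.fixture(scope="module")
def toy_boundary(toy_membrane):
    return find_growth_boundary(toy_membrane.model, toy_membrane.params)


class TestBoundaryRoot:
    def test_toy_membrane_agrees_with_grid_scan_oracle(
        self, toy_membrane, toy_boundary
    ):
        """Bisection boundary equals a brute-force fine-grid scan to 1e-4."""

        def smallest_feasible(ts):
            for t in ts:
                try:
                    st = pc.solve(toy_membrane.model, toy_membrane.params,
                                  t_d=float(t), _verify=False)
                except SolverError:
                    continue
                if st.feasible:
                    return float(t)
            return None

        # coarse localization then two refinements: final step < 5e-5 rel
        lo, hi = toy_membrane.expected["t_d_rs"], 1.0e4
        for n in (300, 200, 200):
            t_first = smallest_feasible(np.geomspace(lo, hi, n))
            assert t_first is not None
            step = (hi / lo) ** (1.0 / (n - 1))
            lo, hi = t_first / step, t_first * step
        assert toy_boundary.t_d_min == pytest.approx(t_first, rel=1e-4)

    def test_boundary_state_is_membrane_exhausted(self, toy_boundary):
        st = toy_boundary.boundary_state
        assert st.feasible
        assert st.lipid_area_um2 == pytest.approx(0.0, abs=1e-6 * st.area_um2)

    def test_infeasible_just_below_feasible_just_above(
        self, toy_membrane, toy_boundary
    ):
        t_min = toy_boundary.t_d_min
        below = pc.solve(toy_membrane.model, toy_membrane.params, t_d=t_min - 0.01)
        above = pc.solve(toy_membrane.model, toy_membrane.params, t_d=t_min + 0.01)
        assert not below.feasible and above.feasible

    def test_reported_n_rs_max_sits_at_boundary(self, toy_membrane, toy_boundary):
        st = pc.solve(toy_membrane.model, toy_membrane.params,
                      t_d=toy_boundary.t_d_min + 1e-6)
        assert st.n_rs == pytest.approx(toy_boundary.n_rs_max, rel=1e-4)


class TestAsymptoticLimits:
    def test_lipid_model_minimum_is_cytosol_only_value(self, canonical):
        rep = find_growth_boundary("sspcm-rs+aa+rna+lip", canonical)
        t_rna = pc.closed_form_doubling_time("sspcm-rs+aa+rna", canonical)
        assert rep.t_d_min == pytest.approx(t_rna, rel=1e-9)
        assert rep.n_rs_max_method == "tolerance_defined"
        assert math.isfinite(rep.n_rs_max)
        assert rep.epsilon_s == 0.005

    def test_bare_lipid_and_genome_models_floor_at_replicator_time(self, canonical):
        t_rs = pc.closed_form_doubling_time("sspcm-rs", canonical)
        for mid in ("sspcm-rs+lip", "sspcm-rs+dna"):
            rep = find_growth_boundary(mid, canonical)
            assert rep.t_d_min == pytest.approx(t_rs, rel=1e-9)
            assert rep.n_rs_max_method == "tolerance_defined"

    def test_tolerance_convention_is_consistent(self, canonical):
        """At the conventional maximal N_rs, t_d sits epsilon above the floor."""
        rep = find_growth_boundary("sspcm-rs+aa+rna+lip", canonical)
        st = pc.solve("sspcm-rs+aa+rna+lip", canonical, t_d=rep.t_d_min + 0.005)
        assert st.n_rs == pytest.approx(rep.n_rs_max, rel=1e-9)

    def test_flat_models_have_no_size_limit(self, canonical):
        for mid in ("sspcm-rs", "sspcm-rs+aa", "sspcm-rs+aa+rna",
                    "sspcm-rs+aa+prot"):
            rep = find_growth_boundary(mid, canonical)
            assert math.isinf(rep.n_rs_max)
            assert rep.n_rs_max_method == "infinite"

    def test_asymptotic_doubling_time_strips_second_group(self, canonical):
        assert asymptotic_doubling_time(
            "sspcm-rs+aa+rna+lip", canonical
        ) == pytest.approx(
            pc.closed_form_doubling_time("sspcm-rs+aa+rna", canonical), rel=1e-12
        )


class TestClassification:
    @pytest.mark.parametrize(
        "model_id,limit_type,slower",
        [
            ("sspcm-rs", "molecular_properties", ()),
            ("sspcm-rs+aa", "molecular_properties", ()),
            ("sspcm-rs+aa+prot", "molecular_properties", ("unspecified_protein",)),
            ("sspcm-rs+aa+rna", "molecular_properties", ()),
            ("sspcm-rs+aa+rna+lip", "molecular_properties", ("cell_geometry",)),
            ("sspcm-rs+lip", "molecular_properties", ("cell_geometry",)),
            ("sspcm-rs+dna", "molecular_properties", ("dna_replication",)),
            (
                "sspcm-rs+aa+rna+lip+mprot",
                "membrane_surface_area",
                ("cell_geometry",),
            ),
            (
                "sspcm-srs-m",
                "membrane_surface_area",
                ("cell_geometry", "dna_replication"),
            ),
            (
                "sspcm-srs-r",
                "membrane_surface_area",
                ("cell_geometry", "dna_replication"),
            ),
        ],
    )
    def test_limit_table_structure(self, model_id, limit_type, slower, canonical):
        rep = find_growth_boundary(model_id, canonical)
        assert rep.limit_type == limit_type
        assert rep.slower_growth == slower


class TestComposition:
    def test_fractions_sum_to_one(self, canonical):
        st = pc.solve("sspcm-srs-r", canonical, t_d=1.0e3)
        report = composition_report(st)
        assert sum(report["mass_fractions"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_dna_dominates_slow_genome_model(self, canonical):
        """At slow growth the fixed genome is nearly all of the dry mass."""
        st = pc.solve("sspcm-rs+dna", canonical, t_d=1.0e4)
        assert composition_report(st)["mass_fractions"]["dna_associated"] > 0.95

    def test_dna_fraction_small_at_fast_growth_large_at_slow(self, canonical):
        rep = find_growth_boundary("sspcm-srs-m", canonical)
        fast = rep.boundary_state.mass_fractions["dna_associated"]
        slow = pc.solve("sspcm-srs-m", canonical, t_d=1.0e4).mass_fractions[
            "dna_associated"
        ]
        assert fast < 0.05 < 0.5 < slow


@pytest.fixture(scope="module")
def srs_m_sweep(canonical):
    rep = find_growth_boundary("sspcm-srs-m", canonical)
    grid = np.geomspace(rep.t_d_min * (1 + 1e-7), rep.t_d_min * 2, 40)
    return pc.sweep("sspcm-srs-m", canonical, "t_d_srs", grid)


class TestPhysiologicalWindow:

    def test_window_is_narrow_in_time_wide_in_counts(self, srs_m_sweep):
        win = physiological_window(srs_m_sweep, (1.0e-13, 1.55e-12))
        t_lo, t_hi = win.t_d_range_s
        n_lo, n_hi = win.n_rs_range
        assert (t_hi - t_lo) / t_lo < 0.2  # few hundred seconds
        assert n_hi / n_lo > 10  # counts vary over an order of magnitude

    def test_bounds_excluding_sweep_give_empty_window(self, srs_m_sweep):
        win = physiological_window(srs_m_sweep, (1.0, 2.0))  # grams: absurd
        assert win.t_d_range_s is None and win.partial

    def test_partial_flag_when_bounds_exceed_sweep(self, srs_m_sweep):
        win = physiological_window(srs_m_sweep, (1.0e-20, 1.55e-12))
        assert win.partial
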