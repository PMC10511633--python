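"""Solver correctness: oracle equivalence, conservation, monotonicity,
infeasibility handling and determinism."""

import numpy as np
import pytest

import protocell as pc
from protocell.models import component_masses_da
from protocell.units import GRAMS_PER_DALTON


class TestOracleEquivalence:
    """Numeric solves reproduce the closed forms to 1e-9 relative."""

    GRID = np.geomspace(1.0, 1.0e6, 50)

    @pytest.mark.parametrize(
        "model_id,params_fixture",
        [
            ("sspcm-rs", "canonical"),
            ("sspcm-rs+aa", "canonical"),
            ("sspcm-rs+aa+rna", "canonical"),
            ("sspcm-rs", "toy_analytic"),
            ("sspcm-rs+aa", "toy_analytic"),  # the toy set has no RNA species
        ],
    )
    def test_flat_models(self, model_id, params_fixture, request):
        src = request.getfixturevalue(params_fixture)
        params = src if isinstance(src, pc.ParameterSet) else src.params
        expected = pc.closed_form_doubling_time(model_id, params)
        for n_rs in self.GRID:
            state = pc.solve(model_id, params, n_rs=n_rs)
            assert state.t_d_srs == pytest.approx(expected, rel=1e-9)

    def test_protein_pool_model(self, canonical):
        for n_rs in self.GRID:
            expected = pc.closed_form_doubling_time(
                "sspcm-rs+aa+prot", canonical, n_rs=n_rs, n_aa_prot=5.0e4
            )
            state = pc.solve("sspcm-rs+aa+prot", canonical, n_rs=n_rs,
                             n_aa_prot=5.0e4)
            assert state.t_d_srs == pytest.approx(expected, rel=1e-9)

    def test_pool_reduction_to_pathway_model(self, canonical):
        """With an empty pool the pool model equals the pathway model."""
        t_aa = pc.closed_form_doubling_time("sspcm-rs+aa", canonical)
        for n_rs in (1.0, 42.0, 1e5):
            state = pc.solve("sspcm-rs+aa+prot", canonical, n_rs=n_rs,
                             n_aa_prot=0.0)
            assert state.t_d_srs == pytest.approx(t_aa, rel=1e-12)


class TestFlatLines:
    @pytest.mark.parametrize(
        "model_id",
        ["sspcm-rs", "sspcm-rs+aa", "sspcm-rs+aa+rna"],
    )
    def test_doubling_time_independent_of_size(self, model_id, canonical):
        ts = [
            pc.solve(model_id, canonical, n_rs=n).t_d_srs
            for n in (1.0, 10.0, 1e3, 1e6)
        ]
        assert max(ts) - min(ts) <= 1e-10 * ts[0]


@pytest.fixture(scope="module")
def srs_m_state(canonical):
    return pc.solve("sspcm-srs-m", canonical, t_d=5000.0)


class TestConservation:
    """Doubling, area and energy conservation recomputed from raw counts."""

    def test_protein_doubling_conservation(self, srs_m_state, canonical):
        st = srs_m_state
        sp = canonical.species
        total_aa = 0.0
        for sid, count in st.counts.items():
            if sid.startswith("enz_"):
                total_aa += count * sp["enz"].n_monomers
            elif sid in ("rpc", "rp", "rc", "lpe", "etc", "tp", "mtp"):
                total_aa += count * sp[sid].n_monomers
        assert st.n_rs * sp["rpc"].k_rate * st.t_d_srs == pytest.approx(
            total_aa, rel=1e-9
        )

    def test_rna_doubling_conservation(self, srs_m_state, canonical):
        st = srs_m_state
        sp = canonical.species
        total_nt = (
            st.counts["rrna"] * sp["rrna"].n_monomers
            + st.counts["trna"] * sp["trna"].n_monomers
            + st.counts["mrna_nt"]
        )
        assert st.counts["rp"] * sp["rp"].k_rate * st.t_d_srs == pytest.approx(
            total_nt, rel=1e-9
        )

    def test_area_conservation(self, srs_m_state, canonical):
        st = srs_m_state
        sp = canonical.species
        used_nm2 = st.counts["lip"] * canonical.geometry.area_per_lipid_nm2 / 2.0
        for sid in ("etc", "tp"):
            used_nm2 += st.counts[sid] * sp[sid].footprint_nm2
        assert used_nm2 == pytest.approx(st.area_um2 * 1e6, rel=1e-9)

    def test_energy_conservation(self, srs_m_state, canonical):
        st = srs_m_state
        e = canonical.energy
        f = st.fluxes
        consumption = (
            e.atp_per_aa_polymerized * f["translation_aa"]
            + e.atp_per_nt_polymerized * f["transcription_nt"]
            + e.atp_per_dnt_polymerized * f["replication_dnt"]
            + e.atp_per_lipid * f["lipid_synthesis"]
            + sum(
                pw.atp_per_reaction * pw.length_reactions * f[f"flux_{pid}"]
                for pid, pw in canonical.pathways.items()
            )
            + e.atp_per_transport * f["substrate_import"]
        )
        assert f["atp_production"] == pytest.approx(consumption, rel=1e-9)

    def test_pathway_internal_balance(self, srs_m_state, canonical):
        st = srs_m_state
        for pid, pw in canonical.pathways.items():
            per_step = st.fluxes[f"flux_{pid}"] / canonical.species["enz"].k_rate
            assert st.counts[f"enz_{pid}"] == pytest.approx(
                pw.length_reactions * per_step, rel=1e-9
            )

    def test_mass_fractions_sum_to_one(self, srs_m_state):
        assert sum(srs_m_state.mass_fractions.values()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_dry_mass_equals_component_sum(self, srs_m_state, canonical):
        masses = component_masses_da(srs_m_state, canonical)
        assert srs_m_state.dry_mass_g == pytest.approx(
            sum(masses.values()) * GRAMS_PER_DALTON, rel=1e-12
        )
        w = canonical.geometry.water_mass_fraction
        assert srs_m_state.m_tot_g == pytest.approx(
            srs_m_state.dry_mass_g / (1 - w), rel=1e-12
        )

    @pytest.mark.parametrize(
        "model_id,kw",
        [
            ("sspcm-rs+aa+rna+lip", {"t_d": 1400.0}),
            ("sspcm-rs+lip", {"t_d": 400.0}),
            ("sspcm-rs+dna", {"t_d": 2.0e3}),
            ("sspcm-srs-r", {"t_d": 1.0e3}),
            ("sspcm-rs+aa+rna", {"n_rs": 20.0}),
        ],
    )
    def test_all_residuals_vanish_at_solutions(self, model_id, kw, canonical):
        state = pc.solve(model_id, canonical, **kw)
        system = pc.build_model(model_id, canonical, state.driver)
        for name, res in system.residuals(state).items():
            scale = max(abs(state.t_d_srs), state.m_tot_g,
                        max(abs(v) for v in state.counts.values()))
            assert abs(res) <= 1e-8 * scale, (name, res)


class TestSizeDependence:
    def test_hockey_stick_monotonicity(self, canonical):
        """For membrane/DNA models t_d is non-increasing in N_rs."""
        for model_id in ("sspcm-rs+aa+rna+lip", "sspcm-srs-m", "sspcm-rs+dna"):
            ts = np.geomspace(4000.0, 4.0e5, 12)
            n = [pc.solve(model_id, canonical, t_d=t).n_rs for t in ts]
            assert all(a > b for a, b in zip(n, n[1:])), model_id

    def test_lipid_asymptote_reaches_cytosol_value(self, canonical):
        """t_d of the lipid models approaches the composition without lipids."""
        t_rna = pc.closed_form_doubling_time("sspcm-rs+aa+rna", canonical)
        t_rs = pc.closed_form_doubling_time("sspcm-rs", canonical)
        gap_mid = pc.solve("sspcm-rs+aa+rna+lip", canonical, n_rs=1e6).t_d_srs - t_rna
        gap_big = pc.solve("sspcm-rs+aa+rna+lip", canonical, n_rs=1e10).t_d_srs - t_rna
        assert 0 < gap_big < gap_mid
        assert gap_big / t_rna < 1e-3
        gap = pc.solve("sspcm-rs+lip", canonical, n_rs=1e10).t_d_srs - t_rs
        assert 0 < gap / t_rs < 1e-3

    def test_lip_per_rs_non_increasing_in_n_rs(self, canonical):
        ts = np.geomspace(2475.0, 1.0e4, 8)
        states = [pc.solve("sspcm-srs-m", canonical, t_d=t) for t in ts]
        n_rs = [s.n_rs for s in states]
        ratio = [s.lip_per_rs for s in states]
        # larger cells (higher N_rs) carry fewer lipids per ribosome
        pairs = sorted(zip(n_rs, ratio))
        assert all(r1 >= r2 for (_, r2), (_, r1) in zip(pairs[1:], pairs))


class TestInfeasibility:
    def test_membrane_exhaustion_is_flagged_not_clamped(self, canonical):
        from protocell.limits import find_growth_boundary

        rep = find_growth_boundary("sspcm-rs+aa+rna+lip+mprot", canonical)
        state = pc.solve(
            "sspcm-rs+aa+rna+lip+mprot", canonical, t_d=rep.t_d_min - 0.5
        )
        assert not state.feasible
        assert state.counts["lip"] < 0  # reported, never clipped
        assert any("membrane" in r for r in state.infeasibility)

    def test_replication_cap_flagged(self, toy_dna):
        fast = pc.solve(toy_dna.model, toy_dna.params, t_d=999.0)
        assert not fast.feasible
        assert any("replisome" in r for r in fast.infeasibility)
        slow = pc.solve(toy_dna.model, toy_dna.params, t_d=1001.0)
        assert slow.feasible

    def test_toy_dna_hand_values(self, toy_dna):
        state = pc.solve(toy_dna.model, toy_dna.params, t_d=1000.0)
        exp = toy_dna.expected
        assert state.counts["enz_PW3"] == pytest.approx(exp["n_enz_pw3_at_1000s"])
        assert state.n_rs == pytest.approx(exp["n_rs_at_1000s"], rel=1e-9)
        assert state.fluxes["replication_rate_per_rc"] == pytest.approx(500.0)


class TestDriverInversion:
    def test_n_rs_driver_round_trips(self, canonical):
        for model_id, n_target in [
            ("sspcm-srs-m", 5000.0),
            ("sspcm-rs+aa+rna+lip", 9.0),
            ("sspcm-rs+dna", 2.0),
        ]:
            state = pc.solve(model_id, canonical, n_rs=n_target)
            assert state.n_rs == pytest.approx(n_target, rel=1e-9)
            back = pc.solve(model_id, canonical, t_d=state.t_d_srs)
            assert back.n_rs == pytest.approx(n_target, rel=1e-6)

    def test_flat_models_reject_time_driver(self, canonical):
        with pytest.raises(ValueError, match="drive with n_rs"):
            pc.solve("sspcm-rs", canonical, t_d=400.0)

    def test_exactly_one_driver_required(self, canonical):
        with pytest.raises(ValueError):
            pc.solve("sspcm-rs", canonical)
        with pytest.raises(ValueError):
            pc.solve("sspcm-rs", canonical, t_d=1.0, n_rs=1.0)


class TestSweep:
    def test_single_point_grid(self, canonical):
        result = pc.sweep("sspcm-rs", canonical, "N_rs", [10.0])
        assert len(result.states) == 1
        assert result.states[0].t_d_srs == pytest.approx(362.10, abs=5e-3)

    def test_infeasible_points_recorded_not_fatal(self, canonical):
        grid = [2000.0, 3000.0, 1.0e4]  # 2000 s is beyond the SRS-M boundary
        result = pc.sweep("sspcm-srs-m", canonical, "t_d_srs", grid)
        assert len(result.states) == 3
        assert result.states[0] is None or not result.states[0].feasible
        assert result.states[2].feasible

    def test_grid_must_increase(self, canonical):
        with pytest.raises(ValueError):
            pc.sweep("sspcm-rs", canonical, "N_rs", [2.0, 1.0])

    def test_frame_has_stable_columns(self, canonical):
        frame = pc.sweep("sspcm-rs+lip", canonical, "t_d_srs",
                         [400.0, 500.0]).to_frame()
        for col in ("model_id", "t_d_srs", "N_rs", "m_tot_g", "feasible"):
            assert col in frame.columns


def test_bit_identical_determinism(canonical):
    a = pc.solve("sspcm-srs-m", canonical, t_d=2600.0)
    b = pc.solve("sspcm-srs-m", canonical, t_d=2600.0)
    assert a.t_d_srs == b.t_d_srs
    assert a.counts == b.counts
    assert a.m_tot_g == b.m_tot_g and a.volume_um3 == b.volume_um3
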