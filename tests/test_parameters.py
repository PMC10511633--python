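"""Parameter loading, validation, round-trips and calibration arithmetic."""

import math

import pytest

import protocell as pc
from protocell.parameters import (
    DEFAULT_COUPLINGS,
    CalibrationError,
    ConfigurationError,
    ReferenceError_,
    ValidationError,
)


class TestLoading:
    def test_defaults_fill_missing_couplings(self, minimal_config):
        params = pc.load_parameters(minimal_config)
        for name, value in DEFAULT_COUPLINGS.items():
            assert params.coupling(name) == value

    def test_geometry_optional_for_membrane_free_use(self, minimal_config):
        params = pc.load_parameters(minimal_config)
        assert params.geometry_available is False
        # membrane-free models still build and solve
        assert pc.solve("sspcm-rs", params, n_rs=1.0).t_d_srs == pytest.approx(
            7336.0 / 20.26
        )

    def test_negative_rate_names_offending_species(self, minimal_config):
        minimal_config["species"]["enz"] = {
            "role": "enzyme",
            "n_monomers": 300,
            "monomer_kind": "aa",
            "k_rate": -1.0,
        }
        with pytest.raises(ValidationError, match="enz"):
            pc.load_parameters(minimal_config)

    def test_missing_mandatory_section(self):
        with pytest.raises(ConfigurationError, match="species"):
            pc.load_parameters({"geometry": {}})

    def test_unknown_enzyme_reference(self, minimal_config):
        minimal_config["pathways"] = {
            "PW2": {"length_reactions": 10, "enzyme": "nope", "product_monomer": "aa"}
        }
        with pytest.raises(ReferenceError_, match="nope"):
            pc.load_parameters(minimal_config)

    def test_footprint_requires_membrane_localization(self, minimal_config):
        minimal_config["species"]["rpc"]["footprint_nm2"] = 1.0
        with pytest.raises(ValidationError, match="footprint"):
            pc.load_parameters(minimal_config)

    def test_mass_consistency_check(self, minimal_config):
        # 7336 aa at ~110 Da each is ~8e5 Da; 10 Da is inconsistent
        minimal_config["species"]["rpc"]["mass_da"] = 10.0
        with pytest.raises(ValidationError, match="inconsistent"):
            pc.load_parameters(minimal_config)

    @pytest.mark.parametrize("fixture_name", ["toy_analytic", "toy_dna"])
    def test_roundtrip(self, fixture_name, request):
        params = request.getfixturevalue(fixture_name).params
        text = pc.dump_parameters(params)
        assert pc.load_parameters(text) == params

    def test_canonical_roundtrip(self, canonical):
        assert pc.load_parameters(pc.dump_parameters(canonical)) == canonical

    def test_json_is_accepted(self, minimal_config):
        import json

        params = pc.load_parameters(json.dumps(minimal_config))
        assert "rpc" in params.species


class TestCouplingValidation:
    def test_complete_set_passes_for_minimal_medium_model(self, canonical):
        checks = pc.validate_couplings(canonical, "sspcm-srs-m")
        assert checks and all(c.passed for c in checks)

    def test_missing_genome_reported(self, toy_analytic):
        checks = pc.validate_couplings(toy_analytic.params, "sspcm-rs+dna")
        failed = [c for c in checks if not c.passed]
        assert any("genome" in c.message or "dna" in c.name for c in failed)

    def test_nonstandard_replisome_pair_warns(self, canonical):
        params = canonical.model_copy(deep=True)
        params.couplings["rc_per_genome"] = 3.0
        checks = pc.validate_couplings(params, "sspcm-srs-m")
        warn = [c for c in checks if c.name == "rc_per_genome"]
        assert warn and warn[0].level == "warning" and warn[0].passed


class TestCalibration:
    def test_doubling_time_anchor_rescales_composition(self, minimal_config):
        params = pc.load_parameters(minimal_config)
        out = pc.calibrate_fallback(params, {"t_d_rs": 362.10})
        assert out.species["rpc"].n_monomers == pytest.approx(362.10 * 20.26)
        assert out.species["rpc"].provenance.value == "calibrated"
        # original untouched
        assert params.species["rpc"].n_monomers == 7336.0

    def test_pathway_anchor_sets_time_coefficient(self, toy_analytic):
        params = toy_analytic.params.model_copy(deep=True)
        params.pathways["PW2"].length_reactions = 200.0
        out = pc.calibrate_fallback(
            params, {"t_d_rs": 362.10, "t_d_rs_pw2": 962.10}
        )
        enz = out.species["enz"]
        assert enz.n_monomers / enz.k_rate == pytest.approx(3.0)  # (962.1-362.1)/200

    def test_empty_anchors_identity(self, canonical):
        assert pc.calibrate_fallback(canonical, {}) == canonical

    def test_idempotent(self, minimal_config):
        params = pc.load_parameters(minimal_config)
        once = pc.calibrate_fallback(params, {"t_d_rs": 400.0})
        twice = pc.calibrate_fallback(once, {"t_d_rs": 400.0})
        assert once.species["rpc"].n_monomers == twice.species["rpc"].n_monomers
        assert once.source_note == twice.source_note

    def test_inconsistent_anchors_rejected(self, toy_analytic):
        with pytest.raises(CalibrationError, match="residual|inconsistent"):
            pc.calibrate_fallback(
                toy_analytic.params, {"t_d_rs": 500.0, "t_d_rs_pw2": 100.0}
            )

    def test_unknown_observable_rejected(self, canonical):
        with pytest.raises(CalibrationError, match="unknown"):
            pc.calibrate_fallback(canonical, {"not_an_observable": 1.0})


def test_canonical_provenance_labels(canonical):
    """Calibrated entries are labeled; well-known compositions are not."""
    assert canonical.species["rpc"].provenance.value == "calibrated"
    assert canonical.species["dna"].provenance.value == "specific"
    assert "calibrated" in canonical.source_note.lower()


def test_calibrated_set_builds_every_model(canonical):
    """Any parameter set whose couplings validate can build those models."""
    for model_id in pc.MODELS:
        checks = pc.validate_couplings(canonical, model_id)
        assert all(c.passed for c in checks)
        system = pc.build_model(model_id, canonical, ("N_rs", 100.0))
        assert pc.degrees_of_freedom_report(system).determined
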