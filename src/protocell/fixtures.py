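"""Deterministic toy parameter sets with hand-computable solutions.

These fixtures exercise every balance archetype without the canonical
parameter file: the analytic fixture's doubling times follow from a few
lines of arithmetic, the membrane fixture's growth boundary is cross-checked
against a brute-force grid scan, and the genome fixture has an exactly
computable replication-feasibility threshold.  Nothing here is random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from .models import ModelSpec
from .parameters import ParameterSet, load_parameters


@dataclass(frozen=True)
class Fixture:
    kind: str
    params: ParameterSet
    model: str | ModelSpec
    expected: dict[str, Any]
    oracle: str


def _toy_analytic() -> Fixture:
    """RPC + PW2 with round numbers: t_d = 100 + 300*10/100 = 130 s."""
    params = load_parameters(
        {
            "species": {
                "rpc": {
                    "role": "self_replicator",
                    "n_monomers": 1000,
                    "monomer_kind": "aa",
                    "k_rate": 10.0,
                },
                "enz": {
                    "role": "enzyme",
                    "n_monomers": 300,
                    "monomer_kind": "aa",
                    "k_rate": 100.0,
                },
            },
            "pathways": {
                "PW2": {
                    "length_reactions": 10,
                    "enzyme": "enz",
                    "product_monomer": "aa",
                }
            },
            "source_note": "toy_analytic fixture (synthetic)",
        }
    )
    return Fixture(
        kind="toy_analytic",
        params=params,
        model="sspcm-rs+aa",
        expected={
            "t_d_rs": 100.0,  # 1000 aa / 10 aa s^-1
            "t_d_rs_pw2": 130.0,  # 100 + 300*10/100
            "enz_per_rs": 1.0,  # l * k_rs / k_enz = 10*10/100
        },
        oracle="hand arithmetic on the protein-doubling and pathway balances",
    )


_TOY_MEMBRANE_SPEC = ModelSpec(
    id="toy-membrane",
    description="synthetic minimal membrane model: RPC, LPE, lipids, ETC, "
    "transporter; linear energy demand from translation",
    included_species=frozenset({"rpc", "lpe", "lip", "etc", "tp"}),
    included_pathways=frozenset(),
    has_membrane=True,
    has_energy=True,
    medium="minimal",
    driver_options=("t_d_srs", "N_rs"),
)


def _toy_membrane() -> Fixture:
    params = load_parameters(
        {
            "species": {
                "rpc": {
                    "role": "self_replicator",
                    "n_monomers": 1000,
                    "monomer_kind": "aa",
                    "k_rate": 10.0,
                },
                "lpe": {
                    "role": "enzyme",
                    "n_monomers": 200,
                    "monomer_kind": "aa",
                    "k_rate": 1.0,
                },
                "lip": {
                    "role": "lipid",
                    "mass_da": 700.0,
                    "localization": "membrane",
                    "footprint_nm2": 0.5,
                },
                "etc": {
                    "role": "membrane_protein",
                    "n_monomers": 1000,
                    "monomer_kind": "aa",
                    "k_rate": 100.0,
                    "localization": "membrane",
                    "footprint_nm2": 10.0,
                },
                "tp": {
                    "role": "membrane_protein",
                    "n_monomers": 500,
                    "monomer_kind": "aa",
                    "k_rate": 100.0,
                    "localization": "membrane",
                    "footprint_nm2": 5.0,
                },
            },
            "geometry": {
                "mode": "fixed_shape",
                "aspect_ratio": 2.0,
                "area_per_lipid_nm2": 0.5,
                "water_mass_fraction": 0.6,
                "density_g_per_cm3": 1.0,
            },
            "energy": {
                "atp_per_aa_polymerized": 4.0,
                "atp_per_nt_polymerized": 1.0,
                "atp_per_dnt_polymerized": 1.0,
                "atp_per_lipid": 1.0,
                "atp_per_transport": 1.0,
                "etc_atp_rate": 100.0,
                "atp_per_substrate_oxidized": 20.0,
            },
            "source_note": "toy_membrane fixture (synthetic)",
        }
    )
    return Fixture(
        kind="toy_membrane",
        params=params,
        model=_TOY_MEMBRANE_SPEC,
        expected={
            # the boundary itself has no closed form; tests recompute it
            # with an independent fine-grid scan over t_d
            "t_d_rs": 100.0,  # bare-replicator floor, 1000 aa / 10 aa s^-1
        },
        oracle="growth boundary cross-checked against a fine grid scan over t_d",
    )


def _toy_dna() -> Fixture:
    """RPC + replisome pair + 1e6-nt genome + PW3 (l=5).

    At t_d = 1000 s the per-replisome rate is 1e6/(2*1000) = 500 nt/s,
    exactly the replisome cap: faster growth is infeasible.  The protein
    balance gives N_rs = (2*2000 + 300*5*1e6/(t*100)) / (t*10 - 1000).
    """
    params = load_parameters(
        {
            "species": {
                "rpc": {
                    "role": "self_replicator",
                    "n_monomers": 1000,
                    "monomer_kind": "aa",
                    "k_rate": 10.0,
                },
                "rc": {
                    "role": "polymerase",
                    "n_monomers": 2000,
                    "monomer_kind": "aa",
                    "k_rate": 500.0,
                },
                "enz": {
                    "role": "enzyme",
                    "n_monomers": 300,
                    "monomer_kind": "aa",
                    "k_rate": 100.0,
                },
                "dna": {
                    "role": "genome",
                    "n_monomers": 1.0e6,
                    "monomer_kind": "dnt",
                },
            },
            "pathways": {
                "PW3": {
                    "length_reactions": 5,
                    "enzyme": "enz",
                    "product_monomer": "dnt",
                }
            },
            "source_note": "toy_dna fixture (synthetic)",
        }
    )
    t = 1000.0
    n_enz3 = 5 * (1.0e6 / t) / 100.0  # 50
    n_rs = (2 * 2000.0 + 300.0 * n_enz3) / (t * 10.0 - 1000.0)
    return Fixture(
        kind="toy_dna",
        params=params,
        model="sspcm-rs+dna",
        expected={
            "feasibility_t_threshold": 1000.0,  # n_dna/(2*k_rc)
            "n_enz_pw3_at_1000s": n_enz3,
            "n_rs_at_1000s": n_rs,
        },
        oracle="hand arithmetic on replication, pathway and protein balances",
    )


_FIXTURES = {
    "toy_analytic": _toy_analytic,
    "toy_membrane": _toy_membrane,
    "toy_dna": _toy_dna,
}


def generate_fixtures(kind: str) -> Fixture:
    """Return one of the deterministic toy fixtures by name."""
    if kind not in _FIXTURES:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[kind]()
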