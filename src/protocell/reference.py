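"""Published reference values used for side-by-side comparison tables.

``PUBLISHED_TABLE1`` holds the doubling-time-limit table as printed
(minimal t_d_srs in seconds, maximal N_rs in molecules/cell, limit type and
slower-growth factors).  Finite maximal-N_rs entries of *asymptotic* models
encode an unpublished convergence convention; they are flagged
``convention`` here and excluded from delta checks (this package reports
its own, documented tolerance convention for those — see docs/methods.md).
"""

from __future__ import annotations

import math

PUBLISHED_TABLE1: dict[str, dict] = {
    "sspcm-rs": {
        "t_d_min": 362.10, "n_rs_max": math.inf, "convention": False,
        "limit_type": "molecular_properties", "slower_growth": (),
    },
    "sspcm-rs+aa": {
        "t_d_min": 962.10, "n_rs_max": math.inf, "convention": False,
        "limit_type": "molecular_properties", "slower_growth": (),
    },
    "sspcm-rs+aa+prot": {
        "t_d_min": 962.10, "n_rs_max": math.inf, "convention": False,
        "limit_type": "molecular_properties",
        "slower_growth": ("unspecified_protein",),
    },
    "sspcm-rs+aa+rna": {
        "t_d_min": 1127.15, "n_rs_max": math.inf, "convention": False,
        "limit_type": "molecular_properties", "slower_growth": (),
    },
    "sspcm-rs+aa+rna+lip": {
        "t_d_min": 1127.15, "n_rs_max": 6.19e14, "convention": True,
        "limit_type": "molecular_properties", "slower_growth": ("cell_geometry",),
    },
    "sspcm-rs+lip": {
        "t_d_min": 362.10, "n_rs_max": 1.16e28, "convention": True,
        "limit_type": "molecular_properties", "slower_growth": ("cell_geometry",),
    },
    "sspcm-rs+aa+rna+lip+mprot": {
        "t_d_min": 2462.68, "n_rs_max": 36699.0, "convention": False,
        "limit_type": "membrane_surface_area", "slower_growth": ("cell_geometry",),
    },
    "sspcm-srs-m": {
        "t_d_min": 2474.27, "n_rs_max": 36992.0, "convention": False,
        "limit_type": "membrane_surface_area",
        "slower_growth": ("cell_geometry", "dna_replication"),
    },
    "sspcm-rs+dna": {
        "t_d_min": 362.10, "n_rs_max": 7.82e16, "convention": True,
        "limit_type": "molecular_properties", "slower_growth": ("dna_replication",),
    },
    "sspcm-srs-r": {
        "t_d_min": 936.40, "n_rs_max": 24681.0, "convention": False,
        "limit_type": "membrane_surface_area",
        "slower_growth": ("cell_geometry", "dna_replication"),
    },
}

#: worked operating points quoted alongside the published table
PUBLISHED_POINTS = {
    "lip_at_1300s": {"model": "sspcm-rs+aa+rna+lip", "t_d": 1300.0, "n_rs": 8.17},
    "srsm_at_1e4s": {"model": "sspcm-srs-m", "t_d": 1.0e4, "n_rs": 17.45},
    "mprot_at_3000s": {
        "model": "sspcm-rs+aa+rna+lip+mprot", "t_d": 3.0e3, "n_rs": 2.22,
    },
    "rsdna_at_1e4s": {
        "model": "sspcm-rs+dna", "t_d": 1.0e4, "n_rs": 3.4, "m_tot_g": 1.63e-14,
    },
}
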