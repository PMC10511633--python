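"""Input-parameter handling for proto-cell self-reproduction models.

A :class:`ParameterSet` fully determines every model: the molecular species
of the self-reproduction system (SRS), the linear biosynthesis pathways
PW1-PW5, the cell geometry, the energy stoichiometries and the couplings
that tie component counts to the ribosome count.

Values are loaded from YAML or JSON documents (schema below), validated,
and carry a provenance label per species:

* ``average`` / ``specific`` / ``precise`` / ``approximate`` / ``generic``
  mirror the conformance vocabulary used for the underlying E. coli data;
* ``calibrated`` marks values that were back-computed from published
  headline results (doubling-time anchors) rather than transcribed from
  molecular data.

Units follow :mod:`protocell.units` throughout.
"""

from __future__ import annotations

import copy
import logging
import math
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .units import GRAMS_PER_DALTON

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: mean mass of a polymerized monomer, Da (overridable per parameter file)
DEFAULT_MONOMER_MASS_DA = {"aa": 110.0, "nt": 324.0, "dnt": 308.0}

#: couplings applied when a parameter file omits them
DEFAULT_COUPLINGS = {
    "trna_per_ribosome": 8.0,
    "mrna_per_ribosome": 0.2,
    "rrna_per_ribosome": 1.0,
    "rc_per_genome": 2.0,
    "genomes_per_cell": 1.0,
}


class ConfigurationError(ValueError):
    """A parameter document is missing a mandatory section or field."""


class ValidationError(ValueError):
    """A parameter value violates an invariant (sign, range, consistency)."""


class ReferenceError_(Exception):
    """A pathway or coupling references a species that does not exist.

    Not a ValueError subclass so that it propagates unwrapped out of
    pydantic model validation.
    """


class CalibrationError(ValueError):
    """Calibration anchors are inconsistent or reference unknown observables."""


class Role(str, Enum):
    self_replicator = "self_replicator"
    polymerase = "polymerase"
    enzyme = "enzyme"
    rna = "rna"
    lipid = "lipid"
    membrane_protein = "membrane_protein"
    genome = "genome"


class Localization(str, Enum):
    cytoplasm = "cytoplasm"
    membrane = "membrane"


class Provenance(str, Enum):
    average = "average"
    specific = "specific"
    precise = "precise"
    approximate = "approximate"
    generic = "generic"
    calibrated = "calibrated"


class MonomerKind(str, Enum):
    aa = "aa"
    nt = "nt"
    dnt = "dnt"
    lipid_precursor = "lipid_precursor"


#: roles whose members are polymers built from counted monomers
_POLYMERIC_ROLES = {
    Role.self_replicator,
    Role.polymerase,
    Role.enzyme,
    Role.rna,
    Role.membrane_protein,
    Role.genome,
}

#: roles that catalyse a process and therefore need a working rate
_CATALYTIC_ROLES = {
    Role.self_replicator,
    Role.polymerase,
    Role.enzyme,
    Role.membrane_protein,
}


class SpeciesSpec(BaseModel):
    """One molecular species or complex of the SRS.

    ``n_monomers`` is the number of polymerized monomers per molecule or
    complex (amino acids for proteins, nucleotides for nucleic acids; both
    strands are counted for the bihelical genome).  ``k_rate`` is the
    apparent working rate: monomers s^-1 for polymerases and the ribosome,
    reactions s^-1 for enzymes, ATP s^-1 for the ETC and substrate s^-1
    for transporters.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    role: Role
    n_monomers: Optional[float] = None
    monomer_kind: Optional[MonomerKind] = None
    k_rate: Optional[float] = None
    mass_da: Optional[float] = None
    localization: Localization = Localization.cytoplasm
    footprint_nm2: Optional[float] = None
    provenance: Provenance = Provenance.generic

    @model_validator(mode="after")
    def _check(self) -> "SpeciesSpec":
        if self.role in _POLYMERIC_ROLES:
            if self.n_monomers is None or self.n_monomers <= 0:
                raise ValidationError(
                    f"species {self.id!r}: polymeric species need n_monomers > 0"
                )
        if self.role in _CATALYTIC_ROLES:
            if self.k_rate is None or self.k_rate <= 0:
                raise ValidationError(
                    f"species {self.id!r}: catalytic species need k_rate > 0"
                )
        if (self.footprint_nm2 is not None) != (
            self.localization is Localization.membrane
        ):
            raise ValidationError(
                f"species {self.id!r}: footprint_nm2 must be given iff the "
                "species is membrane-localized"
            )
        if self.footprint_nm2 is not None and self.footprint_nm2 <= 0:
            raise ValidationError(f"species {self.id!r}: footprint_nm2 must be > 0")
        if self.mass_da is not None and self.mass_da <= 0:
            raise ValidationError(f"species {self.id!r}: mass_da must be > 0")
        return self


class PathwaySpec(BaseModel):
    """A linear chain of identical unidirectional reactions (PW1-PW5).

    Every reaction of the chain carries the same flux and is catalysed by
    the same number of enzyme molecules, so the chain is fully described
    by its length in reactions (fractional lengths allowed), the enzyme
    species and the ATP cost per reaction.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    length_reactions: float = Field(ge=0)
    enzyme: str
    product_monomer: str  # aa | nt | dnt | lipid_precursor | metabolic_intermediate
    atp_per_reaction: float = Field(default=0.0, ge=0)


class GeometryParams(BaseModel):
    """Cell shape (cylinder with spherical caps) and membrane constants.

    Two shape conventions are supported.  ``fixed_shape`` (canonical)
    scales the spherocylinder isotropically at a constant aspect ratio, so
    the surface-to-volume ratio vanishes for large cells.  ``fixed_radius``
    keeps the radius constant, varies the cylinder length, and falls back
    to a sphere below the minimal cylinder volume.
    """

    model_config = ConfigDict(extra="forbid")

    mode: str = "fixed_shape"  # fixed_shape | fixed_radius
    aspect_ratio: float = Field(default=3.0, gt=0)  # total length / diameter
    radius_um: float = Field(default=0.4, gt=0)
    area_per_lipid_nm2: float = Field(gt=0)
    leaflets: int = 2
    water_mass_fraction: float = Field(gt=0, lt=1)
    density_g_per_cm3: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "GeometryParams":
        if self.mode not in ("fixed_shape", "fixed_radius"):
            raise ValidationError(f"unknown geometry mode {self.mode!r}")
        if self.leaflets != 2:
            raise ValidationError("the membrane is a bilayer: leaflets must be 2")
        if self.mode == "fixed_shape" and self.aspect_ratio < 1:
            raise ValidationError("aspect_ratio must be >= 1 (1 is a sphere)")
        return self


class EnergyParams(BaseModel):
    """ATP stoichiometries of polymerization, biosynthesis and transport."""

    model_config = ConfigDict(extra="forbid")

    atp_per_aa_polymerized: float = Field(ge=0)
    atp_per_nt_polymerized: float = Field(ge=0)
    atp_per_dnt_polymerized: float = Field(ge=0)
    atp_per_lipid: float = Field(ge=0)
    atp_per_transport: float = Field(ge=0)
    etc_atp_rate: float = Field(gt=0)
    #: substrate molecules entering PW1 per monomer synthesized downstream
    substrates_per_monomer: float = Field(default=1.0, ge=0)
    #: ATP produced by the ETC per substrate molecule oxidized
    atp_per_substrate_oxidized: float = Field(gt=0)


class ParameterSet(BaseModel):
    """A complete, validated input-parameter set for all models."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    source_note: str = ""
    species: dict[str, SpeciesSpec]
    pathways: dict[str, PathwaySpec] = Field(default_factory=dict)
    geometry: Optional[GeometryParams] = None
    energy: Optional[EnergyParams] = None
    couplings: dict[str, float] = Field(default_factory=dict)
    monomer_mass_da: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MONOMER_MASS_DA)
    )
    #: relative tolerance for the mass vs n_monomers consistency check
    mass_consistency_rtol: float = 0.5

    @property
    def geometry_available(self) -> bool:
        return self.geometry is not None

    @model_validator(mode="after")
    def _check(self) -> "ParameterSet":
        for pid, pw in self.pathways.items():
            if pw.enzyme not in self.species:
                raise ReferenceError_(
                    f"pathway {pid!r} references unknown enzyme species {pw.enzyme!r}"
                )
        if self.couplings.get("rrna_per_ribosome", 1.0) != 1.0:
            # assembled rRNA (5S+16S+23S at 1:1:1) pairs one-to-one with RPC
            raise ValidationError("rrna_per_ribosome must be 1")
        for sp in self.species.values():
            if (
                sp.mass_da is not None
                and sp.n_monomers is not None
                and sp.monomer_kind is not None
                and sp.monomer_kind != MonomerKind.lipid_precursor
            ):
                expected = sp.n_monomers * self.monomer_mass_da[sp.monomer_kind.value]
                if not math.isclose(
                    sp.mass_da, expected, rel_tol=self.mass_consistency_rtol
                ):
                    raise ValidationError(
                        f"species {sp.id!r}: mass_da={sp.mass_da} inconsistent with "
                        f"n_monomers x mean monomer mass = {expected:.1f} Da"
                    )
        return self

    # -- convenience accessors used by the balance assembler ---------------

    def species_mass_da(self, sid: str) -> float:
        """Molecular mass in Da, from mass_da or n_monomers x monomer mass."""
        sp = self.species[sid]
        if sp.mass_da is not None:
            return sp.mass_da
        if sp.n_monomers is not None and sp.monomer_kind is not None:
            return sp.n_monomers * self.monomer_mass_da[sp.monomer_kind.value]
        raise ValidationError(f"species {sid!r}: no mass derivable")

    def species_mass_g(self, sid: str) -> float:
        return self.species_mass_da(sid) * GRAMS_PER_DALTON

    def coupling(self, name: str) -> float:
        if name in self.couplings:
            return self.couplings[name]
        return DEFAULT_COUPLINGS[name]


# ---------------------------------------------------------------------------
# loading / serialization
# ---------------------------------------------------------------------------

_MANDATORY_SECTIONS = ("species",)


def _inject_ids(doc: Mapping[str, Any]) -> dict[str, Any]:
    """Copy the document, writing mapping keys into 'id' fields."""
    out = copy.deepcopy(dict(doc))
    for section in ("species", "pathways"):
        if section in out and isinstance(out[section], Mapping):
            out[section] = {
                key: {"id": key, **val} for key, val in out[section].items()
            }
    return out


def load_parameters(source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Load and validate a ParameterSet from YAML/JSON text, a file or a dict.

    Missing optional couplings are filled from :data:`DEFAULT_COUPLINGS`
    (one log line per default applied).  Geometry and energy sections may
    be absent when only membrane-free models will be built.
    """
    if isinstance(source, Mapping):
        doc: Any = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, Mapping):
        raise ConfigurationError("parameter document did not parse to a mapping")
    for section in _MANDATORY_SECTIONS:
        if section not in doc or not doc[section]:
            raise ConfigurationError(f"missing mandatory section {section!r}")
    doc = _inject_ids(doc)
    couplings = dict(doc.get("couplings") or {})
    for name, value in DEFAULT_COUPLINGS.items():
        if name not in couplings:
            couplings[name] = value
            logger.info("coupling %s not given; default %s applied", name, value)
    doc["couplings"] = couplings
    try:
        params = ParameterSet(**doc)
    except (ValidationError, ReferenceError_, ConfigurationError):
        raise
    except Exception as exc:  # pydantic wraps field errors
        raise ValidationError(str(exc)) from exc
    if params.geometry is None:
        logger.info("no geometry section: only membrane-free models available")
    return params


def dump_parameters(params: ParameterSet, path: str | Path | None = None) -> str:
    """Serialize a ParameterSet to canonical YAML (round-trips exactly)."""
    doc = params.model_dump(mode="json", exclude_none=True)
    for section in ("species", "pathways"):
        if section in doc:
            for key in doc[section]:
                doc[section][key].pop("id", None)
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# coupling validation per model
# ---------------------------------------------------------------------------


class CheckResult(BaseModel):
    name: str
    passed: bool
    level: str = "error"  # error | warning
    message: str = ""


def validate_couplings(params: ParameterSet, model_id: str) -> list[CheckResult]:
    """Check that every species/pathway/coupling a model needs is present.

    Returns machine-readable pass/fail records; never raises — callers
    decide how to react.
    """
    from .models import get_model_spec  # local import to avoid a cycle

    spec = get_model_spec(model_id)
    checks: list[CheckResult] = []

    def add(name: str, passed: bool, message: str = "", level: str = "error") -> None:
        checks.append(CheckResult(name=name, passed=passed, level=level, message=message))

    for sid in sorted(spec.included_species):
        add(
            f"species:{sid}",
            sid in params.species,
            "" if sid in params.species else f"species {sid!r} missing",
        )
    if spec.has_dna:
        have_genome = any(
            s.role is Role.genome for s in params.species.values()
        )
        add("genome_species", have_genome, "" if have_genome else "genome species missing")
        rc = params.coupling("rc_per_genome")
        add(
            "rc_per_genome",
            True,
            "" if rc == 2 else f"rc_per_genome={rc} deviates from the canonical pair",
            level="info" if rc == 2 else "warning",
        )
    for pid in sorted(spec.included_pathways):
        add(
            f"pathway:{pid}",
            pid in params.pathways,
            "" if pid in params.pathways else f"pathway {pid!r} missing",
        )
    if spec.has_membrane:
        add(
            "geometry",
            params.geometry is not None,
            "" if params.geometry is not None else "geometry section missing",
        )
    if spec.has_energy:
        add(
            "energy",
            params.energy is not None,
            "" if params.energy is not None else "energy section missing",
        )
    return checks


# ---------------------------------------------------------------------------
# calibration fallback
# ---------------------------------------------------------------------------

#: closed-form observables a calibration anchor may reference
_ANCHOR_OBSERVABLES = ("t_d_rs", "t_d_rs_pw2")


def calibrate_fallback(
    params: ParameterSet, anchors: Mapping[str, float]
) -> ParameterSet:
    """Rescale the minimal number of free parameters to match anchors exactly.

    Supported anchors (closed-form observables):

    * ``t_d_rs``      — doubling time of the bare ribosomal protein complex,
      n_rpc / k_rs; matched by rescaling n_rpc at fixed k_rs.
    * ``t_d_rs_pw2``  — doubling time with the amino-acid pathway,
      t_d_rs + n_enz * l_PW2 / k_enz; matched by rescaling n_enz at fixed
      k_enz and l_PW2 (the per-reaction time coefficient n_enz/k_enz is the
      free quantity).

    The input set is never modified; the returned copy records the
    calibration in ``source_note``.  Calibration is idempotent.
    """
    for name in anchors:
        if name not in _ANCHOR_OBSERVABLES:
            raise CalibrationError(
                f"anchor {name!r} references an unknown observable; "
                f"known: {_ANCHOR_OBSERVABLES}"
            )
    if not anchors:
        return params.model_copy(deep=True)

    out = params.model_copy(deep=True)
    notes = []
    if "t_d_rs" in anchors:
        rpc = out.species["rpc"]
        new_n = anchors["t_d_rs"] * rpc.k_rate
        if not math.isclose(new_n, rpc.n_monomers or 0.0, rel_tol=0, abs_tol=1e-12):
            rpc.n_monomers = new_n
            if rpc.mass_da is not None:
                rpc.mass_da = None  # re-derived from monomers
            rpc.provenance = Provenance.calibrated
            notes.append(f"n_rpc={new_n:.6g} from t_d_rs={anchors['t_d_rs']}")
    if "t_d_rs_pw2" in anchors:
        if "PW2" not in out.pathways:
            raise CalibrationError("anchor t_d_rs_pw2 requires pathway PW2")
        rpc = out.species["rpc"]
        t_rs = (rpc.n_monomers or 0.0) / rpc.k_rate
        target = anchors["t_d_rs_pw2"] - t_rs
        if target < 0:
            raise CalibrationError(
                f"inconsistent anchors: t_d_rs_pw2 < t_d_rs (residual {target:.4g} s)"
            )
        pw2 = out.pathways["PW2"]
        enz = out.species[pw2.enzyme]
        # free quantity is the time coefficient n_enz/k_enz
        coeff = target / pw2.length_reactions
        new_n = coeff * enz.k_rate
        if not math.isclose(new_n, enz.n_monomers or 0.0, rel_tol=0, abs_tol=1e-12):
            enz.n_monomers = new_n
            if enz.mass_da is not None:
                enz.mass_da = None
            enz.provenance = Provenance.calibrated
            notes.append(
                f"n_enz={new_n:.6g} (n_enz/k_enz={coeff:.6g} s) "
                f"from t_d_rs_pw2={anchors['t_d_rs_pw2']}"
            )
    if notes:
        out.source_note = (out.source_note + "; " if out.source_note else "") + (
            "calibrated: " + ", ".join(notes)
        )
    return ParameterSet(**out.model_dump())  # re-validate


# ---------------------------------------------------------------------------
# packaged canonical parameters
# ---------------------------------------------------------------------------


def canonical_parameters() -> ParameterSet:
    """The packaged default parameter set.

    Molecular compositions and rates follow E. coli K-12 conventions where
    a well-known value exists; the remaining inputs (pathway lengths, a few
    membrane and energy constants) are calibrated against the published
    doubling-time anchors and labeled ``calibrated`` — see the provenance
    fields and ``source_note`` inside the file.
    """
    path = Path(__file__).parent / "data" / "canonical.yaml"
    return load_parameters(path)
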