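"""Typed parameter database for the solubility model.

Houses the melting properties, the PC-SAFT pure-component parameter sets
(including association schemes and the water segment-diameter temperature
rule), the temperature-linear binary interaction parameters

    k_ij(T) = k_slope * T + k_intercept

and the cocrystal solubility-product definitions.  A complete database for
the nicotinamide (NA) / succinic acid (SA) 2:1 cocrystal in water, ethanol,
acetonitrile and ethyl acetate ships with the package and is loaded with
``load_parameter_db("packaged")``.

All temperatures are kelvin, energies are expressed as ε/k_B in kelvin,
segment diameters in ångström, molar masses in g/mol, fusion enthalpies in
kJ/mol and Δc_p in J/(mol K).
"""

from __future__ import annotations

import json
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: CODATA-rounded molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314


class ValidationError(ValueError):
    """A parameter record violates one of its invariants."""


class ResolutionError(KeyError):
    """A record references a component id that is not in the database."""


class PureComponentParams(BaseModel):
    """PC-SAFT pure-component parameter set for one substance.

    ``n_donor_sites``/``n_acceptor_sites`` encode the association scheme:
    1/1 for a two-site (2B-like) self-associating solvent, 2/2 for a
    four-site solute.  ``induced_association`` marks polar but
    non-self-associating solvents that are given zero association energy and
    an association volume of 0.01 so that they cross-bond with associating
    partners but not with themselves.
    """

    model_config = ConfigDict(frozen=True)

    component_id: str
    molar_mass: float
    segment_number: float
    segment_diameter: float
    dispersion_energy: float
    assoc_energy: float = 0.0
    assoc_volume: float = 0.0
    n_donor_sites: int = 0
    n_acceptor_sites: int = 0
    induced_association: bool = False
    sigma_rule: Optional[str] = None

    @field_validator("molar_mass", "segment_diameter", "dispersion_energy")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if info.field_name == "dispersion_energy":
            if v < 0:
                raise ValueError(f"{info.field_name} must be >= 0, got {v}")
            return v
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("segment_number")
    @classmethod
    def _segments(cls, v: float) -> float:
        if v < 1:
            raise ValueError(f"segment_number must be >= 1, got {v}")
        return v

    @field_validator("assoc_volume")
    @classmethod
    def _kappa_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"assoc_volume must lie in [0, 1], got {v}")
        return v

    @field_validator("sigma_rule")
    @classmethod
    def _known_rule(cls, v: Optional[str]) -> Optional[str]:
        if v not in (None, "water"):
            raise ValueError(f"unknown sigma_rule {v!r}")
        return v

    @model_validator(mode="after")
    def _scheme_consistency(self) -> "PureComponentParams":
        if self.induced_association:
            if self.assoc_energy != 0.0 or self.assoc_volume != 0.01:
                raise ValueError(
                    "induced associator requires assoc_energy = 0 and "
                    "assoc_volume = 0.01"
                )
        if self.n_donor_sites == 0 and self.n_acceptor_sites == 0:
            if self.assoc_energy != 0.0:
                raise ValueError("component without sites must have assoc_energy = 0")
        if min(self.n_donor_sites, self.n_acceptor_sites) < 0:
            raise ValueError("site counts must be non-negative")
        return self

    @property
    def has_sites(self) -> bool:
        return self.n_donor_sites + self.n_acceptor_sites > 0

    def sigma_at(self, T: float) -> float:
        """Segment diameter at ``T`` (Å); applies the water rule if set."""
        return sigma_at_temperature(self, T)


class MeltingProperties(BaseModel):
    """Fusion properties entering the solid-liquid equilibrium equation."""

    model_config = ConfigDict(frozen=True)

    component_id: str
    melting_temperature: float
    fusion_enthalpy: float  # kJ/mol; converted to J/mol at the single use site
    delta_cp: float = 0.0

    @field_validator("melting_temperature")
    @classmethod
    def _tm(cls, v: float) -> float:
        if v <= 273.0:
            raise ValueError(f"melting_temperature must exceed 273 K, got {v}")
        return v

    @field_validator("fusion_enthalpy")
    @classmethod
    def _dh(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"fusion_enthalpy must be > 0, got {v}")
        return v

    @field_validator("delta_cp")
    @classmethod
    def _dcp(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"delta_cp must be >= 0, got {v}")
        return v


class BinaryInteraction(BaseModel):
    """Temperature-linear dispersion correction for one unordered pair."""

    model_config = ConfigDict(frozen=True)

    pair: tuple[str, str]
    k_slope: float = 0.0  # 1/K
    k_intercept: float = 0.0
    valid_T_range: tuple[float, float] = (273.15, 373.15)
    provenance: str = ""

    @model_validator(mode="after")
    def _check(self) -> "BinaryInteraction":
        a, b = self.pair
        if a == b:
            raise ValueError("pair members must be distinct")
        lo, hi = self.valid_T_range
        if lo > hi:
            raise ValueError("valid_T_range must be ordered")
        for T in (lo, hi):
            k = self.k_slope * T + self.k_intercept
            if not -1.0 < k < 1.0:
                raise ValueError(
                    f"k_ij({T}) = {k} outside (-1, 1) for pair {self.pair}"
                )
        return self

    def at(self, T: float) -> float:
        return kij_at_temperature(self, T)


class CocrystalDefinition(BaseModel):
    """Stoichiometry and solubility-product reference of one cocrystal."""

    model_config = ConfigDict(frozen=True)

    api_id: str
    cf_id: str
    nu_api: int
    nu_cf: int
    ks_ref: float
    t_ref: float
    dh_ref: float  # kJ/mol

    @model_validator(mode="after")
    def _check(self) -> "CocrystalDefinition":
        if self.nu_api < 1 or self.nu_cf < 1:
            raise ValueError("stoichiometric coefficients must be >= 1")
        if self.ks_ref <= 0 or self.t_ref <= 0:
            raise ValueError("ks_ref and t_ref must be positive")
        return self


class ParameterDB(BaseModel):
    """Complete, cross-referenced parameter set."""

    model_config = ConfigDict(frozen=True)

    components: tuple[PureComponentParams, ...]
    melting: tuple[MeltingProperties, ...] = ()
    binaries: tuple[BinaryInteraction, ...] = ()
    cocrystals: tuple[CocrystalDefinition, ...] = ()
    universal_gas_constant: float = GAS_CONSTANT

    @model_validator(mode="after")
    def _resolve(self) -> "ParameterDB":
        ids = {c.component_id for c in self.components}
        if len(ids) != len(self.components):
            raise ValueError("duplicate component ids")
        for m in self.melting:
            if m.component_id not in ids:
                raise ResolutionError(f"melting entry for unknown component {m.component_id!r}")
        for b in self.binaries:
            for cid in b.pair:
                if cid not in ids:
                    raise ResolutionError(f"binary entry references unknown component {cid!r}")
        for cc in self.cocrystals:
            for cid in (cc.api_id, cc.cf_id):
                if cid not in ids:
                    raise ResolutionError(f"cocrystal references unknown component {cid!r}")
        return self

    # -- lookups ---------------------------------------------------------

    def component(self, component_id: str) -> PureComponentParams:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise ResolutionError(f"unknown component {component_id!r}")

    def melting_of(self, component_id: str) -> MeltingProperties:
        for m in self.melting:
            if m.component_id == component_id:
                return m
        raise ResolutionError(f"no melting properties for {component_id!r}")

    def binary(self, id_a: str, id_b: str) -> BinaryInteraction:
        """Binary record for an unordered pair; zero record if absent."""
        key = frozenset((id_a, id_b))
        for b in self.binaries:
            if frozenset(b.pair) == key:
                return b
        return BinaryInteraction(pair=(id_a, id_b), provenance="default-zero")

    def kij(self, id_a: str, id_b: str, T: float, warn: bool = False) -> float:
        b = self.binary(id_a, id_b)
        return kij_at_temperature(b, T, warn=warn)

    def cocrystal(self, api_id: str = "NA", cf_id: str = "SA") -> CocrystalDefinition:
        for cc in self.cocrystals:
            if cc.api_id == api_id and cc.cf_id == cf_id:
                return cc
        raise ResolutionError(f"no cocrystal {api_id}/{cf_id} in database")

    def with_binary(self, id_a: str, id_b: str, k_slope: float, k_intercept: float) -> "ParameterDB":
        """Copy of the database with one binary pair replaced (or added)."""
        key = frozenset((id_a, id_b))
        kept = tuple(b for b in self.binaries if frozenset(b.pair) != key)
        new = BinaryInteraction(
            pair=(id_a, id_b),
            k_slope=k_slope,
            k_intercept=k_intercept,
            valid_T_range=(1.0, 1000.0),
            provenance="override",
        )
        return self.model_copy(update={"binaries": kept + (new,)})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(serialize_parameter_db(self))


# ---------------------------------------------------------------------------


def sigma_at_temperature(comp: PureComponentParams, T: float) -> float:
    """Temperature-dependent segment diameter in Å.

    For water the two-exponential expression
    σ(T) = 2.7927 + 10.11 exp(−0.01775 T) − 1.417 exp(−0.01146 T)
    is used; all other components have a constant diameter.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if comp.sigma_rule == "water":
        return 2.7927 + 10.11 * math.exp(-0.01775 * T) - 1.417 * math.exp(-0.01146 * T)
    return comp.segment_diameter


def kij_at_temperature(pair: BinaryInteraction, T: float, warn: bool = True) -> float:
    """Evaluate k_ij(T) = k_slope·T + k_intercept."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    lo, hi = pair.valid_T_range
    if warn and not lo <= T <= hi and (pair.k_slope != 0.0 or pair.k_intercept != 0.0):
        warnings.warn(
            f"k_ij for pair {pair.pair} evaluated at {T} K outside its "
            f"fitted range [{lo}, {hi}] K",
            stacklevel=2,
        )
    return pair.k_slope * T + pair.k_intercept


def serialize_parameter_db(db: ParameterDB) -> str:
    """JSON text that round-trips through :func:`load_parameter_db`."""
    payload = {
        "components": [
            {k: v for k, v in c.model_dump().items() if v is not None}
            for c in db.components
        ],
        "melting": [m.model_dump() for m in db.melting],
        "binaries": [
            {**b.model_dump(), "pair": list(b.pair), "valid_T_range": list(b.valid_T_range)}
            for b in db.binaries
        ],
        "cocrystals": [cc.model_dump() for cc in db.cocrystals],
    }
    return json.dumps(payload, indent=2)


def load_parameter_db(path: str | Path = "packaged") -> ParameterDB:
    """Load a parameter database from JSON, or the packaged default.

    The packaged default carries the full nicotinamide/succinic-acid system:
    melting properties of both solutes, PC-SAFT parameters for the solutes
    and the four (anti-)solvents, the temperature-linear binary interaction
    parameters, and the 2:1 cocrystal solubility-product reference.
    """
    if path == "packaged":
        text = resources.files("cocrysol.data").joinpath("parameters.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"parameter file does not parse as JSON: {exc}") from exc
    try:
        return ParameterDB(
            components=tuple(PureComponentParams(**c) for c in raw.get("components", [])),
            melting=tuple(MeltingProperties(**m) for m in raw.get("melting", [])),
            binaries=tuple(
                BinaryInteraction(
                    **{**b, "pair": tuple(b["pair"]), "valid_T_range": tuple(b["valid_T_range"])}
                )
                for b in raw.get("binaries", [])
            ),
            cocrystals=tuple(CocrystalDefinition(**c) for c in raw.get("cocrystals", [])),
        )
    except ResolutionError:
        raise
    except (ValueError, KeyError) as exc:
        raise ValidationError(str(exc)) from exc
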