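"""Model parameters, units, and configuration I/O.

The simulator mixes two natural unit systems: geometry and transport are
stated in SI lengths (m, s) while concentrations are conventionally quoted
in μmol·L⁻¹.  Internally every concentration is stored in μmol·m⁻³
(1 μmol·L⁻¹ = 10³ μmol·m⁻³) so that a permeability ``P`` (m·s⁻¹) times a
concentration difference gives a per-area molar flux (μmol·m⁻²·s⁻¹) that is
directly comparable to the carrier-mediated term ``T_m / SA_BBB``.

All public constructors accept the conventional (printed) units; helpers
named ``*_internal`` return the μmol·m⁻³ representation.
"""

from __future__ import annotations

import configparser
import io
import math
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "UMOL_PER_L_TO_UMOL_PER_M3",
    "DrugDoseParams",
    "BrainUnitGeometry",
    "TransportParams",
    "BBBParams",
    "BindingParams",
    "SimulationGrid",
    "ModelParameters",
    "derive_unit_length",
    "effective_diffusion",
    "convert_concentration",
    "convert_concentration_inverse",
    "load_config",
    "dump_config",
    "default_parameters",
]

#: 1 μmol·L⁻¹ expressed in μmol·m⁻³.
UMOL_PER_L_TO_UMOL_PER_M3 = 1.0e3

# Admissible literature ranges for the swept parameters.  Values outside
# these are rejected unless ``allow_out_of_range`` is set, because they are
# almost always a unit mistake rather than a deliberate scenario.
_RANGES = {
    "P": (1.0e-10, 1.0e-5),          # m s^-1
    "v_blood": (0.5e-6, 50.0e-6),    # m s^-1
    "k1_on": (1.0e-4, 1.0e2),        # (umol L^-1 s)^-1
    "k2_on": (1.0e-6, 1.0e1),
    "k1_off": (1.0e-6, 1.0e1),       # s^-1
    "k2_off": (1.0e-4, 1.0e3),
}


def _check_range(name: str, value: float, allow: bool) -> None:
    lo, hi = _RANGES[name]
    if not allow and not (lo <= value <= hi):
        raise ValueError(
            f"{name} = {value:g} outside admissible range [{lo:g}, {hi:g}]; "
            "set allow_out_of_range=True to override"
        )


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DrugDoseParams(_Frozen):
    """Oral dosing inputs driving the arteriole inlet concentration.

    The inlet follows the classical two-exponential (Bateman) profile of
    one-compartment first-order absorption and elimination.
    """

    F: float = Field(gt=0.0, le=1.0, description="bioavailability (-)")
    Dose: float = Field(gt=0.0, description="administered amount (μmol)")
    V_d: float = Field(gt=0.0, description="distribution volume (L)")
    K_a: float = Field(gt=0.0, description="absorption rate constant (s⁻¹)")
    K_e: float = Field(gt=0.0, description="elimination rate constant (s⁻¹)")

    @model_validator(mode="after")
    def _distinct_rates(self) -> "DrugDoseParams":
        if self.K_a == self.K_e:
            raise ValueError("K_a must differ from K_e (Bateman prefactor divides by K_a - K_e)")
        return self


class BrainUnitGeometry(_Frozen):
    """Cubic brain unit bounded by capillaries on its twelve edges.

    The edge length of the unit is the intercapillary distance plus one
    capillary diameter, ``l_cap + 2 r``; the cube is the same size along
    x, y and z.
    """

    r: float = Field(gt=0.0, description="capillary radius (m)")
    l_cap: float = Field(gt=0.0, description="intercapillary distance (m)")

    @property
    def unit_length(self) -> float:
        """Edge length x_r = y_r = z_r = l_cap + 2r (m)."""
        return self.l_cap + 2.0 * self.r

    # aliases matching the axis-specific names used in the equations
    @property
    def x_r(self) -> float:
        return self.unit_length

    @property
    def y_r(self) -> float:
        return self.unit_length

    @property
    def z_r(self) -> float:
        return self.unit_length


class TransportParams(_Frozen):
    """Diffusion and bulk-flow parameters for brain ECF and capillary blood.

    ``D_star`` is the tortuosity-corrected effective diffusion coefficient;
    if the free-medium ``D`` and tortuosity ``lam`` are supplied they must
    satisfy D* = D/λ².  The ECF bulk flow is bidirectional: the same speed
    ``v_ECF`` is applied along +x and +z.
    """

    D_star: float = Field(gt=0.0, description="effective diffusion coefficient (m² s⁻¹)")
    v_ECF: float = Field(ge=0.0, description="ECF bulk-flow speed along +x and +z (m s⁻¹)")
    v_blood: float = Field(ge=0.0, description="capillary blood speed (m s⁻¹)")
    D: float | None = Field(default=None, gt=0.0, description="free-medium diffusion (m² s⁻¹)")
    lam: float | None = Field(default=None, ge=1.0, description="tortuosity λ (-)")
    allow_out_of_range: bool = False

    @model_validator(mode="after")
    def _consistent(self) -> "TransportParams":
        if (self.D is None) != (self.lam is None):
            raise ValueError("D and lam must be supplied together")
        if self.D is not None and self.lam is not None:
            implied = self.D / self.lam**2
            if not math.isclose(implied, self.D_star, rel_tol=1e-12):
                raise ValueError(
                    f"D/λ² = {implied:g} inconsistent with D_star = {self.D_star:g}"
                )
        if self.v_blood > 0:
            _check_range("v_blood", self.v_blood, self.allow_out_of_range)
        return self


class BBBParams(_Frozen):
    """Blood-brain-barrier permeation and carrier-transport constants.

    Passive permeation is ``P (μ - ρ)``.  Active influx/efflux follow
    Michaelis-Menten kinetics with maximal rates ``T_m_in``/``T_m_out``
    (μmol s⁻¹ over the whole barrier area ``SA_BBB``) and half-saturation
    concentrations ``K_m_in``/``K_m_out`` (μmol L⁻¹).

    ``P`` may alternatively be composed from transcellular and paracellular
    routes: P = p_trans·f_trans + (D_para/W_PCS)·f_para.  An explicitly
    supplied ``P`` takes precedence over the composition inputs.
    """

    P: float | None = Field(default=None, ge=0.0, description="permeability (m s⁻¹)")
    T_m_in: float = Field(default=0.0, ge=0.0, description="max active influx (μmol s⁻¹)")
    T_m_out: float = Field(default=0.0, ge=0.0, description="max active efflux (μmol s⁻¹)")
    K_m_in: float = Field(default=1.0, gt=0.0, description="influx half-saturation (μmol L⁻¹)")
    K_m_out: float = Field(default=1.0, gt=0.0, description="efflux half-saturation (μmol L⁻¹)")
    SA_BBB: float = Field(default=0.0, ge=0.0, description="barrier surface area (m²)")
    p_trans: float | None = Field(default=None, ge=0.0)
    f_trans: float | None = Field(default=None, ge=0.0, le=1.0)
    D_para: float | None = Field(default=None, ge=0.0)
    W_PCS: float | None = Field(default=None, gt=0.0)
    f_para: float | None = Field(default=None, ge=0.0, le=1.0)
    allow_out_of_range: bool = False

    @model_validator(mode="after")
    def _resolve(self) -> "BBBParams":
        if self.P is None and self.p_trans is None:
            raise ValueError("either P or its composition inputs must be given")
        if (self.T_m_in > 0 or self.T_m_out > 0) and self.SA_BBB <= 0:
            raise ValueError("SA_BBB must be positive when an active transport rate is nonzero")
        if self.permeability > 0:    # P = 0 models an impermeable barrier
            _check_range("P", self.permeability, self.allow_out_of_range)
        return self

    @property
    def permeability(self) -> float:
        """Resolved permeability P (m s⁻¹): explicit value or route composition."""
        if self.P is not None:
            return self.P
        assert self.p_trans is not None
        f_trans = self.f_trans if self.f_trans is not None else 0.0
        f_para = self.f_para if self.f_para is not None else 0.0
        p_para = 0.0
        if self.D_para is not None and self.W_PCS is not None:
            p_para = self.D_para / self.W_PCS
        return self.p_trans * f_trans + p_para * f_para

    @property
    def K_m_in_internal(self) -> float:
        return self.K_m_in * UMOL_PER_L_TO_UMOL_PER_M3

    @property
    def K_m_out_internal(self) -> float:
        return self.K_m_out * UMOL_PER_L_TO_UMOL_PER_M3


class BindingParams(_Frozen):
    """Two-class reversible binding in brain ECF.

    Class 1 is the specific (pharmacological target) pool, class 2 the
    nonspecific tissue pool.  Association rates are in (μmol L⁻¹ s)⁻¹,
    dissociation rates in s⁻¹, site totals in μmol L⁻¹.
    """

    k1_on: float = Field(ge=0.0)
    k1_off: float = Field(ge=0.0)
    k2_on: float = Field(ge=0.0)
    k2_off: float = Field(ge=0.0)
    B1_tot: float = Field(ge=0.0)
    B2_tot: float = Field(ge=0.0)
    allow_out_of_range: bool = False

    @model_validator(mode="after")
    def _check(self) -> "BindingParams":
        if self.k1_on > 0 and self.B1_tot <= 0:
            raise ValueError("B1_tot must be > 0 when k1_on > 0")
        if self.k2_on > 0 and self.B2_tot <= 0:
            raise ValueError("B2_tot must be > 0 when k2_on > 0")
        if self.k1_on > 0:
            _check_range("k1_on", self.k1_on, self.allow_out_of_range)
        if self.k2_on > 0:
            _check_range("k2_on", self.k2_on, self.allow_out_of_range)
        if self.k1_off > 0:
            _check_range("k1_off", self.k1_off, self.allow_out_of_range)
        if self.k2_off > 0:
            _check_range("k2_off", self.k2_off, self.allow_out_of_range)
        return self

    # association rates act on internal concentrations (μmol m⁻³), so the
    # printed (μmol L⁻¹ s)⁻¹ value shrinks by the same factor of 10³
    @property
    def k1_on_internal(self) -> float:
        return self.k1_on / UMOL_PER_L_TO_UMOL_PER_M3

    @property
    def k2_on_internal(self) -> float:
        return self.k2_on / UMOL_PER_L_TO_UMOL_PER_M3

    @property
    def B1_tot_internal(self) -> float:
        return self.B1_tot * UMOL_PER_L_TO_UMOL_PER_M3

    @property
    def B2_tot_internal(self) -> float:
        return self.B2_tot * UMOL_PER_L_TO_UMOL_PER_M3


class SimulationGrid(_Frozen):
    """Discretization controls: ECF cell counts, capillary nodes, time step."""

    n_x: int = Field(ge=3)
    n_y: int = Field(ge=3)
    n_z: int = Field(ge=3)
    n_edge: int = Field(default=23, ge=3, description="plasma nodes per capillary edge")
    dt: float = Field(gt=0.0, description="time step (s)")
    t_end: float = Field(gt=0.0, description="simulation horizon (s)")
    snapshot_times: tuple[float, ...] = ()

    @model_validator(mode="after")
    def _snapshots_on_grid(self) -> "SimulationGrid":
        for t in self.snapshot_times:
            if not (0.0 <= t <= self.t_end + 1e-12):
                raise ValueError(f"snapshot time {t} outside [0, t_end]")
            k = round(t / self.dt)
            # snapshots are captured exactly, never interpolated, so dt must
            # divide every snapshot time
            if abs(k * self.dt - t) > 1e-6 * self.dt:
                raise ValueError(f"snapshot time {t} does not lie on the time grid")
        return self

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


class ModelParameters(_Frozen):
    """Complete resolved parameter set for one simulation."""

    dosing: DrugDoseParams
    geometry: BrainUnitGeometry
    transport: TransportParams
    bbb: BBBParams
    binding: BindingParams
    grid: SimulationGrid


# ---------------------------------------------------------------------------
# elementary derived quantities

def derive_unit_length(geometry: BrainUnitGeometry) -> float:
    """Brain-unit edge length l_cap + 2r (m)."""
    return geometry.unit_length


def effective_diffusion(D: float, lam: float) -> float:
    """Tortuosity-corrected diffusion coefficient D* = D/λ² (m² s⁻¹).

    Tortuosity hinders diffusion, so λ < 1 is rejected.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    if lam < 1.0:
        raise ValueError("tortuosity λ must be ≥ 1")
    return D / lam**2


def convert_concentration(value_umol_per_L: float) -> float:
    """μmol·L⁻¹ → μmol·m⁻³."""
    if value_umol_per_L < 0:
        raise ValueError("concentration must be non-negative")
    return value_umol_per_L * UMOL_PER_L_TO_UMOL_PER_M3


def convert_concentration_inverse(value_umol_per_m3: float) -> float:
    """μmol·m⁻³ → μmol·L⁻¹."""
    if value_umol_per_m3 < 0:
        raise ValueError("concentration must be non-negative")
    return value_umol_per_m3 / UMOL_PER_L_TO_UMOL_PER_M3


# ---------------------------------------------------------------------------
# configuration I/O (flat INI dialect, sections [dosing] ... [grid])

_SECTION_FIELDS = {
    "dosing": ("F", "Dose", "V_d", "K_a", "K_e"),
    "geometry": ("r", "l_cap"),
    "transport": ("D_star", "v_ECF", "v_blood", "D", "lam"),
    "bbb": ("P", "T_m_in", "T_m_out", "K_m_in", "K_m_out", "SA_BBB",
            "p_trans", "f_trans", "D_para", "W_PCS", "f_para"),
    "binding": ("k1_on", "k1_off", "k2_on", "k2_off", "B1_tot", "B2_tot"),
    "grid": ("n_x", "n_y", "n_z", "n_edge", "dt", "t_end", "snapshot_times"),
}

_MODELS = {
    "dosing": DrugDoseParams,
    "geometry": BrainUnitGeometry,
    "transport": TransportParams,
    "bbb": BBBParams,
    "binding": BindingParams,
    "grid": SimulationGrid,
}


def _parse_value(section: str, key: str, raw: str):
    if key == "snapshot_times":
        raw = raw.strip()
        return tuple(float(tok) for tok in raw.split(",") if tok.strip()) if raw else ()
    if key.startswith("n_"):
        return int(raw)
    return float(raw)


def load_config(path: str | Path | io.StringIO, *,
                allow_out_of_range: bool = False) -> ModelParameters:
    """Read a flat INI-style parameter file into a validated parameter set.

    Unknown keys raise; missing optional keys fall back to field defaults.
    """
    cp = configparser.ConfigParser()
    if isinstance(path, io.StringIO):
        cp.read_file(path)
    else:
        read = cp.read(str(path))
        if not read:
            raise FileNotFoundError(path)
    kwargs: dict[str, object] = {}
    for section, model in _MODELS.items():
        if not cp.has_section(section):
            raise ValueError(f"config missing required section [{section}]")
        fields: dict[str, object] = {}
        for key, raw in cp.items(section):
            # configparser lowercases keys; recover canonical spelling
            canon = {f.lower(): f for f in _SECTION_FIELDS[section]}.get(key)
            if canon is None:
                raise ValueError(f"unknown key '{key}' in section [{section}]")
            fields[canon] = _parse_value(section, canon, raw)
        if allow_out_of_range and "allow_out_of_range" in model.model_fields:
            fields["allow_out_of_range"] = True
        kwargs[section] = model(**fields)
    return ModelParameters(**kwargs)


def dump_config(params: ModelParameters, path: str | Path | None = None) -> str:
    """Serialize a parameter set back to the flat INI dialect.

    The written file round-trips: load(dump(p)) compares equal to p.
    """
    cp = configparser.ConfigParser()
    for section, names in _SECTION_FIELDS.items():
        cp.add_section(section)
        block = getattr(params, section)
        for name in names:
            value = getattr(block, name, None)
            if value is None:
                continue
            if name == "snapshot_times":
                if not value:
                    continue
                cp.set(section, name, ", ".join(repr(t) for t in value))
            elif isinstance(value, int):
                cp.set(section, name, str(value))
            else:
                cp.set(section, name, repr(float(value)))
    buf = io.StringIO()
    cp.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def default_parameters(**overrides: Mapping[str, object]) -> ModelParameters:
    """Rat-brain default parameter set shipped with the package.

    ``overrides`` maps section name to a dict of field updates, e.g.
    ``default_parameters(binding={"k1_off": 0.5})``.
    """
    params = load_config(_default_config_path())
    if overrides:
        updates = {}
        for section, fields in overrides.items():
            block = getattr(params, section)
            updates[section] = type(block)(**{**block.model_dump(), **fields})
        params = params.model_copy(update=updates)
    return params


def _default_config_path() -> Path:
    return Path(__file__).parent / "data" / "defaults.cfg"
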