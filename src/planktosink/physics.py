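"""Physical core: molecular composition model, Stokes settling, transport numbers.

Unit conventions (package-wide):

* densities in g/mL (numerically equal to pg/fL),
* volumes in fL (= µm³),
* lengths/radii in µm,
* velocities in µm/s,
* dynamic viscosity in Pa·s,
* gravity in m/s².

All physics is evaluated in SI internally; conversion happens at the
boundaries of the public functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .errors import DomainError, InvalidCompositionError

__all__ = [
    "COMPONENTS",
    "DRY_COMPONENTS",
    "ComponentDensities",
    "MolecularComposition",
    "FluidEnvironment",
    "CellShape",
    "CellState",
    "TransportQuery",
    "D_NITRATE_UM2_S",
    "D_VIRUS_UM2_S",
    "composition_to_cell_state",
    "equivalent_radius",
    "sphere_volume",
    "sinking_velocity",
    "stokes_velocity",
    "peclet_number",
    "reynolds_number",
]

#: Molecular groups making up a cell, in canonical order.
COMPONENTS = ("water", "protein", "lipid", "carbohydrate", "other")

#: The non-water groups, jointly called the cell's "dry contents".
DRY_COMPONENTS = ("protein", "lipid", "carbohydrate", "other")

# Unit conversion factors.
_G_ML_TO_KG_M3 = 1e3
_UM_TO_M = 1e-6
_M_S_TO_UM_S = 1e6

#: Diffusivity of nitrate in seawater, µm²/s.
D_NITRATE_UM2_S = 1700.0
#: Diffusivity of a small (virus-sized) particle, µm²/s.
D_VIRUS_UM2_S = 10.0


@dataclass(frozen=True)
class ComponentDensities:
    """Mass density of each molecular group, g/mL."""

    water: float = 0.998
    protein: float = 1.35
    lipid: float = 0.92
    carbohydrate: float = 1.50
    other: float = 1.30

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            rho = getattr(self, name)
            if not 0.0 < rho < 3.0:
                raise DomainError(
                    f"density of {name!r} must be in (0, 3) g/mL, got {rho}"
                )

    def of(self, component: str) -> float:
        if component not in COMPONENTS:
            raise DomainError(f"unknown component {component!r}")
        return getattr(self, component)


@dataclass(frozen=True)
class MolecularComposition:
    """Volume of each molecular group in one cell, fL."""

    water: float = 0.0
    protein: float = 0.0
    lipid: float = 0.0
    carbohydrate: float = 0.0
    other: float = 0.0

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if v < 0.0:
                raise InvalidCompositionError(
                    f"volume of {name!r} must be >= 0 fL, got {v}"
                )
        if self.total_volume() <= 0.0:
            raise InvalidCompositionError("total composition volume must be > 0 fL")

    def volume_of(self, component: str) -> float:
        if component not in COMPONENTS:
            raise DomainError(f"unknown component {component!r}")
        return getattr(self, component)

    def total_volume(self) -> float:
        return float(sum(getattr(self, c) for c in COMPONENTS))

    def dry_volume(self) -> float:
        return float(sum(getattr(self, c) for c in DRY_COMPONENTS))

    def mass(self, densities: ComponentDensities) -> float:
        """Total cell mass in pg (volume fL × density pg/fL)."""
        return float(
            sum(getattr(self, c) * densities.of(c) for c in COMPONENTS)
        )

    def density(self, densities: ComponentDensities) -> float:
        """Volume-weighted mean density, g/mL."""
        return self.mass(densities) / self.total_volume()

    def dry_density(self, densities: ComponentDensities) -> float:
        vdry = self.dry_volume()
        if vdry <= 0.0:
            raise InvalidCompositionError("dry volume is zero; dry density undefined")
        mdry = sum(getattr(self, c) * densities.of(c) for c in DRY_COMPONENTS)
        return float(mdry / vdry)

    def scaled(self, component: str, fold: float) -> "MolecularComposition":
        """Return a copy with one group's volume multiplied by ``fold``.

        ``component="dry"`` scales all non-water groups jointly.
        """
        if fold < 0.0:
            raise DomainError(f"fold must be >= 0, got {fold}")
        if component == "dry":
            changes = {c: getattr(self, c) * fold for c in DRY_COMPONENTS}
        elif component in COMPONENTS:
            changes = {component: getattr(self, component) * fold}
        else:
            raise DomainError(f"unknown component {component!r}")
        return replace(self, **changes)

    def shifted(self, deltas: dict) -> "MolecularComposition":
        """Return a copy with per-group volume deltas (fL) applied."""
        changes = {}
        for name, dv in deltas.items():
            if name not in COMPONENTS:
                raise DomainError(f"unknown component {name!r}")
            changes[name] = getattr(self, name) + float(dv)
        return replace(self, **changes)


@dataclass(frozen=True)
class FluidEnvironment:
    """Properties of the surrounding fluid (defaults: seawater at ~22 °C)."""

    density: float = 1.026  # g/mL
    dynamic_viscosity: float = 1.07e-3  # Pa·s
    gravity: float = 9.81  # m/s²

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0 or self.gravity <= 0:
            raise DomainError("fluid density, viscosity and gravity must be positive")


@dataclass(frozen=True)
class CellShape:
    """Shape description with a multiplicative drag correction factor.

    For a sphere the correction factor is exactly 1. A non-sphere factor
    further than 10% from 1 triggers a warning: real pico/nanoplankton
    corrections are expected to stay within that band.
    """

    kind: str = "sphere"
    correction_factor: float = 1.0
    aspect_ratios: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "spheroid", "ellipsoid"):
            raise DomainError(f"unknown shape kind {self.kind!r}")
        if self.correction_factor <= 0:
            raise DomainError("shape correction factor must be > 0")
        if self.kind == "sphere" and self.correction_factor != 1.0:
            raise DomainError("a sphere has correction factor exactly 1")
        if abs(self.correction_factor - 1.0) > 0.1:
            warnings.warn(
                f"shape correction factor {self.correction_factor} deviates more "
                "than 10% from a sphere",
                stacklevel=2,
            )


SPHERE = CellShape()


@dataclass(frozen=True)
class CellState:
    """Biophysical summary of a cell: volume (fL), density (g/mL), radius (µm)."""

    total_volume: float
    density: float
    equivalent_radius: float = field(default=None)  # type: ignore[assignment]
    shape: CellShape = SPHERE

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise DomainError("cell volume must be > 0 fL")
        r = equivalent_radius(self.total_volume)
        if self.equivalent_radius is None:
            object.__setattr__(self, "equivalent_radius", r)
        elif not math.isclose(self.equivalent_radius, r, rel_tol=1e-9):
            raise DomainError(
                f"equivalent radius {self.equivalent_radius} inconsistent with "
                f"volume {self.total_volume} (expected {r})"
            )
        if not 0.85 < self.density < 1.7:
            warnings.warn(
                f"cell density {self.density} g/mL outside the typical biological "
                "range (0.85, 1.7)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TransportQuery:
    """Inputs for dimensionless transport numbers: U µm/s, L µm, D µm²/s."""

    velocity: float
    length: float
    diffusivity: float = D_NITRATE_UM2_S

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DomainError("length must be > 0 µm")
        if self.diffusivity <= 0:
            raise DomainError("diffusivity must be > 0 µm²/s")


def sphere_volume(radius: float) -> float:
    """Volume (fL) of a sphere with the given radius (µm)."""
    if radius <= 0:
        raise DomainError(f"radius must be > 0 µm, got {radius}")
    return 4.0 / 3.0 * math.pi * radius**3


def equivalent_radius(volume: float) -> float:
    """Radius (µm) of the sphere with the given volume (fL)."""
    if volume <= 0:
        raise DomainError(f"volume must be > 0 fL, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def composition_to_cell_state(
    comp: MolecularComposition,
    densities: ComponentDensities | None = None,
    shape: CellShape = SPHERE,
) -> CellState:
    """Collapse a molecular composition into a biophysical cell state.

    Total volume is the sum of group volumes; density is the volume-fraction
    weighted mean of group densities.
    """
    densities = densities or ComponentDensities()
    v = comp.total_volume()
    return CellState(
        total_volume=v,
        density=comp.density(densities),
        equivalent_radius=equivalent_radius(v),
        shape=shape,
    )


def stokes_velocity(
    cell_density: float,
    radius: float,
    fluid: FluidEnvironment,
    shape: CellShape = SPHERE,
) -> float:
    """Creeping-flow settling velocity in µm/s.

    ``v = 2 (ρ_cell − ρ_fluid) g r² Φ / (9 µ)``; negative values mean the
    cell rises (buoyant).
    """
    if radius <= 0:
        raise DomainError(f"radius must be > 0 µm, got {radius}")
    drho_si = (cell_density - fluid.density) * _G_ML_TO_KG_M3
    r_si = radius * _UM_TO_M
    v_si = (
        2.0
        * drho_si
        * fluid.gravity
        * r_si**2
        * shape.correction_factor
        / (9.0 * fluid.dynamic_viscosity)
    )
    return v_si * _M_S_TO_UM_S


def sinking_velocity(state: CellState, fluid: FluidEnvironment) -> float:
    """Settling velocity (µm/s) of a cell state in a fluid."""
    return stokes_velocity(
        state.density, state.equivalent_radius, fluid, state.shape
    )


def peclet_number(q: TransportQuery) -> float:
    """Pe = U·L/D (all inputs in µm-based units; magnitude of U is used)."""
    return abs(q.velocity) * q.length / q.diffusivity


def reynolds_number(q: TransportQuery, fluid: FluidEnvironment | None = None) -> float:
    """Re = ρ_fluid·U·L/µ, evaluated in SI."""
    fluid = fluid or FluidEnvironment()
    rho_si = fluid.density * _G_ML_TO_KG_M3
    u_si = abs(q.velocity) * _UM_TO_M
    l_si = q.length * _UM_TO_M
    return rho_si * u_si * l_si / fluid.dynamic_viscosity
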