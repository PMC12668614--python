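"""First-order attribution of settling-velocity changes to underlying factors.

Two decomposition modes are supported:

* ``density_volume`` — the velocity is viewed as ``f(ρ, r)`` and the change
  between a baseline (control) state and a perturbed state is split between
  the density term and the radius (volume) term of the first-order Taylor
  expansion at the baseline.
* ``water_dry`` — the velocity is viewed as ``f(V_water, V_dry, ρ_dry)``
  with water density held constant; the change is split between water
  volume, dry volume, and dry density terms.

Each influence is the signed fraction of its Taylor term in the sum of all
terms, so influences always sum to one; individual influences may be
negative or exceed one when factors act in opposite directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DecompositionUndefinedError, DomainError, NoChangeError
from .physics import CellShape, FluidEnvironment, SPHERE, equivalent_radius, stokes_velocity

__all__ = [
    "DryWaterContent",
    "InfluenceResult",
    "taylor_partials",
    "influence_density_volume",
    "influence_water_dry",
    "velocity_from_water_dry",
]

_CANCEL_EPS = 1e-9

# (3 / 4π)^(2/3): prefactor mapping V^(2/3) (fL) to r² (µm²).
_K_V23 = (3.0 / (4.0 * math.pi)) ** (2.0 / 3.0)


@dataclass(frozen=True)
class DryWaterContent:
    """Partition of a cell into water and dry contents.

    Volumes in fL, dry density in g/mL.
    """

    water_volume: float
    dry_volume: float
    dry_density: float

    def __post_init__(self) -> None:
        if self.water_volume < 0 or self.dry_volume < 0:
            raise DomainError("water and dry volumes must be >= 0 fL")
        if self.water_volume + self.dry_volume <= 0:
            raise DomainError("total volume must be > 0 fL")

    @property
    def total_volume(self) -> float:
        return self.water_volume + self.dry_volume

    @property
    def water_fraction(self) -> float:
        return self.water_volume / self.total_volume

    def cell_density(self, water_density: float = 0.998) -> float:
        return (
            self.water_volume * water_density + self.dry_volume * self.dry_density
        ) / self.total_volume


@dataclass(frozen=True)
class InfluenceResult:
    """Signed, sum-to-one attribution of a velocity change to its factors."""

    mode: str  # "density_volume" | "water_dry"
    baseline: tuple
    perturbed: tuple
    terms: dict  # factor -> Taylor term, µm/s
    influences: dict  # factor -> fraction of the total change
    valid: bool = True

    @property
    def total_first_order(self) -> float:
        """Sum of the Taylor terms: first-order prediction of Δv, µm/s."""
        return float(sum(self.terms.values()))

    def influence_of(self, factor: str) -> float:
        if factor == "dry" and self.mode == "water_dry":
            return self.influences["dry_volume"] + self.influences["dry_density"]
        return self.influences[factor]


def _stokes_prefactor(fluid: FluidEnvironment, shape: CellShape) -> float:
    """C such that v [µm/s] = C (ρ−ρ_fluid) r² with ρ in g/mL, r in µm."""
    # g/mL→kg/m³ (1e3) × µm²→m² (1e-12) × m/s→µm/s (1e6) collapses to 1e-3.
    return (
        2.0 * fluid.gravity * shape.correction_factor / (9.0 * fluid.dynamic_viscosity)
    ) * 1e-3


def velocity_from_water_dry(
    content: DryWaterContent,
    fluid: FluidEnvironment,
    water_density: float = 0.998,
    shape: CellShape = SPHERE,
) -> float:
    """Settling velocity (µm/s) of a cell given its water/dry partition."""
    v = content.total_volume
    return stokes_velocity(
        content.cell_density(water_density), equivalent_radius(v), fluid, shape
    )


def taylor_partials(
    mode: str,
    baseline: tuple,
    fluid: FluidEnvironment,
    shape: CellShape = SPHERE,
    water_density: float = 0.998,
) -> dict:
    """Closed-form partial derivatives of the settling velocity at a baseline.

    ``mode="density_volume"``: baseline ``(ρ0, r0)`` → keys ``density``
    (µm/s per g/mL) and ``radius`` (µm/s per µm).

    ``mode="water_dry"``: baseline ``(Vw0, Vd0, ρd0)`` → keys ``water``
    and ``dry_volume`` (µm/s per fL) and ``dry_density`` (µm/s per g/mL).
    """
    c = _stokes_prefactor(fluid, shape)
    if mode == "density_volume":
        rho0, r0 = baseline
        if r0 <= 0:
            raise DomainError("baseline radius must be > 0 µm")
        return {
            "density": c * r0**2,
            "radius": 2.0 * c * (rho0 - fluid.density) * r0,
        }
    if mode == "water_dry":
        vw0, vd0, rhod0 = baseline
        v = vw0 + vd0
        if v <= 0:
            raise DomainError("baseline total volume must be > 0 fL")
        m = vw0 * water_density + vd0 * rhod0  # total mass, pg
        ck = c * _K_V23
        common = -(m / 3.0) * v ** (-4.0 / 3.0) - (2.0 / 3.0) * fluid.density * v ** (
            -1.0 / 3.0
        )
        return {
            "water": ck * (water_density * v ** (-1.0 / 3.0) + common),
            "dry_volume": ck * (rhod0 * v ** (-1.0 / 3.0) + common),
            "dry_density": ck * vd0 * v ** (-1.0 / 3.0),
        }
    raise DomainError(f"unknown decomposition mode {mode!r}")


def _fractions(terms: dict) -> dict:
    total = sum(terms.values())
    scale = max((abs(t) for t in terms.values()), default=0.0)
    if scale == 0.0:
        raise NoChangeError("baseline and perturbed states are identical")
    if abs(total) < _CANCEL_EPS * scale:
        raise DecompositionUndefinedError(
            "Taylor terms cancel; influence fractions are undefined"
        )
    return {k: t / total for k, t in terms.items()}


def influence_density_volume(
    baseline: tuple,
    perturbed: tuple,
    fluid: FluidEnvironment | None = None,
    shape: CellShape = SPHERE,
) -> InfluenceResult:
    """Attribute a velocity change to cell density vs cell volume (radius).

    ``baseline``/``perturbed`` are ``(density g/mL, radius µm)`` pairs; the
    expansion point is the baseline (control) state.
    """
    fluid = fluid or FluidEnvironment()
    partials = taylor_partials("density_volume", baseline, fluid, shape)
    drho = perturbed[0] - baseline[0]
    dr = perturbed[1] - baseline[1]
    terms = {
        "density": partials["density"] * drho,
        "volume": partials["radius"] * dr,
    }
    fracs = _fractions(terms)
    # enforce the exact complement identity against rounding
    fracs["volume"] = 1.0 - fracs["density"]
    return InfluenceResult(
        mode="density_volume",
        baseline=tuple(baseline),
        perturbed=tuple(perturbed),
        terms=terms,
        influences=fracs,
    )


def influence_water_dry(
    baseline: DryWaterContent | tuple,
    perturbed: DryWaterContent | tuple,
    fluid: FluidEnvironment | None = None,
    water_density: float = 0.998,
    shape: CellShape = SPHERE,
) -> InfluenceResult:
    """Attribute a velocity change to water volume, dry volume and dry density."""
    fluid = fluid or FluidEnvironment()
    if isinstance(baseline, DryWaterContent):
        baseline = (baseline.water_volume, baseline.dry_volume, baseline.dry_density)
    if isinstance(perturbed, DryWaterContent):
        perturbed = (
            perturbed.water_volume,
            perturbed.dry_volume,
            perturbed.dry_density,
        )
    partials = taylor_partials("water_dry", baseline, fluid, shape, water_density)
    terms = {
        "water": partials["water"] * (perturbed[0] - baseline[0]),
        "dry_volume": partials["dry_volume"] * (perturbed[1] - baseline[1]),
        "dry_density": partials["dry_density"] * (perturbed[2] - baseline[2]),
    }
    fracs = _fractions(terms)
    return InfluenceResult(
        mode="water_dry",
        baseline=tuple(baseline),
        perturbed=tuple(perturbed),
        terms=terms,
        influences=fracs,
    )
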