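"""Population-level biophysics from single-cell instrument measurements.

A resonator reports single-cell buoyant masses (pg) and an impedance counter
reports single-cell volumes (fL); the two instruments measure *different*
cells from the same culture. Population averages of the two arms combine
into cell density (fluid density + mean buoyant mass / mean volume), an
equivalent spherical radius, and a Stokes settling velocity.

The dual-fluid solver turns paired buoyant-mass means measured in normal and
heavy-water media into the population's dry volume and dry density,
assuming complete exchange of intracellular water with the medium (so water
contributes no buoyant mass in either fluid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DomainError,
    EmptyPopulationError,
    InconsistentMeasurementError,
    InsufficientDataError,
    PairingError,
)
from .influence import DryWaterContent
from .physics import (
    CellShape,
    FluidEnvironment,
    SPHERE,
    equivalent_radius,
    stokes_velocity,
)

__all__ = [
    "SingleCellSample",
    "PopulationBiophysics",
    "ProliferationEstimate",
    "filter_small_particles",
    "population_biophysics",
    "dual_fluid_dry_content",
    "proliferation_rate",
]

logger = logging.getLogger(__name__)

INSTRUMENTS = ("resonator", "impedance_counter")


@dataclass(frozen=True)
class SingleCellSample:
    """One instrument's per-cell measurements for a culture replicate.

    ``values`` are buoyant masses in pg for the resonator (may be negative)
    or volumes in fL for the impedance counter (strictly positive).
    """

    species: str
    condition: str
    replicate_id: str
    instrument: str
    values: np.ndarray
    fluid_density: float = 1.026  # g/mL, density of the measurement medium
    fluid: str = "h2o"

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise DomainError(
                f"instrument must be one of {INSTRUMENTS}, got {self.instrument!r}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise DomainError("values must be a 1-D array")
        if self.instrument == "impedance_counter" and np.any(values <= 0):
            raise DomainError("counter volumes must be > 0 fL")
        if self.fluid_density <= 0:
            raise DomainError("fluid density must be > 0 g/mL")
        object.__setattr__(self, "values", values)

    @property
    def n_cells(self) -> int:
        return int(self.values.size)

    def mean(self, statistic: str = "mean") -> float:
        if self.n_cells == 0:
            raise EmptyPopulationError("sample contains no cells")
        if statistic == "mean":
            return float(np.mean(self.values))
        if statistic == "median":
            return float(np.median(self.values))
        raise DomainError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class PopulationBiophysics:
    """Population-average biophysical state inferred from two instrument arms."""

    species: str
    condition: str
    replicate_id: str
    mean_buoyant_mass: float  # pg
    mean_volume: float  # fL
    density: float  # g/mL
    equivalent_radius: float  # µm
    sinking_velocity: float  # µm/s
    n_mass: int
    n_volume: int


@dataclass(frozen=True)
class ProliferationEstimate:
    rate: float  # doublings/day
    window: float  # days spanned by the counts used


def filter_small_particles(
    sample: SingleCellSample, threshold: float
) -> SingleCellSample:
    """Drop measurement values below a viability threshold.

    The threshold is in the sample's own units (fL for counter volumes, pg
    for buoyant masses); values strictly below it are treated as debris.
    """
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    keep = sample.values >= threshold
    n_removed = int(np.sum(~keep))
    if n_removed and not np.any(keep):
        raise EmptyPopulationError(
            f"threshold {threshold} removed all {sample.n_cells} particles"
        )
    if n_removed:
        logger.info(
            "removed %d/%d particles below %g from %s/%s/%s (%s)",
            n_removed,
            sample.n_cells,
            threshold,
            sample.species,
            sample.condition,
            sample.replicate_id,
            sample.instrument,
        )
    return replace(sample, values=sample.values[keep])


def population_biophysics(
    mass_sample: SingleCellSample,
    volume_sample: SingleCellSample,
    fluid: FluidEnvironment | None = None,
    shape: CellShape = SPHERE,
    statistic: str = "mean",
) -> PopulationBiophysics:
    """Combine unpaired buoyant-mass and volume arms into population biophysics.

    Density is the measurement-fluid density plus the ratio of the mean
    buoyant mass to the mean volume; the settling velocity is evaluated via
    Stokes' law in the (possibly different) ambient ``fluid``.
    """
    if mass_sample.instrument != "resonator":
        raise PairingError("mass_sample must come from the resonator")
    if volume_sample.instrument != "impedance_counter":
        raise PairingError("volume_sample must come from the impedance counter")
    key_m = (mass_sample.species, mass_sample.condition, mass_sample.replicate_id)
    key_v = (volume_sample.species, volume_sample.condition, volume_sample.replicate_id)
    if key_m != key_v:
        raise PairingError(f"sample metadata mismatch: {key_m} vs {key_v}")
    fluid = fluid or FluidEnvironment(density=mass_sample.fluid_density)

    mean_bm = mass_sample.mean(statistic)
    mean_vol = volume_sample.mean(statistic)
    density = mass_sample.fluid_density + mean_bm / mean_vol
    radius = equivalent_radius(mean_vol)
    velocity = stokes_velocity(density, radius, fluid, shape)
    return PopulationBiophysics(
        species=mass_sample.species,
        condition=mass_sample.condition,
        replicate_id=mass_sample.replicate_id,
        mean_buoyant_mass=mean_bm,
        mean_volume=mean_vol,
        density=density,
        equivalent_radius=radius,
        sinking_velocity=velocity,
        n_mass=mass_sample.n_cells,
        n_volume=volume_sample.n_cells,
    )


def dual_fluid_dry_content(
    bm_h2o_mean: float,
    bm_d2o_mean: float,
    rho1: float,
    rho2: float,
    total_volume: float,
    exchange_factor: float = 1.0,
) -> DryWaterContent:
    """Solve for dry volume and dry density from two-fluid buoyant masses.

    Inverts the forward model ``BM_k = V_dry (ρ_dry − ρ_k)`` for fluids of
    density ``rho1`` (normal medium) < ``rho2`` (heavy-water medium):

    * ``V_dry = (BM1 − BM2) / (ρ2 − ρ1)``
    * ``ρ_dry = ρ1 + BM1 / V_dry``

    ``total_volume`` (fL, from the counter in the normal medium) fixes the
    water volume by subtraction. ``exchange_factor`` optionally scales the
    heavy-water buoyant mass to compensate for incomplete labile-hydrogen
    exchange; the default of 1 applies no correction.
    """
    if rho2 <= rho1:
        raise DomainError(
            f"heavy-water medium must be denser: rho2={rho2} <= rho1={rho1}"
        )
    if total_volume <= 0:
        raise DomainError("total volume must be > 0 fL")
    bm2 = bm_d2o_mean * exchange_factor
    if bm_h2o_mean <= bm2:
        raise InconsistentMeasurementError(
            f"BM in the lighter fluid ({bm_h2o_mean} pg) must exceed BM in the "
            f"denser fluid ({bm2} pg)"
        )
    dry_volume = (bm_h2o_mean - bm2) / (rho2 - rho1)
    if dry_volume > total_volume:
        raise InconsistentMeasurementError(
            f"solved dry volume {dry_volume:.3g} fL exceeds the measured total "
            f"volume {total_volume:.3g} fL"
        )
    dry_density = rho1 + bm_h2o_mean / dry_volume
    return DryWaterContent(
        water_volume=total_volume - dry_volume,
        dry_volume=dry_volume,
        dry_density=dry_density,
    )


def proliferation_rate(counts, times) -> ProliferationEstimate:
    """Doublings per day from cell counts, assuming exponential growth.

    Least-squares slope of log2(count) against time; exact for two points or
    for perfectly exponential series.
    """
    counts = np.asarray(counts, dtype=float)
    times = np.asarray(times, dtype=float)
    if counts.shape != times.shape or counts.ndim != 1:
        raise DomainError("counts and times must be 1-D arrays of equal length")
    if counts.size < 2:
        raise InsufficientDataError("need at least 2 counts")
    if np.any(counts <= 0):
        raise DomainError("all counts must be > 0")
    if np.unique(times).size != times.size:
        raise DomainError("times must be distinct")
    slope = np.polyfit(times, np.log2(counts), 1)[0]
    return ProliferationEstimate(
        rate=float(slope), window=float(times.max() - times.min())
    )
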