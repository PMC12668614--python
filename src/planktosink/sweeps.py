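"""Composition sweeps: vary one molecular group at a time and study settling.

Provides the simulation primitives behind the composition-to-sinking curves:
single-group (or joint dry-content) fold sweeps with a first-order
density/volume split, buoyancy-reversal threshold finding, and attribution of
an observed velocity change to measured compositional changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AttributionUndefinedError, DomainError
from .influence import taylor_partials
from .physics import (
    CellShape,
    CellState,
    ComponentDensities,
    COMPONENTS,
    DRY_COMPONENTS,
    FluidEnvironment,
    MolecularComposition,
    SPHERE,
    composition_to_cell_state,
    sinking_velocity,
)

__all__ = [
    "SweepResult",
    "BuoyancyThreshold",
    "AttributionResult",
    "default_fold_grid",
    "sweep_component",
    "buoyancy_threshold",
    "attribute_observed_change",
]

#: Relative discrepancy between first-order and exact Δv above which the
#: density/volume split is flagged as not meaningful.
TAYLOR_VALID_TOL = 0.20

_SWEEPABLE = COMPONENTS + ("dry",)


def default_fold_grid(
    fold_min: float = 0.25, fold_max: float = 20.0, steps: int = 48
) -> np.ndarray:
    """Log-spaced fold grid covering depletion through multi-fold accumulation."""
    if fold_min <= 0 or fold_max <= fold_min or steps < 1:
        raise DomainError("need 0 < fold_min < fold_max and steps >= 1")
    return np.geomspace(fold_min, fold_max, steps)


@dataclass(frozen=True)
class SweepResult:
    """Settling velocity as one molecular group is scaled by a fold factor."""

    component: str
    fold_grid: np.ndarray
    velocity: np.ndarray  # µm/s
    density_contribution: np.ndarray  # µm/s, first-order Taylor term
    volume_contribution: np.ndarray  # µm/s, first-order Taylor term
    taylor_valid: np.ndarray  # bool per fold
    baseline_state: CellState

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.component,
                "fold": self.fold_grid,
                "velocity_um_s": self.velocity,
                "density_contribution": self.density_contribution,
                "volume_contribution": self.volume_contribution,
                "taylor_valid": self.taylor_valid,
            }
        )


@dataclass(frozen=True)
class BuoyancyThreshold:
    """Fold change at which cell density crosses the fluid density."""

    component: str
    mode: str  # "accumulate" | "deplete"
    fold: float | None
    reachable: bool
    residual: float  # ρ_cell − ρ_fluid at the solution, g/mL


@dataclass(frozen=True)
class AttributionResult:
    """How much of an observed Δv a simulated compositional change explains."""

    components: tuple
    simulated_delta_v: float  # µm/s
    observed_delta_v: float  # µm/s
    percent_explained: float  # 100 · simulated / observed


def _check_component(component: str) -> None:
    if component not in _SWEEPABLE:
        raise DomainError(
            f"component must be one of {_SWEEPABLE}, got {component!r}"
        )


def sweep_component(
    baseline: MolecularComposition,
    densities: ComponentDensities,
    component: str,
    fold_grid: np.ndarray | None = None,
    fluid: FluidEnvironment | None = None,
    shape: CellShape = SPHERE,
) -> SweepResult:
    """Scale one molecular group (or all dry groups jointly) over a fold grid.

    At each fold the scaled composition is collapsed to a cell state and its
    settling velocity evaluated exactly; the density and volume contributions
    are the Taylor terms of ``f(ρ, r)`` expanded at fold = 1. Points where
    the first-order sum strays more than ``TAYLOR_VALID_TOL`` (relative) from
    the exact change are flagged ``taylor_valid = False``.
    """
    _check_component(component)
    fluid = fluid or FluidEnvironment()
    grid = np.asarray(
        default_fold_grid() if fold_grid is None else fold_grid, dtype=float
    )
    if grid.ndim != 1 or grid.size == 0:
        raise DomainError("fold grid must be a non-empty 1-D array")
    if np.any(grid <= 0):
        raise DomainError("fold values must be > 0")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise DomainError("fold grid must be strictly increasing")

    base_state = composition_to_cell_state(baseline, densities, shape)
    v0 = sinking_velocity(base_state, fluid)
    partials = taylor_partials(
        "density_volume", (base_state.density, base_state.equivalent_radius), fluid, shape
    )

    velocity = np.empty_like(grid)
    dens_term = np.empty_like(grid)
    vol_term = np.empty_like(grid)
    valid = np.ones(grid.shape, dtype=bool)
    for i, fold in enumerate(grid):
        state = composition_to_cell_state(baseline.scaled(component, fold), densities, shape)
        v = sinking_velocity(state, fluid)
        velocity[i] = v
        dens_term[i] = partials["density"] * (state.density - base_state.density)
        vol_term[i] = partials["radius"] * (
            state.equivalent_radius - base_state.equivalent_radius
        )
        exact_dv = v - v0
        first_order = dens_term[i] + vol_term[i]
        if exact_dv != 0.0:
            valid[i] = abs(first_order - exact_dv) <= TAYLOR_VALID_TOL * abs(exact_dv)
    return SweepResult(
        component=component,
        fold_grid=grid,
        velocity=velocity,
        density_contribution=dens_term,
        volume_contribution=vol_term,
        taylor_valid=valid,
        baseline_state=base_state,
    )


def _density_at_fold(
    baseline: MolecularComposition,
    densities: ComponentDensities,
    component: str,
    fold: float,
) -> float:
    return baseline.scaled(component, fold).density(densities)


# Residual tolerance on |ρ_cell − ρ_fluid| at the reported threshold fold.
_DENSITY_TOL = 1e-6
_MAX_FOLD = 1e6


def buoyancy_threshold(
    baseline: MolecularComposition,
    densities: ComponentDensities,
    component: str,
    mode: str = "accumulate",
    fluid: FluidEnvironment | None = None,
) -> BuoyancyThreshold:
    """Find the fold change of one group at which the cell becomes neutrally
    buoyant (cell density = fluid density).

    ``mode="accumulate"`` searches folds ≥ 1 (bracket expanded geometrically
    up to 10⁶); ``mode="deplete"`` searches folds in (0, 1]. When the density
    never crosses the fluid density on the search interval the threshold is
    reported unreachable.
    """
    _check_component(component)
    if mode not in ("accumulate", "deplete"):
        raise DomainError(f"mode must be 'accumulate' or 'deplete', got {mode!r}")
    fluid = fluid or FluidEnvironment()

    scaled_volume = (
        baseline.dry_volume() if component == "dry" else baseline.volume_of(component)
    )
    if scaled_volume <= 0.0:
        raise DomainError(
            f"baseline has zero {component!r} volume; scaling it has no effect"
        )
    if mode == "deplete" and component != "dry":
        # depleting a single group to fold 0 must leave a valid composition
        if baseline.total_volume() - scaled_volume <= 0.0:
            raise DomainError(
                f"cannot deplete {component!r}: it is the entire cell volume"
            )

    def residual(fold: float) -> float:
        return _density_at_fold(baseline, densities, component, fold) - fluid.density

    r1 = residual(1.0)
    if abs(r1) < _DENSITY_TOL:
        return BuoyancyThreshold(component, mode, 1.0, True, r1)
    if r1 < 0:
        raise DomainError(
            "baseline cell density is already below the fluid density"
        )

    if mode == "accumulate":
        lo, r_lo = 1.0, r1
        hi = 2.0
        while residual(hi) > 0:
            hi *= 2.0
            if hi > _MAX_FOLD:
                return BuoyancyThreshold(component, mode, None, False, residual(_MAX_FOLD))
        r_hi = residual(hi)
    else:  # deplete: density decreases as the (dense) group is removed
        hi, r_hi = 1.0, r1
        lo = 0.5
        while residual(lo) > 0:
            lo /= 2.0
            if lo < 1.0 / _MAX_FOLD:
                return BuoyancyThreshold(component, mode, None, False, residual(lo))
        r_lo = residual(lo)

    # bisection on the density residual
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if abs(r_mid) < _DENSITY_TOL * 1e-3:
            break
        if (r_mid > 0) == (r_lo > 0):
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    else:  # pragma: no cover - bisection always converges well before 200 steps
        mid, r_mid = 0.5 * (lo + hi), residual(0.5 * (lo + hi))
    return BuoyancyThreshold(component, mode, float(mid), True, float(r_mid))


def attribute_observed_change(
    baseline: MolecularComposition,
    densities: ComponentDensities,
    component_deltas: dict,
    observed_delta_v: float,
    fluid: FluidEnvironment | None = None,
    shape: CellShape = SPHERE,
) -> AttributionResult:
    """Percent of an observed velocity change explained by given volume deltas.

    ``component_deltas`` maps group names to volume changes in fL; these are
    applied to the baseline composition, the settling velocity re-evaluated,
    and the simulated change expressed as a percentage of the observed one.
    """
    if observed_delta_v == 0.0:
        raise AttributionUndefinedError(
            "observed velocity change is zero; attribution undefined"
        )
    fluid = fluid or FluidEnvironment()
    v0 = sinking_velocity(composition_to_cell_state(baseline, densities, shape), fluid)
    perturbed = baseline.shifted(component_deltas)
    v1 = sinking_velocity(composition_to_cell_state(perturbed, densities, shape), fluid)
    simulated = v1 - v0
    return AttributionResult(
        components=tuple(sorted(component_deltas)),
        simulated_delta_v=simulated,
        observed_delta_v=observed_delta_v,
        percent_explained=100.0 * simulated / observed_delta_v,
    )
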