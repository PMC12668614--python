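"""Synthetic single-cell measurement studies with known ground truth.

Emulates the measurement structure the analysis pipeline expects:

* per-cell lognormal size variation shared across all molecular groups,
* unpaired instrument arms (resonator and impedance counter sample
  different cells from the same culture),
* a paired heavy-water resonator arm in which intracellular water has fully
  exchanged with the medium and therefore contributes no buoyant mass,
* between-culture (replicate) compositional scatter,
* condition effects expressed as per-group volume fold changes,
* multi-day cell counts growing exponentially.

All randomness flows from one study-level seed; each (species, condition,
replicate, arm) combination draws from an independent, documented substream
so datasets are reproducible element-for-element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .physics import (
    CellShape,
    ComponentDensities,
    COMPONENTS,
    DRY_COMPONENTS,
    FluidEnvironment,
    MolecularComposition,
    SPHERE,
    composition_to_cell_state,
    sinking_velocity,
)
from .populations import SingleCellSample

__all__ = [
    "MeasurementFluid",
    "SpeciesProfile",
    "ConditionEffect",
    "StudyDesign",
    "StudyDataset",
    "composition_from_fractions",
    "representative_composition",
    "simulate_single_cells",
    "simulate_study",
    "example_nine_species_design",
]

#: Default density of seawater medium in which 90% of the water is heavy.
D2O_MEDIUM_DENSITY = 1.122


@dataclass(frozen=True)
class MeasurementFluid:
    """A measurement medium: its bulk density and the density that fully
    exchanged intracellular water takes inside a cell suspended in it.

    For the normal medium the intracellular water keeps the composition
    model's water density. For the heavy-water medium the exchanged water is
    denser; by default the salt contribution (bulk minus water density) is
    taken equal in both media, which makes the two-fluid buoyant-mass
    difference depend on dry volume only.
    """

    name: str
    density: float  # g/mL
    water_density: float | None = None  # None → use the composition's water density

    def intracellular_water_density(self, default: float) -> float:
        return default if self.water_density is None else self.water_density


def standard_fluids(
    h2o_density: float = 1.026,
    d2o_density: float = D2O_MEDIUM_DENSITY,
    water_density: float = 0.998,
) -> dict:
    """The H2O/D2O measurement-fluid pair with a consistent salt offset."""
    salt_offset = h2o_density - water_density
    return {
        "h2o": MeasurementFluid("h2o", h2o_density, None),
        "d2o": MeasurementFluid("d2o", d2o_density, d2o_density - salt_offset),
    }


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth description of one species under its control condition."""

    name: str
    baseline_composition: MolecularComposition
    shape: CellShape = SPHERE
    cell_size_cv: float = 0.3
    peclet_length_um: float | None = None  # None → equivalent spherical diameter

    def __post_init__(self) -> None:
        if self.cell_size_cv < 0:
            raise DomainError("cell size CV must be >= 0")


@dataclass(frozen=True)
class ConditionEffect:
    """Per-group volume fold changes injected by a culture condition."""

    condition: str
    volume_folds: dict = field(default_factory=dict)
    replicate_sd: float = 0.0  # lognormal sd (log scale) of per-replicate scatter
    doublings_per_day: float = 1.0

    def __post_init__(self) -> None:
        for name, fold in self.volume_folds.items():
            if name not in COMPONENTS:
                raise DomainError(f"unknown component {name!r} in condition effect")
            if fold <= 0:
                raise DomainError(f"fold for {name!r} must be > 0, got {fold}")
        if self.replicate_sd < 0:
            raise DomainError("replicate scatter sd must be >= 0")

    def apply(self, comp: MolecularComposition) -> MolecularComposition:
        changes = {
            name: comp.volume_of(name) * fold
            for name, fold in self.volume_folds.items()
        }
        return replace(comp, **changes)


@dataclass(frozen=True)
class StudyDesign:
    """Species × conditions × replicates × cells layout of a synthetic study."""

    species: tuple  # names, must match the profiles mapping
    conditions: tuple  # names, must match the effects mapping
    n_replicates: int = 4
    n_cells: int = 300
    noise_cv: float = 0.05
    include_d2o_arm: bool = True
    include_counts: bool = True
    count_days: tuple = (4.0, 5.0, 6.0)
    initial_count_per_ml: float = 1e5

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_cells < 1:
            raise DomainError("need at least 1 replicate and 1 cell")
        if self.noise_cv < 0:
            raise DomainError("instrument noise CV must be >= 0")


@dataclass
class StudyDataset:
    """Tidy synthetic measurement tables plus the design they came from."""

    measurements: pd.DataFrame
    counts: pd.DataFrame | None
    design: StudyDesign
    seed: int


def composition_from_fractions(
    total_volume: float,
    water_volume_fraction: float,
    dry_mass_fractions: dict,
    densities: ComponentDensities | None = None,
) -> MolecularComposition:
    """Build a composition from a total volume, a water volume fraction and
    dry *mass* fractions (w/w), converting mass to volume via group densities.
    """
    densities = densities or ComponentDensities()
    if not 0.0 < water_volume_fraction < 1.0:
        raise DomainError("water volume fraction must be in (0, 1)")
    if abs(sum(dry_mass_fractions.values()) - 1.0) > 1e-9:
        raise DomainError("dry mass fractions must sum to 1")
    water = total_volume * water_volume_fraction
    dry_volume = total_volume - water
    # mass fraction w_i → volume share proportional to w_i / ρ_i
    shares = {c: w / densities.of(c) for c, w in dry_mass_fractions.items()}
    norm = sum(shares.values())
    volumes = {c: dry_volume * s / norm for c, s in shares.items()}
    return MolecularComposition(water=water, **volumes)


def representative_composition(
    total_volume: float = 100.0,
    densities: ComponentDensities | None = None,
) -> MolecularComposition:
    """A literature-representative nanoplankton composition.

    Water occupies ~70% of cell volume; the dry mass splits into roughly
    half protein, a third carbohydrate, and the rest lipid plus a small
    residual pool — typical bulk values for nutrient-replete green algae
    and diatoms.
    """
    return composition_from_fractions(
        total_volume,
        water_volume_fraction=0.70,
        dry_mass_fractions={
            "protein": 0.50,
            "carbohydrate": 0.30,
            "lipid": 0.15,
            "other": 0.05,
        },
        densities=densities,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """n multiplicative factors with mean 1 and coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=n)


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one (study, species, condition, …) cell."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


_ARM_INDEX = {"resonator_h2o": 0, "resonator_d2o": 1, "counter": 2, "counts": 3}


def simulate_single_cells(
    composition: MolecularComposition,
    densities: ComponentDensities,
    fluid: MeasurementFluid,
    instrument: str,
    n: int,
    rng: np.random.Generator,
    noise_cv: float = 0.05,
    cell_size_cv: float = 0.3,
    *,
    species: str = "synthetic",
    condition: str = "high",
    replicate_id: str = "r1",
) -> SingleCellSample:
    """Draw one instrument arm of per-cell measurements.

    Each cell's group volumes are the composition scaled by a shared
    lognormal size factor (mean 1, CV ``cell_size_cv``). The counter reports
    total volume; the resonator reports the summed buoyant mass
    ``Σ V_i (ρ_i − ρ_fluid)`` with the water density replaced by the fluid's
    exchanged-water density. Both are multiplied by mean-1 lognormal
    instrument noise of CV ``noise_cv``.
    """
    if n < 1:
        raise DomainError("need n >= 1 cells")
    size = _lognormal_factors(rng, cell_size_cv, n)
    noise = _lognormal_factors(rng, noise_cv, n)
    if instrument == "impedance_counter":
        values = composition.total_volume() * size * noise
    elif instrument == "resonator":
        water_rho = fluid.intracellular_water_density(densities.water)
        bm_per_fl = 0.0
        for comp_name in COMPONENTS:
            rho = water_rho if comp_name == "water" else densities.of(comp_name)
            bm_per_fl += composition.volume_of(comp_name) * (rho - fluid.density)
        values = bm_per_fl * size * noise
    else:
        raise DomainError(f"unknown instrument {instrument!r}")
    return SingleCellSample(
        species=species,
        condition=condition,
        replicate_id=replicate_id,
        instrument=instrument,
        values=values,
        fluid_density=fluid.density,
        fluid=fluid.name,
    )


def _scattered(
    comp: MolecularComposition, sd: float, rng: np.random.Generator
) -> MolecularComposition:
    """Apply per-group lognormal replicate scatter to a composition."""
    if sd == 0.0:
        return comp
    factors = rng.lognormal(mean=0.0, sigma=sd, size=len(COMPONENTS))
    return MolecularComposition(
        **{c: comp.volume_of(c) * f for c, f in zip(COMPONENTS, factors)}
    )


def simulate_study(
    design: StudyDesign,
    profiles: dict,
    effects: dict,
    seed: int,
    densities: ComponentDensities | None = None,
    fluids: dict | None = None,
    ambient: FluidEnvironment | None = None,
) -> tuple:
    """Generate a full tidy study dataset plus its ground truth.

    ``profiles`` maps species names to :class:`SpeciesProfile`; ``effects``
    maps condition names to :class:`ConditionEffect`. Returns
    ``(StudyDataset, ground_truth DataFrame)`` where the ground truth holds
    the scatter-free and per-replicate compositions, densities, and settling
    velocities actually used to generate each arm.
    """
    densities = densities or ComponentDensities()
    fluids = fluids or standard_fluids(water_density=densities.water)
    ambient = ambient or FluidEnvironment(density=fluids["h2o"].density)
    for name in design.species:
        if name not in profiles:
            raise ValidationError(f"no profile for species {name!r}")
    for name in design.conditions:
        if name not in effects:
            raise ValidationError(f"no effect for condition {name!r}")

    frames = []
    truth_rows = []
    count_rows = []
    for si, species in enumerate(design.species):
        profile = profiles[species]
        for ci, condition in enumerate(design.conditions):
            effect = effects[condition]
            cond_comp = effect.apply(profile.baseline_composition)
            for ri in range(design.n_replicates):
                rep = f"r{ri + 1}"
                rep_rng = _substream(seed, si, ci, ri, 99)
                rep_comp = _scattered(cond_comp, effect.replicate_sd, rep_rng)
                state = composition_to_cell_state(rep_comp, densities, profile.shape)
                truth_rows.append(
                    {
                        "species": species,
                        "condition": condition,
                        "replicate_id": rep,
                        **{f"{c}_fl": rep_comp.volume_of(c) for c in COMPONENTS},
                        "total_volume_fl": state.total_volume,
                        "density_g_ml": state.density,
                        "radius_um": state.equivalent_radius,
                        "v_um_s": sinking_velocity(state, ambient),
                    }
                )
                arms = [("resonator", "h2o"), ("impedance_counter", "h2o")]
                if design.include_d2o_arm:
                    arms.append(("resonator", "d2o"))
                for instrument, fluid_name in arms:
                    arm_key = (
                        "counter"
                        if instrument == "impedance_counter"
                        else f"resonator_{fluid_name}"
                    )
                    rng = _substream(seed, si, ci, ri, _ARM_INDEX[arm_key])
                    sample = simulate_single_cells(
                        rep_comp,
                        densities,
                        fluids[fluid_name],
                        instrument,
                        design.n_cells,
                        rng,
                        noise_cv=design.noise_cv,
                        cell_size_cv=profile.cell_size_cv,
                        species=species,
                        condition=condition,
                        replicate_id=rep,
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "species": species,
                                "condition": condition,
                                "replicate_id": rep,
                                "instrument": instrument,
                                "fluid": fluid_name,
                                "fluid_density_g_ml": fluids[fluid_name].density,
                                "value": sample.values,
                                "unit": "fL"
                                if instrument == "impedance_counter"
                                else "pg",
                            }
                        )
                    )
                if design.include_counts:
                    rng = _substream(seed, si, ci, ri, _ARM_INDEX["counts"])
                    t0 = design.count_days[0]
                    for day in design.count_days:
                        expected = design.initial_count_per_ml * 2.0 ** (
                            effect.doublings_per_day * (day - t0)
                        )
                        count_rows.append(
                            {
                                "species": species,
                                "condition": condition,
                                "replicate_id": rep,
                                "day": day,
                                "count_per_ml": expected
                                * _lognormal_factors(rng, 0.02, 1)[0],
                            }
                        )
    measurements = pd.concat(frames, ignore_index=True)
    counts = pd.DataFrame(count_rows) if design.include_counts else None
    dataset = StudyDataset(
        measurements=measurements, counts=counts, design=design, seed=seed
    )
    return dataset, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# canned designs
# ---------------------------------------------------------------------------


def example_nine_species_design(
    n_replicates: int = 4,
    n_cells: int = 300,
    noise_cv: float = 0.05,
    cell_size_cv: float = 0.3,
    include_d2o_arm: bool = True,
    include_counts: bool = False,
) -> tuple:
    """A nine-species high/low study emulating the canonical response pattern:
    seven species sink faster when starved, one sinks slower, one is unchanged.

    Returns ``(design, profiles, effects)`` ready for :func:`simulate_study`.
    The injected condition effects act on group volumes; the resulting
    velocity ratios follow from the composition model (they are ground truth,
    not free parameters).
    """
    base_volumes = {
        "sp1": 30.0,
        "sp2": 60.0,
        "sp3": 100.0,
        "sp4": 150.0,
        "sp5": 45.0,
        "sp6": 80.0,
        "sp7": 200.0,
        "sp8": 120.0,
        "sp9": 55.0,
    }
    profiles = {
        name: SpeciesProfile(
            name=name,
            baseline_composition=representative_composition(volume),
            cell_size_cv=cell_size_cv,
        )
        for name, volume in base_volumes.items()
    }
    # seven increase (carbohydrate/protein accumulation of varying strength),
    # one decreases (lipid accumulation + protein loss), one is null
    increase_folds = [
        {"carbohydrate": 3.0},
        {"carbohydrate": 2.5, "protein": 1.3},
        {"carbohydrate": 4.0},
        {"protein": 1.8, "carbohydrate": 2.0},
        {"carbohydrate": 3.5, "water": 1.1},
        {"carbohydrate": 2.2, "other": 1.5},
        {"protein": 2.0, "carbohydrate": 1.5},
    ]
    effects_by_species = {
        f"sp{i + 1}": folds for i, folds in enumerate(increase_folds)
    }
    effects_by_species["sp8"] = {"lipid": 8.0, "protein": 0.4}  # sinks slower
    effects_by_species["sp9"] = {}  # unchanged

    design = StudyDesign(
        species=tuple(sorted(base_volumes)),
        conditions=("high", "low"),
        n_replicates=n_replicates,
        n_cells=n_cells,
        noise_cv=noise_cv,
        include_d2o_arm=include_d2o_arm,
        include_counts=include_counts,
    )
    return design, profiles, effects_by_species


def simulate_nine_species_study(
    seed: int,
    n_replicates: int = 4,
    n_cells: int = 300,
    noise_cv: float = 0.05,
    cell_size_cv: float = 0.3,
    replicate_sd: float = 0.03,
    include_d2o_arm: bool = True,
    include_counts: bool = True,
) -> tuple:
    """Generate the canonical nine-species high/low dataset.

    Because the injected effects differ per species while conditions are
    shared, each species is simulated as its own one-species study and the
    tables concatenated. Returns ``(StudyDataset, ground_truth DataFrame)``.
    """
    design, profiles, effects_by_species = example_nine_species_design(
        n_replicates=n_replicates,
        n_cells=n_cells,
        noise_cv=noise_cv,
        cell_size_cv=cell_size_cv,
        include_d2o_arm=include_d2o_arm,
        include_counts=include_counts,
    )
    frames = []
    truths = []
    counts = []
    for si, species in enumerate(design.species):
        sub_design = replace(design, species=(species,))
        effects = {
            "high": ConditionEffect("high", {}, replicate_sd=replicate_sd),
            "low": ConditionEffect(
                "low",
                effects_by_species[species],
                replicate_sd=replicate_sd,
                doublings_per_day=0.15,
            ),
        }
        dataset, truth = simulate_study(
            sub_design,
            {species: profiles[species]},
            effects,
            seed=seed * 1000 + si,
        )
        frames.append(dataset.measurements)
        truths.append(truth)
        if dataset.counts is not None:
            counts.append(dataset.counts)
    measurements = pd.concat(frames, ignore_index=True)
    dataset = StudyDataset(
        measurements=measurements,
        counts=pd.concat(counts, ignore_index=True) if counts else None,
        design=design,
        seed=seed,
    )
    return dataset, pd.concat(truths, ignore_index=True)
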