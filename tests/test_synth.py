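import numpy as np
import pandas as pd
import pytest

from planktosink import (
    ComponentDensities,
    ConditionEffect,
    SpeciesProfile,
    StudyDesign,
    composition_to_cell_state,
    population_biophysics,
    dual_fluid_dry_content,
    run_study,
    simulate_single_cells,
    simulate_study,
)
from planktosink.errors import DomainError, ValidationError
from planktosink.synth import (
    composition_from_fractions,
    representative_composition,
    standard_fluids,
)


@pytest.fixture
def fluids():
    return standard_fluids()


@pytest.fixture
def profile(representative):
    return SpeciesProfile(name="sp", baseline_composition=representative)


def gen(comp, fluids, instrument, fluid="h2o", n=100, seed=0, noise=0.05, cv=0.3):
    return simulate_single_cells(
        comp,
        ComponentDensities(),
        fluids[fluid],
        instrument,
        n,
        np.random.default_rng(seed),
        noise_cv=noise,
        cell_size_cv=cv,
    )


class TestCompositionBuilders:
    def test_fraction_builder_mass_balance(self, densities):
        comp = composition_from_fractions(
            100.0, 0.6, {"protein": 0.7, "lipid": 0.3}, densities
        )
        assert comp.water == pytest.approx(60.0)
        assert comp.total_volume() == pytest.approx(100.0)
        # dry mass fractions are respected after density conversion
        m_protein = comp.protein * densities.protein
        m_lipid = comp.lipid * densities.lipid
        assert m_protein / (m_protein + m_lipid) == pytest.approx(0.7, rel=1e-9)

    def test_representative_water_fraction(self, representative):
        assert representative.water / representative.total_volume() == pytest.approx(
            0.70
        )

    def test_bad_fractions_rejected(self):
        with pytest.raises(DomainError):
            composition_from_fractions(100.0, 1.2, {"protein": 1.0})
        with pytest.raises(DomainError):
            composition_from_fractions(100.0, 0.5, {"protein": 0.4})


class TestSimulateSingleCells:
    def test_degenerate_generator_recovers_state_exactly(
        self, representative, fluids, seawater
    ):
        mass = gen(representative, fluids, "resonator", n=10, noise=0.0, cv=0.0)
        vol = gen(representative, fluids, "impedance_counter", n=10, noise=0.0, cv=0.0)
        pop = population_biophysics(mass, vol, fluid=seawater)
        truth = composition_to_cell_state(representative, ComponentDensities())
        assert pop.mean_volume == pytest.approx(truth.total_volume, rel=1e-12)
        assert pop.density == pytest.approx(truth.density, rel=1e-12)

    def test_seed_determinism(self, representative, fluids):
        a = gen(representative, fluids, "resonator", seed=5)
        b = gen(representative, fluids, "resonator", seed=5)
        assert np.array_equal(a.values, b.values)
        c = gen(representative, fluids, "resonator", seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_resonator_expectation_matches_buoyant_mass(
        self, representative, fluids, densities
    ):
        """E[value] = V(ρ_cell − ρ_fluid) in the normal medium."""
        s = gen(representative, fluids, "resonator", n=200_000, seed=1)
        state = composition_to_cell_state(representative, densities)
        expected = state.total_volume * (state.density - fluids["h2o"].density)
        assert np.mean(s.values) == pytest.approx(expected, rel=5e-3)

    def test_d2o_arm_difference_isolates_dry_volume(
        self, representative, fluids, densities
    ):
        """E[BM_h2o − BM_d2o] = V_dry (ρ2 − ρ1)."""
        n = 200_000
        bm1 = gen(representative, fluids, "resonator", "h2o", n=n, seed=2)
        bm2 = gen(representative, fluids, "resonator", "d2o", n=n, seed=3)
        expected = representative.dry_volume() * (
            fluids["d2o"].density - fluids["h2o"].density
        )
        diff = np.mean(bm1.values) - np.mean(bm2.values)
        assert diff == pytest.approx(expected, rel=2e-2)

    def test_dual_fluid_solver_unbiased_on_synthetic_data(
        self, representative, fluids, densities
    ):
        bm1 = gen(representative, fluids, "resonator", "h2o", n=50_000, seed=4)
        bm2 = gen(representative, fluids, "resonator", "d2o", n=50_000, seed=5)
        content = dual_fluid_dry_content(
            np.mean(bm1.values),
            np.mean(bm2.values),
            fluids["h2o"].density,
            fluids["d2o"].density,
            total_volume=representative.total_volume(),
        )
        assert content.dry_volume == pytest.approx(
            representative.dry_volume(), rel=0.02
        )

    def test_density_recovery_calibration(self, representative, fluids, seawater):
        """n = 300, cv = 0.3, noise 0.05: density within 0.005 g/mL in ≥95%
        of 100 seeds."""
        truth = composition_to_cell_state(representative, ComponentDensities())
        hits = 0
        for seed in range(100):
            mass = gen(representative, fluids, "resonator", n=300, seed=2 * seed)
            vol = gen(
                representative, fluids, "impedance_counter", n=300, seed=2 * seed + 1
            )
            pop = population_biophysics(mass, vol, fluid=seawater)
            hits += abs(pop.density - truth.density) < 0.005
        assert hits >= 95


class TestSimulateStudy:
    def make_design(self, **kw):
        defaults = dict(
            species=("sp",),
            conditions=("high", "low"),
            n_replicates=4,
            n_cells=200,
        )
        defaults.update(kw)
        return StudyDesign(**defaults)

    def test_null_effect_gives_unit_ratio(self, profile):
        design = self.make_design()
        effects = {
            "high": ConditionEffect("high", {}, replicate_sd=0.02),
            "low": ConditionEffect("low", {}, replicate_sd=0.02),
        }
        dataset, truth = simulate_study(design, {"sp": profile}, effects, seed=11)
        report = run_study(dataset.measurements, {})
        row = report.sinking_changes.iloc[0]
        assert row["p_value"] > 0.01
        assert row["mean_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_carbohydrate_injection_recovered_as_dry_driven(self, profile):
        design = self.make_design(n_cells=300)
        effects = {
            "high": ConditionEffect("high", {}, replicate_sd=0.02),
            "low": ConditionEffect("low", {"carbohydrate": 3.0}, replicate_sd=0.02),
        }
        dataset, truth = simulate_study(design, {"sp": profile}, effects, seed=3)
        report = run_study(dataset.measurements, {})
        row = report.sinking_changes.iloc[0]
        assert row["mean_ratio"] > 1.0
        assert row["p_value"] < 0.05
        dry = report.influence_molecular.query("factor == 'dry'")
        assert (dry["mean_influence"] > 0.5).all()

    def test_ground_truth_consistent_with_dataset(self, profile, densities):
        design = self.make_design(n_cells=50)
        effects = {
            "high": ConditionEffect("high", {}),
            "low": ConditionEffect("low", {"protein": 1.5}),
        }
        dataset, truth = simulate_study(design, {"sp": profile}, effects, seed=8)
        # no replicate scatter: truth equals the effect applied to the profile
        low = truth[truth["condition"] == "low"].iloc[0]
        assert low["protein_fl"] == pytest.approx(profile.baseline_composition.protein * 1.5)
        assert low["density_g_ml"] == pytest.approx(
            effects["low"].apply(profile.baseline_composition).density(densities)
        )

    def test_study_seed_determinism(self, profile):
        design = self.make_design(n_cells=30)
        effects = {
            "high": ConditionEffect("high", {}, replicate_sd=0.05),
            "low": ConditionEffect("low", {}, replicate_sd=0.05),
        }
        d1, t1 = simulate_study(design, {"sp": profile}, effects, seed=9)
        d2, t2 = simulate_study(design, {"sp": profile}, effects, seed=9)
        pd.testing.assert_frame_equal(d1.measurements, d2.measurements)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_species_rejected(self, profile):
        design = self.make_design(species=("ghost",))
        effects = {"high": ConditionEffect("high", {}), "low": ConditionEffect("low", {})}
        with pytest.raises(ValidationError):
            simulate_study(design, {"sp": profile}, effects, seed=0)

    def test_counts_table_layout(self, profile):
        design = self.make_design(n_cells=20, include_counts=True)
        effects = {
            "high": ConditionEffect("high", {}, doublings_per_day=1.0),
            "low": ConditionEffect("low", {}, doublings_per_day=0.1),
        }
        dataset, _ = simulate_study(design, {"sp": profile}, effects, seed=13)
        assert dataset.counts is not None
        assert set(dataset.counts["day"]) == {4.0, 5.0, 6.0}
        # low condition grows much more slowly
        by_cond = dataset.counts.groupby("condition")["count_per_ml"].max()
        assert by_cond["high"] > 3 * by_cond["low"]


class TestConditionEffect:
    def test_apply_folds(self, representative):
        effect = ConditionEffect("low", {"lipid": 2.0, "water": 0.5})
        out = effect.apply(representative)
        assert out.lipid == pytest.approx(2.0 * representative.lipid)
        assert out.water == pytest.approx(0.5 * representative.water)
        assert out.protein == representative.protein

    def test_invalid_folds(self):
        with pytest.raises(DomainError):
            ConditionEffect("low", {"lipid": 0.0})
        with pytest.raises(DomainError):
            ConditionEffect("low", {"plutonium": 2.0})
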