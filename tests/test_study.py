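import json
import math

import numpy as np
import pandas as pd
import pytest

from planktosink import relative_sinking_change, run_study, run_test
from planktosink.errors import (
    DomainError,
    InsufficientDataError,
    ValidationError,
    ZeroVarianceError,
)
from planktosink.synth import simulate_nine_species_study


class TestRunTest:
    def test_one_sample_t_hand_case(self):
        # mean 3.0, sd sqrt(0.08/3): t = 2 / (sd/2) = 24.4949
        r = run_test("one_sample_t_vs_1", [3.0, 2.8, 3.2, 3.0])
        sd = math.sqrt(0.08 / 3.0)
        assert r.statistic == pytest.approx(2.0 / (sd / 2.0), rel=1e-9)
        assert r.statistic == pytest.approx(24.49, abs=5e-3)
        assert r.df == 3

    def test_one_sample_centered(self):
        r = run_test("one_sample_t_vs_1", [0.9, 1.1])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_paired_identical_groups(self):
        with pytest.raises(ZeroVarianceError):
            run_test("paired_t", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_constant_shift(self):
        # constant difference: zero variance of differences is an error too
        with pytest.raises(ZeroVarianceError):
            run_test("paired_t", [2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_paired_t_oracle(self):
        a = np.array([2.1, 3.3, 4.0, 5.2])
        b = np.array([1.8, 2.9, 4.3, 4.4])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        r = run_test("paired_t", a, b)
        assert r.statistic == pytest.approx(t_expected, rel=1e-9)
        assert r.df == 3

    def test_welch_t_oracle(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_expected = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        r = run_test("welch_t", a, b)
        assert r.statistic == pytest.approx(t_expected, rel=1e-9)
        assert r.df == pytest.approx(df_expected, rel=1e-9)

    def test_anova_f_oracle(self):
        groups = [
            np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        ]
        # closed-form one-way ANOVA from sums of squares
        grand = np.concatenate(groups).mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, 15
        f_expected = (ss_between / df_b) / (ss_within / df_w)
        r = run_test("anova_tukey", *groups)
        assert r.statistic == pytest.approx(f_expected, rel=1e-9)
        assert r.df == df_b
        assert r.effect["df_within"] == df_w

    def test_tukey_against_statsmodels(self):
        """Dual-route check: pairwise p-values vs an independent implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [
            np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        ]
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 6)
        sm = pairwise_tukeyhsd(values, labels)
        r = run_test("anova_tukey", *groups)
        ours = {(p["group_a"], p["group_b"]): p["p_value"] for p in r.effect["tukey"]}
        for (i, j), p_sm in zip([(0, 1), (0, 2), (1, 2)], sm.pvalues):
            assert ours[(i, j)] == pytest.approx(p_sm, abs=1e-6)

    def test_linear_fit_hand_case(self):
        r = run_test("linear_fit", [1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert r.effect["slope"] == pytest.approx(0.5)
        assert r.effect["intercept"] == pytest.approx(1.0)
        assert r.effect["r_squared"] == pytest.approx(0.25)

    def test_anova_identical_groups(self):
        with pytest.raises(ZeroVarianceError):
            run_test("anova_tukey", [1.0, 1.0], [1.0, 1.0], [1.0, 1.0])

    def test_unknown_kind(self):
        with pytest.raises(DomainError):
            run_test("bayes_factor", [1.0, 2.0])


class TestRelativeSinkingChange:
    def test_hand_case(self):
        high = {"r1": 1.0, "r2": 1.0, "r3": 1.0, "r4": 1.0}
        low = {"r1": 3.0, "r2": 2.8, "r3": 3.2, "r4": 3.0}
        r = relative_sinking_change(high, low)
        assert r.effect["mean_ratio"] == pytest.approx(3.0)
        assert r.statistic == pytest.approx(24.49, abs=5e-3)
        assert r.df == 3

    def test_all_ratios_one_is_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            relative_sinking_change({"a": 2.0, "b": 3.0}, {"a": 2.0, "b": 3.0})

    def test_centered_ratios(self):
        r = relative_sinking_change({"a": 1.0, "b": 1.0}, {"a": 0.9, "b": 1.1})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert r.effect["mean_ratio"] == pytest.approx(1.0)

    def test_nonpositive_high_pair_excluded(self):
        high = {"a": -0.5, "b": 1.0, "c": 1.0, "d": 1.0}
        low = {"a": 2.0, "b": 2.0, "c": 2.2, "d": 1.9}
        with pytest.warns(UserWarning, match="excluded"):
            r = relative_sinking_change(high, low)
        assert r.effect["n"] == 3

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            relative_sinking_change({"a": 1.0}, {"a": 2.0})


@pytest.fixture(scope="module")
def nine_species():
    dataset, truth = simulate_nine_species_study(seed=42, n_cells=200)
    return dataset, truth


class TestRunStudy:
    def test_recovers_injected_pattern(self, nine_species):
        dataset, _ = nine_species
        report = run_study(dataset.measurements, {}, dataset.counts)
        counts = report.significant_changes(alpha=0.01)
        assert counts["increased"] == 7
        assert counts["decreased"] == 1
        assert counts["unchanged"] == 1

    def test_influences_sum_to_one(self, nine_species):
        dataset, _ = nine_species
        report = run_study(dataset.measurements, {})
        bio = report.influence_biophysical
        for (_, _), grp in bio.groupby(["species", "condition"]):
            total = grp.set_index("factor")["mean_influence"]
            assert total["density"] + total["volume"] == pytest.approx(1.0, abs=1e-9)
        mol = report.influence_molecular
        for (_, _), grp in mol.groupby(["species", "condition"]):
            total = grp.set_index("factor")["mean_influence"]
            assert total["water"] + total["dry_volume"] + total[
                "dry_density"
            ] == pytest.approx(1.0, abs=1e-9)
            assert total["dry"] == pytest.approx(
                total["dry_volume"] + total["dry_density"], abs=1e-9
            )

    def test_velocity_reproducible_from_stored_state(self, nine_species, seawater):
        from planktosink import stokes_velocity

        dataset, _ = nine_species
        report = run_study(dataset.measurements, {})
        for _, row in report.biophysics.iterrows():
            v = stokes_velocity(row["density_g_ml"], row["radius_um"], seawater)
            assert row["v_um_s"] == pytest.approx(v, rel=1e-9)

    def test_deterministic_report(self, nine_species):
        dataset, _ = nine_species
        r1 = run_study(dataset.measurements, {}, dataset.counts)
        r2 = run_study(dataset.measurements, {}, dataset.counts)
        assert r1.to_json() == r2.to_json()

    def test_missing_d2o_arm_flagged(self, nine_species):
        dataset, _ = nine_species
        no_d2o = dataset.measurements[dataset.measurements["fluid"] != "d2o"]
        report = run_study(no_d2o, {})
        assert report.flags["dry_water_available"] is False
        assert report.influence_molecular.empty

    def test_schema_validation(self):
        with pytest.raises(ValidationError):
            run_study(pd.DataFrame({"species": ["a"]}))

    def test_unit_mismatch_rejected(self, nine_species):
        dataset, _ = nine_species
        bad = dataset.measurements.copy()
        bad.loc[bad.index[:5], "unit"] = "kg"
        with pytest.raises(ValidationError):
            run_study(bad)

    def test_peclet_table_consistent(self, nine_species):
        dataset, _ = nine_species
        report = run_study(dataset.measurements, {})
        merged = report.peclet.merge(
            report.biophysics, on=["species", "condition", "replicate_id"]
        )
        for _, row in merged.iterrows():
            expected = (
                abs(row["v_um_s"]) * 2.0 * row["radius_um"] / row["diffusivity_um2_s"]
            )
            assert row["peclet"] == pytest.approx(expected, rel=1e-9)

    def test_proliferation_rates_recovered(self, nine_species):
        dataset, _ = nine_species
        report = run_study(dataset.measurements, {}, dataset.counts)
        assert not report.proliferation.empty
        # high-nutrient condition was generated at 1 doubling/day ± 2% noise
        high = report.proliferation[report.proliferation["condition"] == "high"]
        assert high["doublings_per_day"].mean() == pytest.approx(1.0, abs=0.1)

    def test_report_write_and_json(self, nine_species, tmp_path):
        dataset, _ = nine_species
        report = run_study(dataset.measurements, {})
        report.write(tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        payload = json.loads((tmp_path / "out" / "report.json").read_text())
        assert "provenance" in payload and "config_hash" in payload["provenance"]
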