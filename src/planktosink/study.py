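"""Replicate-level statistics and the end-to-end study orchestration.

Takes tidy single-cell measurement tables (resonator buoyant masses and
counter volumes across species × conditions × replicates, optionally with a
heavy-water resonator arm and daily cell counts) and produces the full
analysis: per-replicate biophysics, low-vs-high fold-change tests, influence
decompositions, transport-number tables, and proliferation rates, bundled
into a machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DecompositionUndefinedError,
    DomainError,
    InsufficientDataError,
    ValidationError,
    ZeroVarianceError,
)
from .influence import (
    DryWaterContent,
    influence_density_volume,
    influence_water_dry,
)
from .physics import (
    CellShape,
    D_NITRATE_UM2_S,
    D_VIRUS_UM2_S,
    FluidEnvironment,
    TransportQuery,
    peclet_number,
)
from .populations import (
    SingleCellSample,
    dual_fluid_dry_content,
    filter_small_particles,
    population_biophysics,
    proliferation_rate,
)

__all__ = [
    "TestResult",
    "StudyReport",
    "relative_sinking_change",
    "run_test",
    "run_study",
]

logger = logging.getLogger(__name__)

TEST_KINDS = ("one_sample_t_vs_1", "paired_t", "welch_t", "anova_tukey", "linear_fit")

MEASUREMENT_COLUMNS = [
    "species",
    "condition",
    "replicate_id",
    "instrument",
    "fluid",
    "fluid_density_g_ml",
    "value",
    "unit",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test or fit."""

    test: str
    statistic: float
    df: float
    p_value: float
    effect: dict = field(default_factory=dict)


def _require_variance(x: np.ndarray, context: str) -> None:
    if np.ptp(x) == 0.0:
        raise ZeroVarianceError(f"{context}: all values identical ({x[0]!r})")


def run_test(kind: str, *groups) -> TestResult:
    """Run a named hypothesis test on the supplied group arrays.

    * ``one_sample_t_vs_1`` — one group, t test of the mean against 1.
    * ``paired_t`` — two equal-length groups, paired t test.
    * ``welch_t`` — two groups, unequal-variance t test.
    * ``anova_tukey`` — ≥2 groups, one-way ANOVA plus Tukey HSD pairwise
      p-values.
    * ``linear_fit`` — (x, y) pair, ordinary least-squares line with R².
    """
    if kind not in TEST_KINDS:
        raise DomainError(f"unknown test kind {kind!r}; choose from {TEST_KINDS}")
    arrays = [np.asarray(g, dtype=float) for g in groups]

    if kind == "one_sample_t_vs_1":
        (x,) = arrays
        if x.size < 2:
            raise InsufficientDataError("one-sample t test needs >= 2 values")
        _require_variance(x, "one-sample t test")
        res = stats.ttest_1samp(x, 1.0)
        return TestResult(
            kind,
            float(res.statistic),
            float(x.size - 1),
            float(res.pvalue),
            effect={
                "mean": float(np.mean(x)),
                "sem": float(stats.sem(x)),
                "n": int(x.size),
            },
        )
    if kind == "paired_t":
        a, b = arrays
        if a.size != b.size:
            raise DomainError("paired t test needs equal-length groups")
        if a.size < 2:
            raise InsufficientDataError("paired t test needs >= 2 pairs")
        _require_variance(a - b, "paired t test (differences)")
        res = stats.ttest_rel(a, b)
        return TestResult(
            kind,
            float(res.statistic),
            float(a.size - 1),
            float(res.pvalue),
            effect={"mean_difference": float(np.mean(a - b)), "n": int(a.size)},
        )
    if kind == "welch_t":
        a, b = arrays
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("Welch t test needs >= 2 values per group")
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            raise ZeroVarianceError("Welch t test: both groups constant")
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult(
            kind,
            float(res.statistic),
            float(res.df),
            float(res.pvalue),
            effect={"mean_difference": float(np.mean(a) - np.mean(b))},
        )
    if kind == "anova_tukey":
        if len(arrays) < 2:
            raise InsufficientDataError("ANOVA needs >= 2 groups")
        if any(g.size < 2 for g in arrays):
            raise InsufficientDataError("ANOVA needs >= 2 values per group")
        pooled = np.concatenate(arrays)
        _require_variance(pooled, "ANOVA")
        f = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairwise = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                pairwise.append(
                    {
                        "group_a": i,
                        "group_b": j,
                        "mean_difference": float(
                            np.mean(arrays[i]) - np.mean(arrays[j])
                        ),
                        "p_value": float(tukey.pvalue[i, j]),
                    }
                )
        df_between = float(len(arrays) - 1)
        df_within = float(pooled.size - len(arrays))
        return TestResult(
            kind,
            float(f.statistic),
            df_between,
            float(f.pvalue),
            effect={"df_within": df_within, "tukey": pairwise},
        )
    # linear_fit
    x, y = arrays
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("linear fit needs >= 3 (x, y) pairs")
    _require_variance(x, "linear fit (x)")
    res = stats.linregress(x, y)
    return TestResult(
        kind,
        float(res.slope / res.stderr) if res.stderr > 0 else math.inf,
        float(x.size - 2),
        float(res.pvalue),
        effect={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
        },
    )


def relative_sinking_change(
    high: dict, low: dict, min_pairs: int = 2
) -> TestResult:
    """Low/high velocity ratios paired by replicate id, tested against 1.

    ``high`` and ``low`` map replicate ids to settling velocities (µm/s).
    Pairs whose high-condition velocity is not strictly positive are dropped
    with a warning (the ratio is not interpretable).
    """
    ratios = {}
    for rep in sorted(set(high) & set(low)):
        if high[rep] <= 0:
            warnings.warn(
                f"replicate {rep!r}: non-positive high-condition velocity "
                f"{high[rep]:.3g} µm/s; pair excluded from ratio analysis",
                stacklevel=2,
            )
            continue
        ratios[rep] = low[rep] / high[rep]
    if len(ratios) < min_pairs:
        raise InsufficientDataError(
            f"only {len(ratios)} usable replicate pairs (need >= {min_pairs})"
        )
    values = np.array([ratios[r] for r in sorted(ratios)])
    result = run_test("one_sample_t_vs_1", values)
    result.effect["ratios"] = {r: float(ratios[r]) for r in sorted(ratios)}
    result.effect["mean_ratio"] = float(np.mean(values))
    return result


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Machine-readable results of a full study run."""

    biophysics: pd.DataFrame
    sinking_changes: pd.DataFrame
    influence_biophysical: pd.DataFrame
    influence_molecular: pd.DataFrame
    dry_water: pd.DataFrame
    peclet: pd.DataFrame
    proliferation: pd.DataFrame
    flags: dict
    provenance: dict

    def significant_changes(self, alpha: float = 0.05, condition: str = "low") -> dict:
        """Count species with increased/decreased/unchanged settling."""
        sub = self.sinking_changes[self.sinking_changes["condition"] == condition]
        increased = decreased = unchanged = 0
        for _, row in sub.iterrows():
            if row["p_value"] < alpha:
                if row["mean_ratio"] > 1:
                    increased += 1
                else:
                    decreased += 1
            else:
                unchanged += 1
        return {"increased": increased, "decreased": decreased, "unchanged": unchanged}

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "flags": self.flags,
            "tables": {
                name: json.loads(getattr(self, name).to_json(orient="records"))
                for name in (
                    "biophysics",
                    "sinking_changes",
                    "influence_biophysical",
                    "influence_molecular",
                    "dry_water",
                    "peclet",
                    "proliferation",
                )
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "biophysics",
            "sinking_changes",
            "influence_biophysical",
            "influence_molecular",
            "dry_water",
            "peclet",
            "proliferation",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _validate_measurements(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns: {missing}")
    bad_unit = df[
        ~(
            ((df["instrument"] == "resonator") & (df["unit"] == "pg"))
            | ((df["instrument"] == "impedance_counter") & (df["unit"] == "fL"))
        )
    ]
    if len(bad_unit):
        raise ValidationError(
            "unit/instrument mismatch (resonator rows must be 'pg', counter "
            f"rows 'fL') in {len(bad_unit)} rows",
            rows=bad_unit.index.tolist(),
        )
    non_numeric = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric values in {len(non_numeric)} rows",
            rows=non_numeric.index.tolist(),
        )


def _sample_from_rows(rows: pd.DataFrame) -> SingleCellSample:
    first = rows.iloc[0]
    return SingleCellSample(
        species=first["species"],
        condition=first["condition"],
        replicate_id=str(first["replicate_id"]),
        instrument=first["instrument"],
        values=rows["value"].to_numpy(dtype=float),
        fluid_density=float(first["fluid_density_g_ml"]),
        fluid=first["fluid"],
    )


def _species_options(config: dict | None, species: str) -> dict:
    config = config or {}
    return (config.get("species") or {}).get(species, {})


def _shape_for(config: dict | None, species: str) -> CellShape:
    opts = _species_options(config, species)
    phi = float(opts.get("shape_factor", 1.0))
    if phi == 1.0:
        return CellShape()
    return CellShape(kind="spheroid", correction_factor=phi)


def _aggregate_influences(rows: list) -> list:
    """Mean ± SEM of per-pair influence fractions per (species, condition)."""
    out = []
    frame = pd.DataFrame(rows)
    if frame.empty:
        return out
    for (species, condition, factor), grp in frame.groupby(
        ["species", "condition", "factor"], sort=True
    ):
        vals = grp["influence"].to_numpy(dtype=float)
        out.append(
            {
                "species": species,
                "condition": condition,
                "factor": factor,
                "mean_influence": float(np.mean(vals)),
                "sem_influence": float(stats.sem(vals)) if vals.size > 1 else float("nan"),
                "n_pairs": int(vals.size),
            }
        )
    return out


def run_study(
    measurements: pd.DataFrame,
    config: dict | None = None,
    counts: pd.DataFrame | None = None,
) -> StudyReport:
    """Run the complete analysis over a tidy measurement table.

    ``config`` (optional) may carry a ``physics`` block (fluid constants),
    a ``species`` block (per-species shape factor, transport length, and
    small-particle threshold), ``baseline_condition`` (default ``"high"``),
    ``statistic`` ("mean"/"median") and ``use_condition_means`` for the
    influence decomposition. Stages whose data are absent (e.g. no
    heavy-water arm, no counts) are skipped and flagged.
    """
    config = config or {}
    _validate_measurements(measurements)
    measurements = measurements.copy()
    measurements["value"] = pd.to_numeric(measurements["value"])
    baseline_condition = config.get("baseline_condition", "high")
    statistic = config.get("statistic", "mean")
    physics_cfg = config.get("physics", {})
    fluid = FluidEnvironment(
        density=float(physics_cfg.get("fluid_density", 1.026)),
        dynamic_viscosity=float(physics_cfg.get("dynamic_viscosity", 1.07e-3)),
        gravity=float(physics_cfg.get("gravity", 9.81)),
    )
    water_density = float(physics_cfg.get("water_density", 0.998))
    flags: dict = {"skipped": []}

    # --- per-replicate biophysics ------------------------------------------
    bio_rows = []
    dry_rows = []
    groups = measurements.groupby(["species", "condition", "replicate_id"], sort=True)
    for (species, condition, rep), rows in groups:
        opts = _species_options(config, species)
        shape = _shape_for(config, species)
        counter = rows[
            (rows["instrument"] == "impedance_counter") & (rows["fluid"] == "h2o")
        ]
        res_h2o = rows[(rows["instrument"] == "resonator") & (rows["fluid"] == "h2o")]
        res_d2o = rows[(rows["instrument"] == "resonator") & (rows["fluid"] == "d2o")]
        if counter.empty or res_h2o.empty:
            flags["skipped"].append(
                {"species": species, "condition": condition, "replicate_id": str(rep),
                 "reason": "missing resonator or counter arm"}
            )
            continue
        vol_sample = _sample_from_rows(counter)
        mass_sample = _sample_from_rows(res_h2o)
        threshold = opts.get("min_volume_fl")
        if threshold is not None:
            vol_sample = filter_small_particles(vol_sample, float(threshold))
        mass_threshold = opts.get("min_mass_pg")
        if mass_threshold is not None:
            mass_sample = filter_small_particles(mass_sample, float(mass_threshold))
        pop = population_biophysics(
            mass_sample, vol_sample, fluid=fluid, shape=shape, statistic=statistic
        )
        bio_rows.append(
            {
                "species": species,
                "condition": condition,
                "replicate_id": str(rep),
                "mean_bm_pg": pop.mean_buoyant_mass,
                "mean_vol_fl": pop.mean_volume,
                "density_g_ml": pop.density,
                "radius_um": pop.equivalent_radius,
                "v_um_s": pop.sinking_velocity,
                "n_mass": pop.n_mass,
                "n_volume": pop.n_volume,
            }
        )
        if not res_d2o.empty:
            d2o_sample = _sample_from_rows(res_d2o)
            try:
                content = dual_fluid_dry_content(
                    bm_h2o_mean=mass_sample.mean(statistic),
                    bm_d2o_mean=d2o_sample.mean(statistic),
                    rho1=mass_sample.fluid_density,
                    rho2=d2o_sample.fluid_density,
                    total_volume=pop.mean_volume,
                )
            except Exception as exc:  # inconsistent replicate: flag, keep going
                flags["skipped"].append(
                    {"species": species, "condition": condition,
                     "replicate_id": str(rep), "reason": f"dual-fluid solve: {exc}"}
                )
            else:
                dry_rows.append(
                    {
                        "species": species,
                        "condition": condition,
                        "replicate_id": str(rep),
                        "water_volume_fl": content.water_volume,
                        "dry_volume_fl": content.dry_volume,
                        "dry_density_g_ml": content.dry_density,
                        "water_fraction": content.water_fraction,
                    }
                )
    biophysics = pd.DataFrame(bio_rows)
    dry_water = pd.DataFrame(dry_rows)
    if dry_water.empty:
        flags["dry_water_available"] = False
        flags["skipped"].append({"reason": "no heavy-water resonator arm"})
    else:
        flags["dry_water_available"] = True

    # --- fold-change tests --------------------------------------------------
    change_rows = []
    if not biophysics.empty:
        for species, sp_rows in biophysics.groupby("species", sort=True):
            base = sp_rows[sp_rows["condition"] == baseline_condition]
            if base.empty:
                continue
            high = dict(zip(base["replicate_id"], base["v_um_s"]))
            for condition, cond_rows in sp_rows.groupby("condition", sort=True):
                if condition == baseline_condition:
                    continue
                low = dict(zip(cond_rows["replicate_id"], cond_rows["v_um_s"]))
                try:
                    res = relative_sinking_change(high, low)
                except (InsufficientDataError, ZeroVarianceError) as exc:
                    flags["skipped"].append(
                        {"species": species, "condition": condition,
                         "reason": f"fold-change test: {exc}"}
                    )
                    continue
                change_rows.append(
                    {
                        "species": species,
                        "condition": condition,
                        "mean_ratio": res.effect["mean_ratio"],
                        "sem_ratio": res.effect["sem"],
                        "t_statistic": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "n_pairs": res.effect["n"],
                    }
                )
    sinking_changes = pd.DataFrame(change_rows)

    # --- influence decompositions ------------------------------------------
    use_means = bool(config.get("use_condition_means", False))
    bio_influences: list = []
    mol_influences: list = []
    if not biophysics.empty:
        for species, sp_rows in biophysics.groupby("species", sort=True):
            shape = _shape_for(config, species)
            base = sp_rows[sp_rows["condition"] == baseline_condition]
            if base.empty:
                continue
            for condition, cond_rows in sp_rows.groupby("condition", sort=True):
                if condition == baseline_condition:
                    continue
                pairs = _pair_states(base, cond_rows, use_means)
                for rep, b_row, p_row in pairs:
                    try:
                        result = influence_density_volume(
                            (b_row["density_g_ml"], b_row["radius_um"]),
                            (p_row["density_g_ml"], p_row["radius_um"]),
                            fluid=fluid,
                            shape=shape,
                        )
                    except DecompositionUndefinedError as exc:
                        logger.warning(
                            "%s/%s pair %s excluded from biophysical influence: %s",
                            species, condition, rep, exc,
                        )
                        continue
                    for factor in ("density", "volume"):
                        bio_influences.append(
                            {"species": species, "condition": condition,
                             "replicate_pair": rep, "mode": "density_volume",
                             "factor": factor,
                             "term": result.terms[factor],
                             "influence": result.influences[factor],
                             "valid": result.valid}
                        )
        if not dry_water.empty:
            for species, sp_rows in dry_water.groupby("species", sort=True):
                shape = _shape_for(config, species)
                base = sp_rows[sp_rows["condition"] == baseline_condition]
                if base.empty:
                    continue
                for condition, cond_rows in sp_rows.groupby("condition", sort=True):
                    if condition == baseline_condition:
                        continue
                    pairs = _pair_states(base, cond_rows, use_means)
                    for rep, b_row, p_row in pairs:
                        try:
                            result = influence_water_dry(
                                DryWaterContent(
                                    b_row["water_volume_fl"],
                                    b_row["dry_volume_fl"],
                                    b_row["dry_density_g_ml"],
                                ),
                                DryWaterContent(
                                    p_row["water_volume_fl"],
                                    p_row["dry_volume_fl"],
                                    p_row["dry_density_g_ml"],
                                ),
                                fluid=fluid,
                                water_density=water_density,
                                shape=shape,
                            )
                        except DecompositionUndefinedError as exc:
                            logger.warning(
                                "%s/%s pair %s excluded from molecular influence: %s",
                                species, condition, rep, exc,
                            )
                            continue
                        rows = [
                            ("water", result.influences["water"]),
                            ("dry_volume", result.influences["dry_volume"]),
                            ("dry_density", result.influences["dry_density"]),
                            ("dry", result.influence_of("dry")),
                        ]
                        for factor, infl in rows:
                            term = result.terms.get(factor)
                            if factor == "dry":
                                term = (
                                    result.terms["dry_volume"]
                                    + result.terms["dry_density"]
                                )
                            mol_influences.append(
                                {"species": species, "condition": condition,
                                 "replicate_pair": rep, "mode": "water_dry",
                                 "factor": factor, "term": term,
                                 "influence": infl, "valid": result.valid}
                            )
    influence_biophysical = pd.DataFrame(_aggregate_influences(bio_influences))
    influence_molecular = pd.DataFrame(_aggregate_influences(mol_influences))

    # --- transport numbers --------------------------------------------------
    peclet_rows = []
    for _, row in biophysics.iterrows():
        opts = _species_options(config, row["species"])
        length = float(opts.get("peclet_length_um", 2.0 * row["radius_um"]))
        for preset, diff in (("nitrate", D_NITRATE_UM2_S), ("virus", D_VIRUS_UM2_S)):
            peclet_rows.append(
                {
                    "species": row["species"],
                    "condition": row["condition"],
                    "replicate_id": row["replicate_id"],
                    "particle": preset,
                    "diffusivity_um2_s": diff,
                    "length_um": length,
                    "peclet": peclet_number(
                        TransportQuery(row["v_um_s"], length, diff)
                    ),
                }
            )
    peclet = pd.DataFrame(peclet_rows)

    # --- proliferation ------------------------------------------------------
    prolif_rows = []
    if counts is not None and len(counts):
        for (species, condition, rep), rows in counts.groupby(
            ["species", "condition", "replicate_id"], sort=True
        ):
            est = proliferation_rate(
                rows["count_per_ml"].to_numpy(), rows["day"].to_numpy()
            )
            prolif_rows.append(
                {"species": species, "condition": condition,
                 "replicate_id": str(rep), "doublings_per_day": est.rate,
                 "window_days": est.window}
            )
    else:
        flags["skipped"].append({"reason": "no cell-count table"})
    proliferation = pd.DataFrame(prolif_rows)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    from . import __version__

    provenance = {
        "config_hash": config_hash,
        "package_version": __version__,
        "baseline_condition": baseline_condition,
        "n_measurement_rows": int(len(measurements)),
    }
    return StudyReport(
        biophysics=biophysics,
        sinking_changes=sinking_changes,
        influence_biophysical=influence_biophysical,
        influence_molecular=influence_molecular,
        dry_water=dry_water,
        peclet=peclet,
        proliferation=proliferation,
        flags=flags,
        provenance=provenance,
    )


def _pair_states(base: pd.DataFrame, cond: pd.DataFrame, use_means: bool) -> list:
    """Yield (pair id, baseline row, perturbed row) tuples.

    By default pairs replicates by id; with ``use_means`` a single pair of
    condition-mean rows is produced instead.
    """
    if use_means:
        return [("mean", base.mean(numeric_only=True), cond.mean(numeric_only=True))]
    base_by_rep = {row["replicate_id"]: row for _, row in base.iterrows()}
    cond_by_rep = {row["replicate_id"]: row for _, row in cond.iterrows()}
    return [
        (rep, base_by_rep[rep], cond_by_rep[rep])
        for rep in sorted(set(base_by_rep) & set(cond_by_rep))
    ]
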