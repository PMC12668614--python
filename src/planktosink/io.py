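"""Configuration loading, tidy CSV interchange, and workbook import/export.

The canonical interchange format is a tidy, one-row-per-cell CSV with the
columns ``species, condition, replicate_id, instrument, fluid,
fluid_density_g_ml, value, unit``. A best-effort adapter imports workbook
files laid out sheet-per-figure; sheets whose header matches the tidy schema
are imported and everything else is listed in a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .physics import ComponentDensities, FluidEnvironment, MolecularComposition
from .study import MEASUREMENT_COLUMNS

__all__ = [
    "StudyConfig",
    "load_config",
    "read_measurements",
    "write_measurements",
    "read_counts",
    "import_s1_workbook",
    "export_workbook",
]

COUNT_COLUMNS = ["species", "condition", "replicate_id", "day", "count_per_ml"]

_PHYSICS_KEYS = {
    "fluid_density",
    "dynamic_viscosity",
    "gravity",
    "water_density",
    "component_densities",
}
_SPECIES_KEYS = {
    "shape_factor",
    "peclet_length_um",
    "min_volume_fl",
    "min_mass_pg",
    "composition",
}
_TOP_KEYS = {
    "physics",
    "species",
    "baseline_condition",
    "statistic",
    "use_condition_means",
    "significance_alpha",
}

# numbers are written with 9 significant digits in all package CSV output
_FLOAT_FORMAT = "%.9g"


@dataclass
class StudyConfig:
    """Validated study configuration (physics constants plus species table)."""

    physics: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    baseline_condition: str = "high"
    statistic: str = "mean"
    use_condition_means: bool = False
    significance_alpha: float = 0.05

    def fluid(self) -> FluidEnvironment:
        return FluidEnvironment(
            density=float(self.physics.get("fluid_density", 1.026)),
            dynamic_viscosity=float(self.physics.get("dynamic_viscosity", 1.07e-3)),
            gravity=float(self.physics.get("gravity", 9.81)),
        )

    def component_densities(self) -> ComponentDensities:
        overrides = dict(self.physics.get("component_densities", {}))
        if "water_density" in self.physics and "water" not in overrides:
            overrides["water"] = self.physics["water_density"]
        return ComponentDensities(**overrides)

    def composition_for(self, species: str) -> MolecularComposition | None:
        comp = (self.species.get(species) or {}).get("composition")
        if comp is None:
            return None
        return MolecularComposition(**{k: float(v) for k, v in comp.items()})

    def as_dict(self) -> dict:
        return {
            "physics": self.physics,
            "species": self.species,
            "baseline_condition": self.baseline_condition,
            "statistic": self.statistic,
            "use_condition_means": self.use_condition_means,
            "significance_alpha": self.significance_alpha,
        }


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study configuration; unknown keys are fatal."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    physics = raw.get("physics") or {}
    bad = set(physics) - _PHYSICS_KEYS
    if bad:
        raise ValidationError(f"{path}: unknown physics keys: {sorted(bad)}")
    species = raw.get("species") or {}
    for name, block in species.items():
        bad = set(block or {}) - _SPECIES_KEYS
        if bad:
            raise ValidationError(
                f"{path}: unknown keys for species {name!r}: {sorted(bad)}"
            )
    return StudyConfig(
        physics=physics,
        species=species,
        baseline_condition=raw.get("baseline_condition", "high"),
        statistic=raw.get("statistic", "mean"),
        use_condition_means=bool(raw.get("use_condition_means", False)),
        significance_alpha=float(raw.get("significance_alpha", 0.05)),
    )


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a tidy measurement CSV.

    Raises :class:`ValidationError` naming the offending rows on missing
    columns, unit mismatches or non-numeric values. A header-only file
    yields an empty (but well-formed) table.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"replicate_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        return df
    numeric = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[numeric.isna()].tolist()
    if bad:
        raise ValidationError(
            f"{path}: non-numeric 'value' in rows {_fmt_rows(bad)}", rows=bad
        )
    df["value"] = numeric
    expected_unit = df["instrument"].map(
        {"resonator": "pg", "impedance_counter": "fL"}
    )
    mismatch = df.index[df["unit"] != expected_unit].tolist()
    if mismatch:
        raise ValidationError(
            f"{path}: unit mismatch in rows {_fmt_rows(mismatch)} (resonator "
            "rows must be 'pg', impedance_counter rows 'fL')",
            rows=mismatch,
        )
    return df


def _fmt_rows(rows: list, limit: int = 10) -> str:
    # +2: account for the header line and 1-based numbering in the file
    shown = [str(r + 2) for r in rows[:limit]]
    suffix = "" if len(rows) <= limit else f" … ({len(rows)} total)"
    return ", ".join(shown) + suffix


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a tidy measurement table with the package's numeric formatting."""
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"replicate_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# workbook adapter
# ---------------------------------------------------------------------------


def export_workbook(tables: dict, path) -> None:
    """Write named tables to one workbook sheet each (tidy layout)."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, df in tables.items():
            df.to_excel(writer, sheet_name=str(name)[:31], index=False)


def import_s1_workbook(path) -> tuple:
    """Best-effort import of a sheet-per-figure workbook.

    Returns ``(tables, manifest)``: ``tables`` maps sheet names to tidy
    DataFrames for every sheet whose header contains the measurement schema;
    ``manifest`` records, per sheet, whether it was mapped and why not.
    Unreadable files raise ``OSError``.
    """
    path = Path(path)
    try:
        book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise OSError(f"could not read workbook {path}: {exc}") from exc
    tables: dict = {}
    manifest = []
    for sheet, df in book.items():
        entry = {"sheet": sheet, "n_rows": int(len(df))}
        if set(MEASUREMENT_COLUMNS).issubset(df.columns):
            sub = df[MEASUREMENT_COLUMNS].copy()
            sub["value"] = pd.to_numeric(sub["value"], errors="coerce")
            sub = sub.dropna(subset=["value"])
            sub["replicate_id"] = sub["replicate_id"].astype(str)
            tables[sheet] = sub
            entry.update(mapped=True, kind="measurements")
        elif set(COUNT_COLUMNS).issubset(df.columns):
            tables[sheet] = df[COUNT_COLUMNS].copy()
            entry.update(mapped=True, kind="counts")
        else:
            entry.update(
                mapped=False,
                kind="unknown",
                reason="header does not match any documented schema",
            )
        manifest.append(entry)
    return tables, manifest
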