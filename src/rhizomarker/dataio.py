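"""Tabular I/O and the core in-memory containers.

A :class:`FeatureTable` is the pipeline's central object: an aligned LC-MS
ion-feature table (m/z, retention time, ionization mode) crossed with a
sample design (soil type, extraction solution, replicate). Feature tables
are read from / written to plain CSV or TSV; the delimiter is inferred from
the extension (``.csv`` comma, ``.tsv``/``.txt`` tab) — no sniffing.

Missing intensities are stored as NaN, never as 0: a zero is a meaningful
"not detected" only for the raw presence/absence accounting, while NaN marks
a cell the aligner produced no value for.
"""

from __future__ import annotations

import dataclasses
import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .masses import formula_to_monoisotopic_mass

SOIL_TYPES = ("control", "plant")
SOLUTIONS = (0, 50, 95)  # % MeOH (v/v) in the acidified extraction solution
MODES = ("positive", "negative")

FEATURE_COLUMNS = ["feature_id", "mz", "rt", "mode"]

# library mass must agree with its formula to this tolerance (Da)
LIBRARY_MASS_TOL = 0.001


def _delimiter(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass(frozen=True)
class SampleInfo:
    """Design metadata for one sample column."""

    sample_id: str
    soil_type: str | None = None
    solution: int | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.soil_type is not None and self.soil_type not in SOIL_TYPES:
            raise ValidationError(
                f"soil_type {self.soil_type!r} for {self.sample_id}: expected one of {SOIL_TYPES}"
            )
        if self.solution is not None and self.solution not in SOLUTIONS:
            raise ValidationError(
                f"solution {self.solution!r} for {self.sample_id}: expected one of {SOLUTIONS}"
            )
        if self.replicate is not None and self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer ({self.sample_id})")


@dataclass(frozen=True)
class IonFeature:
    """One aligned (m/z, RT) ion signal."""

    feature_id: str
    mz: float
    rt: float  # seconds
    mode: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValidationError(f"feature {self.feature_id}: rt must be >= 0")
        if self.mode not in MODES:
            raise ValidationError(
                f"feature {self.feature_id}: mode {self.mode!r} not in {MODES}"
            )


@dataclass
class FeatureTable:
    """Ion features x samples intensity matrix plus design metadata.

    ``features``: DataFrame indexed by feature_id with columns mz, rt, mode.
    ``samples``: DataFrame indexed by sample_id with columns soil_type,
    solution, replicate (any may be missing when no design was supplied).
    ``intensities``: float array (n_features, n_samples), NaN = missing.
    ``stages_applied``: preprocessing stages already applied, in order; each
    stage may run at most once on a table.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    intensities: np.ndarray
    stages_applied: tuple[str, ...] = ()

    # -- construction / validation -------------------------------------------------

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        nf, ns = len(self.features), len(self.samples)
        if self.intensities.shape != (nf, ns):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{nf} features x {ns} samples"
            )
        if self.features.index.duplicated().any():
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature_id: {list(dupes)[:5]}")
        if self.samples.index.duplicated().any():
            dupes = self.samples.index[self.samples.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample_id: {list(dupes)[:5]}")
        if (self.features["mz"] <= 0).any():
            raise ValidationError("mz values must be > 0")
        if (self.features["rt"] < 0).any():
            raise ValidationError("rt values must be >= 0")
        bad_mode = set(self.features["mode"].unique()) - set(MODES)
        if bad_mode:
            raise FormatError(f"unknown ionization mode(s) {sorted(bad_mode)}; expected {MODES}")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValidationError("negative intensity encountered")
        if "soil_type" in self.samples:
            bad = set(self.samples["soil_type"].dropna().unique()) - set(SOIL_TYPES)
            if bad:
                raise ValidationError(f"unknown soil_type(s) {sorted(bad)}")

    # -- convenience ---------------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.samples.copy(), self.intensities.copy(),
            self.stages_applied,
        )

    def with_stage(self, stage: str, intensities: np.ndarray) -> "FeatureTable":
        if stage in self.stages_applied:
            raise ValidationError(f"preprocessing stage {stage!r} already applied")
        return FeatureTable(
            self.features.copy(), self.samples.copy(), intensities,
            self.stages_applied + (stage,),
        )

    def subset_samples(self, mask: Sequence[bool] | pd.Series) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.features.copy(), self.samples.loc[mask].copy(),
            self.intensities[:, mask], self.stages_applied,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = self.features.index.get_indexer(feature_ids)
        if (idx < 0).any():
            missing = [f for f, i in zip(feature_ids, idx) if i < 0]
            raise ValidationError(f"unknown feature_id(s): {missing[:5]}")
        return FeatureTable(
            self.features.iloc[idx].copy(), self.samples.copy(),
            self.intensities[idx], self.stages_applied,
        )

    def soil_mask(self, soil_type: str) -> np.ndarray:
        if "soil_type" not in self.samples:
            raise ValidationError("table has no sample design (soil_type missing)")
        return (self.samples["soil_type"] == soil_type).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: feature metadata columns followed by sample columns."""
        df = self.features.reset_index()
        inten = pd.DataFrame(self.intensities, columns=self.sample_ids)
        return pd.concat([df, inten], axis=1)


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry used for putative annotation."""

    name: str
    formula: str | None
    monoisotopic_mass: float
    met_class: str
    plausible_in_soil: bool

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValidationError(f"{self.name}: monoisotopic_mass must be > 0")
        if self.formula:
            computed = formula_to_monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) > LIBRARY_MASS_TOL:
                raise ValidationError(
                    f"{self.name}: mass {self.monoisotopic_mass:.4f} disagrees with "
                    f"formula {self.formula} ({computed:.4f} Da)"
                )


# -- readers ------------------------------------------------------------------------


def read_sample_design(path: str | Path) -> pd.DataFrame:
    """Sample design CSV/TSV with columns sample_id, soil_type, solution, replicate."""
    df = pd.read_csv(path, sep=_delimiter(path))
    required = {"sample_id", "soil_type", "solution", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample design missing column(s): {sorted(missing)}")
    for _, row in df.iterrows():
        SampleInfo(str(row["sample_id"]), str(row["soil_type"]),
                   int(row["solution"]), int(row["replicate"]))
    return df.set_index("sample_id")


def read_feature_table(
    path: str | Path, design: pd.DataFrame | str | Path | None = None
) -> FeatureTable:
    """Read a feature-table CSV/TSV.

    Layout: header ``feature_id, mz, rt, mode`` followed by one column per
    sample. Empty cells and "NA" are missing values. ``design`` (DataFrame
    indexed by sample_id, or a path) attaches soil_type/solution/replicate
    metadata to the sample columns.
    """
    df = pd.read_csv(path, sep=_delimiter(path), na_values=["NA"], keep_default_na=True)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path}: missing mandatory column(s) {missing}")
    features = df[FEATURE_COLUMNS].copy()
    features["feature_id"] = features["feature_id"].astype(str)
    features = features.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    if not sample_cols:
        raise FormatError(f"feature table {path}: no sample columns")
    intensities = df[sample_cols].to_numpy(dtype=float)

    if isinstance(design, (str, Path)):
        design = read_sample_design(design)
    if design is not None:
        unknown = [s for s in sample_cols if s not in design.index]
        if unknown:
            raise ValidationError(f"sample column(s) not in design: {unknown}")
        samples = design.loc[sample_cols].copy()
    else:
        samples = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"))
    return FeatureTable(features, samples, intensities)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep=_delimiter(path), index=False, na_rep="")


def write_sample_design(table: FeatureTable, path: str | Path) -> None:
    table.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep=_delimiter(path), index=False
    )


def read_compound_library(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a compound-library CSV (bundled default library when path is None).

    Columns: name, formula, monoisotopic_mass (optional when formula given),
    class, plausible_in_soil. Compound names are normalized to Unicode NFC.
    """
    if path is None:
        with resources.as_file(
            resources.files("rhizomarker").joinpath("data/compound_library.csv")
        ) as p:
            return read_compound_library(p)
    df = pd.read_csv(path, sep=_delimiter(path))
    required = {"name", "formula", "class", "plausible_in_soil"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"compound library missing column(s): {sorted(missing)}")
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        name = unicodedata.normalize("NFC", str(row["name"]))
        formula = row["formula"] if isinstance(row["formula"], str) and row["formula"].strip() else None
        mass = row.get("monoisotopic_mass", np.nan)
        if mass is None or (isinstance(mass, float) and np.isnan(mass)):
            if formula is None:
                raise ValidationError(f"{name}: neither monoisotopic_mass nor formula given")
            mass = formula_to_monoisotopic_mass(formula)
        records.append(
            CompoundRecord(
                name=name,
                formula=formula,
                monoisotopic_mass=float(mass),
                met_class=str(row["class"]),
                plausible_in_soil=_parse_bool(row["plausible_in_soil"], name),
            )
        )
    return records


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


# -- report writing ------------------------------------------------------------------


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return {c: _to_jsonable(obj[c].tolist()) for c in obj.columns}
    if isinstance(obj, pd.Series):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Serialize a pipeline result deterministically to JSON or TSV.

    JSON handles any nesting of dataclasses, DataFrames, arrays and mappings;
    TSV expects a DataFrame or a list of flat records (one row per entry; an
    empty list yields a header-only file when columns are known).
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(results), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        if isinstance(results, pd.DataFrame):
            df = results
        else:
            rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                    for r in results]
            df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown report format {format!r} (json or tsv)")
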