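"""Data model and file contracts for regional morphometry feature tables.

The pipeline operates on subject-level tables of regional cortical
morphometry: for each of 33 bilateral cortical regions we carry four
measures per hemisphere — gray matter volume (GMV), white matter volume
(WMV), cerebrospinal fluid volume (CSF), all in mm^3, and mean cortical
thickness (CT) in mm — giving 33 x 2 x 4 = 264 features per subject,
plus chronological age (years) and sex.

Feature columns are named ``region__hemisphere__measure`` with a
double-underscore separator so region labels may themselves contain
single underscores (normalized from spaces/hyphens).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MEASURES",
    "MEASURE_UNITS",
    "HEMISPHERES",
    "DEFAULT_REGIONS",
    "PARENCHYMA",
    "INTRACRANIAL",
    "MEASURE_COMBINATIONS",
    "RegionSchema",
    "FeatureTable",
    "MeasureCombination",
    "SchemaMismatchError",
    "ValidationError",
    "feature_name",
    "parse_feature_name",
    "load_feature_table",
    "assemble_feature_matrix",
    "write_results",
    "read_results",
]

MEASURES: tuple[str, ...] = ("GMV", "WMV", "CSF", "CT")
MEASURE_UNITS: dict[str, str] = {"GMV": "mm3", "WMV": "mm3", "CSF": "mm3", "CT": "mm"}
VOLUME_MEASURES: tuple[str, ...] = ("GMV", "WMV", "CSF")
HEMISPHERES: tuple[str, str] = ("left", "right")
SEXES: tuple[str, str] = ("male", "female")

# Default registry of 33 bilateral cortical region labels. The atlas contract
# is the count and the label set, not anatomy: all computations key on labels.
# The five regions that anchor the default synthetic preset (pre-central
# gyrus, cingulate, superior temporal gyrus, insula, superior frontal gyrus)
# are included under their normalized names.
DEFAULT_REGIONS: tuple[str, ...] = (
    "superior_frontal_gyrus",
    "middle_frontal_gyrus",
    "inferior_frontal_gyrus",
    "pre_central_gyrus",
    "post_central_gyrus",
    "paracentral_lobule",
    "superior_parietal_gyrus",
    "inferior_parietal_lobule",
    "supramarginal_gyrus",
    "angular_gyrus",
    "pre_cuneus",
    "cuneus",
    "superior_occipital_gyrus",
    "middle_occipital_gyrus",
    "inferior_occipital_gyrus",
    "lingual_gyrus",
    "fusiform_gyrus",
    "parahippocampal_gyrus",
    "superior_temporal_gyrus",
    "middle_temporal_gyrus",
    "inferior_temporal_gyrus",
    "temporal_pole",
    "transverse_temporal_gyrus",
    "insula",
    "cingulate",
    "gyrus_rectus",
    "medial_orbitofrontal_gyrus",
    "lateral_orbitofrontal_gyrus",
    "entorhinal_cortex",
    "planum_temporale",
    "frontal_pole",
    "occipital_pole",
    "subcallosal_gyrus",
)

META_COLUMNS: tuple[str, ...] = ("subject_id", "age", "sex")


class SchemaMismatchError(ValueError):
    """Feature columns do not match the declared region schema."""


class ValidationError(ValueError):
    """Table contents violate a data invariant (range, sign, missingness)."""


def normalize_label(label: str) -> str:
    """Normalize a region label: lowercase, spaces/hyphens to underscores."""
    return re.sub(r"[\s\-]+", "_", label.strip().lower())


def feature_name(region: str, hemisphere: str, measure: str) -> str:
    return f"{region}__{hemisphere}__{measure}"


def parse_feature_name(name: str) -> tuple[str, str, str]:
    parts = name.split("__")
    if len(parts) != 3:
        raise SchemaMismatchError(
            f"feature column {name!r} does not follow region__hemisphere__measure"
        )
    return parts[0], parts[1], parts[2]


@dataclass(frozen=True)
class RegionSchema:
    """The feature naming contract: regions x hemispheres x measures.

    The default full schema has 33 regions, two hemispheres and four
    measures, i.e. 264 features. Sub-schemas (fewer regions/measures) are
    legal and useful in tests; every operation derives its feature set from
    the schema rather than assuming 264.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    hemispheres: tuple[str, ...] = HEMISPHERES
    measures: tuple[str, ...] = MEASURES
    units: dict[str, str] = field(default_factory=lambda: dict(MEASURE_UNITS))

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("region labels must be unique")
        if len(set(self.measures)) != len(self.measures):
            raise ValidationError("measures must be unique")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValidationError(f"unknown measures: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        return len(self.regions) * len(self.hemispheres) * len(self.measures)

    def feature_keys(self) -> list[tuple[str, str, str]]:
        """Ordered (region, hemisphere, measure) keys: region-major, then
        hemisphere (left before right), then measure (GMV, WMV, CSF, CT)."""
        return [
            (r, h, m)
            for r in self.regions
            for h in self.hemispheres
            for m in self.measures
        ]

    def feature_names(self) -> list[str]:
        return [feature_name(r, h, m) for r, h, m in self.feature_keys()]

    def subset(
        self,
        regions: Sequence[str] | None = None,
        hemispheres: Sequence[str] | None = None,
        measures: Sequence[str] | None = None,
    ) -> "RegionSchema":
        return RegionSchema(
            regions=tuple(regions) if regions is not None else self.regions,
            hemispheres=tuple(hemispheres) if hemispheres is not None else self.hemispheres,
            measures=tuple(measures) if measures is not None else self.measures,
            units={m: MEASURE_UNITS[m] for m in (measures or self.measures)},
        )

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "hemispheres": list(self.hemispheres),
            "measures": list(self.measures),
            "units": dict(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSchema":
        return cls(
            regions=tuple(normalize_label(r) for r in d["regions"]),
            hemispheres=tuple(d.get("hemispheres", HEMISPHERES)),
            measures=tuple(d.get("measures", MEASURES)),
            units=dict(d.get("units", MEASURE_UNITS)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class MeasureCombination:
    """A named sum of measures within a region (e.g. parenchyma = GMV+WMV)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.members) - set(MEASURES)
        if unknown:
            raise ValidationError(f"unknown measures in combination: {sorted(unknown)}")


PARENCHYMA = MeasureCombination("parenchyma", ("GMV", "WMV"))
INTRACRANIAL = MeasureCombination("intracranial", ("GMV", "WMV", "CSF"))
MEASURE_COMBINATIONS: dict[str, MeasureCombination] = {
    c.name: c for c in (PARENCHYMA, INTRACRANIAL)
}


@dataclass
class FeatureTable:
    """A validated subjects x features morphometry table.

    Wraps a :class:`pandas.DataFrame` with columns ``subject_id``, ``age``
    (years), ``sex`` ({male, female}) followed by one column per schema
    feature, in schema order.
    """

    df: pd.DataFrame
    schema: RegionSchema

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return self.df["sex"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    def validate(self) -> "FeatureTable":
        """Check column contract and value invariants; raise on violation."""
        for col in META_COLUMNS:
            if col not in self.df.columns:
                raise SchemaMismatchError(f"missing metadata column {col!r}")
        expected = self.schema.feature_names()
        present = [c for c in self.df.columns if c not in META_COLUMNS]
        missing = sorted(set(expected) - set(present))
        extra = sorted(set(present) - set(expected))
        if missing:
            raise SchemaMismatchError(f"missing feature column(s): {missing[:5]}")
        if extra:
            raise SchemaMismatchError(f"unexpected feature column(s): {extra[:5]}")

        ages = self.df["age"].to_numpy(dtype=float)
        if len(ages):
            if not np.all(np.isfinite(ages)):
                bad = self.df.loc[~np.isfinite(ages), "subject_id"].tolist()
                raise ValidationError(f"non-finite age for subject(s) {bad[:5]}")
            if ages.min() < 0 or ages.max() > 120:
                bad = self.df.loc[(ages < 0) | (ages > 120), "subject_id"].tolist()
                raise ValidationError(f"age outside [0, 120] for subject(s) {bad[:5]}")
            bad_sex = sorted(set(self.df["sex"]) - set(SEXES))
            if bad_sex:
                raise ValidationError(f"sex values must be in {SEXES}; got {bad_sex}")
        for name in expected:
            vals = self.df[name].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            if not np.all(np.isfinite(vals)):
                bad = self.df.loc[~np.isfinite(vals), "subject_id"].tolist()
                raise ValidationError(f"non-finite value in {name} for {bad[:5]}")
            if np.any(vals <= 0):
                bad = self.df.loc[vals <= 0, "subject_id"].tolist()
                raise ValidationError(
                    f"non-positive value in {name} for subject(s) {bad[:5]}"
                )
        # normalize column order to schema order
        self.df = self.df[list(META_COLUMNS) + expected]
        return self

    def subset_rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df.loc[mask].reset_index(drop=True), self.schema)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def feature_matrix(self) -> tuple[np.ndarray, list[str]]:
        return assemble_feature_matrix(self, self.schema)


def load_feature_table(path: str | Path, schema: RegionSchema) -> FeatureTable:
    """Read a CSV feature table and validate it against *schema*.

    The file must have a header with ``subject_id, age, sex`` and one
    column per schema feature named ``region__hemisphere__measure``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    return FeatureTable(df, schema).validate()


def assemble_feature_matrix(
    table: FeatureTable, schema: RegionSchema
) -> tuple[np.ndarray, list[str]]:
    """Return the (subjects x features) float matrix and its column index.

    Column order is deterministic: schema region order, then left/right,
    then GMV/WMV/CSF/CT.
    """
    names = schema.feature_names()
    missing = [n for n in names if n not in table.df.columns]
    if missing:
        raise SchemaMismatchError(f"table lacks feature column(s): {missing[:5]}")
    mat = table.df[names].to_numpy(dtype=float)
    return mat, names


# -- generic structured-results I/O -------------------------------------


def write_results(obj, path: str | Path) -> None:
    """Serialize a results object (anything with ``to_dict``) to JSON.

    Round-trippable: :func:`read_results` on the written file reproduces
    the dictionary exactly (labels bit-exact, reals at full repr precision).
    """
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
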