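"""Standardized numeric feature matrices for graph construction and classification.

Continuous variables are z-scored with the cohort's own mean/SD (population,
``ddof=0``, switchable); categoricals are one-hot encoded with a deterministic
level order; booleans pass through as 0/1 columns.  Scaling and encoding
parameters are stored so held-out rows can be projected with training-set
statistics (no leakage).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ACTIVITY_VARS,
    BIOMARKER_VARS,
    DISEASES,
    EDUCATION_LEVELS,
    MARITAL_LEVELS,
    NUTRIENT_VARS,
    PatientRecord,
)

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "build_feature_matrix", "default_feature_spec"]

#: categorical variable -> deterministic level order
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "marital_status": MARITAL_LEVELS,
    "education": EDUCATION_LEVELS,
}

_BOOLEAN_VARS = ("smoking_100",) + DISEASES

CONTINUOUS_VARS = ("age", "family_pir", "bmi") + BIOMARKER_VARS + ACTIVITY_VARS + NUTRIENT_VARS


def default_feature_spec(
    include_diseases: bool = False,
    records: Sequence[PatientRecord] | None = None,
) -> list[str]:
    """All demographic, lifestyle and biomarker variables, in canonical order.

    When ``records`` is given, the list is restricted to the variables
    actually present on the first record (cohorts are complete-case).
    """
    spec = list(CONTINUOUS_VARS) + ["gender", "marital_status", "education", "smoking_100"]
    if include_diseases:
        spec += list(DISEASES)
    if records:
        first = records[0]
        present = (
            {"age", "family_pir", "bmi", "gender", "marital_status", "education", "smoking_100"}
            | set(first.activity_minutes)
            | set(first.nutrient_intakes)
            | set(first.biomarkers)
            | set(first.diseases)
        )
        spec = [name for name in spec if name in present]
    return spec


def _raw_value(record: PatientRecord, name: str):
    if name in ("age", "family_pir", "bmi", "gender", "marital_status", "education", "smoking_100"):
        return getattr(record, name)
    if name in record.activity_minutes:
        return record.activity_minutes[name]
    if name in record.nutrient_intakes:
        return record.nutrient_intakes[name]
    if name in record.biomarkers:
        return record.biomarkers[name]
    if name in record.diseases:
        return record.diseases[name]
    raise KeyError(f"feature {name!r} not present on record {record.id}")


@dataclass
class FeatureMatrix:
    """Patients x features matrix plus the transform parameters that built it."""

    values: np.ndarray
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]]
    encoding_map: dict[str, dict[str, int]]  # categorical -> level -> column index
    row_ids: list[str]
    spec: list[str] = field(default_factory=list)
    ddof: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transform(self, records: Sequence[PatientRecord]) -> np.ndarray:
        """Project new rows through the stored scaling/encoding (no refitting)."""
        n = len(records)
        out = np.zeros((n, len(self.feature_names)))
        col_of = {name: j for j, name in enumerate(self.feature_names)}
        for i, rec in enumerate(records):
            for name in self.spec:
                if name in self.scaling:
                    mean, sd = self.scaling[name]
                    out[i, col_of[name]] = (float(_raw_value(rec, name)) - mean) / sd
                elif name in self.encoding_map:
                    level = str(_raw_value(rec, name))
                    j = self.encoding_map[name].get(level)
                    if j is None:
                        raise ValueError(f"unseen level {level!r} for {name!r}")
                    out[i, j] = 1.0
                elif name in col_of:  # boolean passthrough
                    out[i, col_of[name]] = float(bool(_raw_value(rec, name)))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=self.row_ids)

    def export(self, matrix_path: str | Path, params_path: str | Path | None = None) -> None:
        """Write the matrix as TSV and the transform parameters as JSON."""
        self.to_frame().to_csv(matrix_path, sep="\t", index_label="id")
        if params_path is not None:
            Path(params_path).write_text(
                json.dumps(
                    {
                        "scaling": {k: list(v) for k, v in self.scaling.items()},
                        "encoding_map": self.encoding_map,
                        "feature_names": self.feature_names,
                        "spec": self.spec,
                        "ddof": self.ddof,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )


def build_feature_matrix(
    records: Sequence[PatientRecord],
    spec: Sequence[str] | None = None,
    include_diseases: bool = False,
    ddof: int = 0,
) -> FeatureMatrix:
    """Assemble the standardized matrix over ``spec`` (default: all variables).

    Continuous columns are z-scored with the cohort mean and SD (``ddof``
    selects population vs sample SD); zero-variance continuous columns are
    dropped with a warning.  Categoricals expand to one-hot blocks in fixed
    level order; booleans become 0/1 columns.  Column order is spec order.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a feature matrix")
    if spec is None:
        spec = default_feature_spec(include_diseases=include_diseases, records=records)
    else:
        spec = list(spec)
        if include_diseases:
            spec += [d for d in DISEASES if d not in spec]

    columns: list[np.ndarray] = []
    names: list[str] = []
    scaling: dict[str, tuple[float, float]] = {}
    encoding: dict[str, dict[str, int]] = {}
    kept_spec: list[str] = []

    for name in spec:
        if name in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[name]
            raw = [str(_raw_value(r, name)) for r in records]
            unknown = set(raw) - set(levels)
            if unknown:
                raise ValueError(f"unknown level(s) {unknown} for {name!r}")
            block = {}
            for level in levels:
                col = np.array([1.0 if v == level else 0.0 for v in raw])
                block[level] = len(names)
                columns.append(col)
                names.append(f"{name}={level}")
            encoding[name] = block
            kept_spec.append(name)
        elif name in _BOOLEAN_VARS:
            col = np.array([float(bool(_raw_value(r, name))) for r in records])
            columns.append(col)
            names.append(name)
            kept_spec.append(name)
        else:
            col = np.array([float(_raw_value(r, name)) for r in records])
            mean = float(col.mean())
            sd = float(col.std(ddof=ddof))
            if sd == 0.0:
                msg = f"dropping zero-variance continuous feature {name!r}"
                warnings.warn(msg)
                logger.warning(msg)
                continue
            columns.append((col - mean) / sd)
            names.append(name)
            scaling[name] = (mean, sd)
            kept_spec.append(name)

    if not columns:
        raise ValueError("no usable features after zero-variance drop")
    values = np.column_stack(columns)
    return FeatureMatrix(
        values=values,
        feature_names=names,
        scaling=scaling,
        encoding_map=encoding,
        row_ids=[r.id for r in records],
        spec=kept_spec,
        ddof=ddof,
    )
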