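"""Synthetic multimorbid cohort generation, diagnostic flagging and inclusion filtering.

The generator draws patients from a mixture of planted subgroups: each group has
its own Gaussian parameters for the continuous variables, its own categorical
level shares, and its own Bernoulli disease prevalences.  Disease flags are made
self-consistent by back-filling raw diagnostic measurements that reproduce each
flag under :func:`flag_diseases`, so every generated record satisfies the
round-trip invariant ``flag_diseases(record.raw) == record.diseases``.

A bundled four-group default template (:func:`default_config`) mimics the
marginal structure of a 2,306-patient multimorbid survey cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "ACTIVITY_VARS",
    "BIOMARKER_VARS",
    "NUTRIENT_VARS",
    "MARITAL_LEVELS",
    "EDUCATION_LEVELS",
    "RawMeasurements",
    "PatientRecord",
    "SynthConfig",
    "flag_diseases",
    "filter_cmm",
    "generate_cohort",
    "default_config",
    "planted_config",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort",
    "read_cohort",
]

DISEASES = ("hypertension", "dyslipidemia", "diabetes", "ckd", "hyperuricemia")

ACTIVITY_VARS = (
    "vigorous_work",
    "moderate_work",
    "walk_bicycle",
    "vigorous_recreational",
    "moderate_recreational",
    "sedentary",
)

BIOMARKER_VARS = (
    "white_blood_cell_count",
    "lymphocyte_percent",
    "red_blood_cell_count",
    "red_cell_distribution_width",
    "hs_crp",
    "fasting_glucose",
    "alkaline_phosphatase",
    "hematocrit",
)

NUTRIENT_VARS = (
    "protein",
    "carbohydrate",
    "dietary_fiber",
    "saturated_fat",
    "monounsaturated_fat",
    "polyunsaturated_fat",
    "cholesterol",
    "vitamin_e",
    "retinol",
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "niacin",
    "vitamin_b6",
    "folate",
    "choline",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_d",
    "vitamin_k",
    "calcium",
    "phosphorus",
    "magnesium",
    "iron",
    "zinc",
    "copper",
    "sodium",
    "potassium",
    "selenium",
    "caffeine",
    "theobromine",
    "alcohol",
)

MARITAL_LEVELS = (
    "married",
    "widowed",
    "divorced",
    "separated",
    "never_married",
    "living_with_partner",
)

EDUCATION_LEVELS = (
    "less_than_9th",
    "grade_9_11",
    "high_school",
    "some_college",
    "college_graduate",
)

#: Physiologic clipping bounds for Gaussian draws (documented constants).
#: Variables not listed are clipped to [0, inf).
CLIP_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 90.0),
    "family_pir": (0.0, 10.0),
    "bmi": (12.0, 80.0),
    "lymphocyte_percent": (1.0, 95.0),
    "hematocrit": (15.0, 65.0),
}

# Diagnostic cutoffs (comparators follow the printed definitions exactly).
SBP_CUTOFF = 140.0          # strict >
DBP_CUTOFF = 90.0           # strict >
TC_CUTOFF = 5.18            # >= , mmol/L
TG_CUTOFF = 1.70            # >= , mmol/L
LDL_CUTOFF = 3.37           # >= , mmol/L
HDL_CUTOFF = 1.04           # strict < , mmol/L
FPG_CUTOFF = 7.0            # >= , mmol/L
OGTT_CUTOFF = 11.1          # >= , mmol/L
ACR_CUTOFF = 30.0           # >= , mg/g
EGFR_CUTOFF = 60.0          # strict < , mL/min/1.73m2
URIC_ACID_CUTOFF_MALE = 420.0    # strict > , umol/L
URIC_ACID_CUTOFF_FEMALE = 357.0  # strict > , umol/L


@dataclass(frozen=True)
class RawMeasurements:
    """Raw diagnostic measurements for one subject.

    Concentrations are in the units of the diagnostic cutoffs (mmol/L for
    lipids and glucose, mg/g for ACR, µmol/L for uric acid).  Duration
    criteria ("lasting more than 3 months") are represented as boolean
    persistence flags because single-visit data cannot verify duration;
    ``low_egfr_over_3mo`` defaults to True so a low eGFR alone is treated
    as persistent.
    """

    sex: str
    systolic_bp: float
    diastolic_bp: float
    dx_hypertension: bool
    total_cholesterol: float
    triglycerides: float
    ldl_c: float
    hdl_c: float
    fasting_glucose: float
    dx_diabetes: bool
    acr: float
    egfr: float
    serum_uric_acid: float
    ogtt_2h_glucose: float | None = None
    kidney_damage_over_3mo: bool = False
    low_egfr_over_3mo: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(
                f"sex must be 'male' or 'female', got {self.sex!r}; "
                "the hyperuricemia cutoff is sex-specific"
            )
        for name in (
            "total_cholesterol",
            "triglycerides",
            "ldl_c",
            "hdl_c",
            "fasting_glucose",
            "acr",
            "egfr",
            "serum_uric_acid",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.ogtt_2h_glucose is not None and self.ogtt_2h_glucose < 0:
            raise ValueError(f"ogtt_2h_glucose must be >= 0, got {self.ogtt_2h_glucose}")
        for name in ("systolic_bp", "diastolic_bp"):
            value = getattr(self, name)
            if not (0 < value < 400):
                raise ValueError(f"{name} must lie in (0, 400), got {value}")


def flag_diseases(m: RawMeasurements) -> dict[str, bool]:
    """Evaluate the five diagnostic rules on raw measurements.

    Returns a dict keyed by :data:`DISEASES`.  Deterministic and idempotent;
    comparator direction (strict vs inclusive) follows the printed cutoffs.
    """
    hypertension = (
        m.systolic_bp > SBP_CUTOFF or m.diastolic_bp > DBP_CUTOFF or m.dx_hypertension
    )
    dyslipidemia = (
        m.total_cholesterol >= TC_CUTOFF
        or m.triglycerides >= TG_CUTOFF
        or m.ldl_c >= LDL_CUTOFF
        or m.hdl_c < HDL_CUTOFF
    )
    diabetes = (
        m.fasting_glucose >= FPG_CUTOFF
        or (m.ogtt_2h_glucose is not None and m.ogtt_2h_glucose >= OGTT_CUTOFF)
        or m.dx_diabetes
    )
    ckd = (
        m.kidney_damage_over_3mo
        or m.acr >= ACR_CUTOFF
        or (m.egfr < EGFR_CUTOFF and m.low_egfr_over_3mo)
    )
    cutoff = URIC_ACID_CUTOFF_MALE if m.sex == "male" else URIC_ACID_CUTOFF_FEMALE
    hyperuricemia = m.serum_uric_acid > cutoff
    return {
        "hypertension": hypertension,
        "dyslipidemia": dyslipidemia,
        "diabetes": diabetes,
        "ckd": ckd,
        "hyperuricemia": hyperuricemia,
    }


@dataclass
class PatientRecord:
    """One subject: demographics, lifestyle, biomarkers, raw measurements, flags."""

    id: str
    age: float
    gender: str
    marital_status: str
    education: str
    family_pir: float
    bmi: float
    smoking_100: bool
    activity_minutes: dict[str, float]
    nutrient_intakes: dict[str, float]
    biomarkers: dict[str, float]
    diseases: dict[str, bool]
    raw: RawMeasurements | None = None
    planted_group: int | None = None

    @property
    def n_diseases(self) -> int:
        return sum(bool(v) for v in self.diseases.values())


def filter_cmm(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Keep subjects with at least two of the five disease flags.

    Order preserved; the input list is not mutated.
    """
    return [r for r in records if r.n_diseases >= 2]


@dataclass
class SynthConfig:
    """Mixture-of-groups generator configuration.

    ``continuous`` maps variable name -> (per-group means, per-group SDs);
    ``categorical`` maps variable name -> {level: per-group probabilities}
    (probabilities are normalized per group); ``binary`` maps variable name
    -> per-group Bernoulli probabilities; ``disease_prevalence`` likewise.
    """

    n_patients: int
    group_weights: tuple[float, ...]
    disease_prevalence: Mapping[str, tuple[float, ...]]
    continuous: Mapping[str, tuple[tuple[float, ...], tuple[float, ...]]]
    categorical: Mapping[str, Mapping[str, tuple[float, ...]]]
    binary: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_weights)

    def validate(self) -> None:
        k = self.n_groups
        if k < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = float(sum(self.group_weights))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_weights must sum to 1 (got {total})")
        for disease, probs in self.disease_prevalence.items():
            if len(probs) != k:
                raise ValueError(f"{disease}: expected {k} prevalences")
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"{disease}: prevalences must lie in [0, 1]")
        for name, (means, sds) in self.continuous.items():
            if len(means) != k or len(sds) != k:
                raise ValueError(f"{name}: expected {k} means and SDs")
            if any(s <= 0 for s in sds):
                raise ValueError(f"{name}: SDs must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["continuous"] = {k: [list(v[0]), list(v[1])] for k, v in self.continuous.items()}
        d["categorical"] = {
            k: {lvl: list(p) for lvl, p in levels.items()}
            for k, levels in self.categorical.items()
        }
        d["disease_prevalence"] = {k: list(v) for k, v in self.disease_prevalence.items()}
        d["binary"] = {k: list(v) for k, v in self.binary.items()}
        d["group_weights"] = list(self.group_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        return cls(
            n_patients=int(d["n_patients"]),
            group_weights=tuple(d["group_weights"]),
            disease_prevalence={k: tuple(v) for k, v in d["disease_prevalence"].items()},
            continuous={k: (tuple(v[0]), tuple(v[1])) for k, v in d["continuous"].items()},
            categorical={
                k: {lvl: tuple(p) for lvl, p in levels.items()}
                for k, levels in d["categorical"].items()
            },
            binary={k: tuple(v) for k, v in d.get("binary", {}).items()},
            rng_seed=int(d.get("rng_seed", 0)),
        )


# --------------------------------------------------------------------------
# Bundled four-group default template (group order: I, II, III, IV).
# Weights use the exact subgroup sizes 471/127/1463/245 over 2306.

_T = 2306.0
_DEFAULT_WEIGHTS = (471 / _T, 127 / _T, 1463 / _T, 245 / _T)

_DEFAULT_PREVALENCE = {
    "hypertension": (0.520, 0.362, 0.450, 0.359),
    "dyslipidemia": (0.701, 0.693, 0.660, 0.612),
    "diabetes": (0.318, 0.252, 0.283, 0.261),
    "ckd": (0.310, 0.307, 0.305, 0.208),
    "hyperuricemia": (0.200, 0.220, 0.228, 0.139),
}

_DEFAULT_CONTINUOUS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "age": ((53.909, 48.307, 50.758, 46.192), (16.472, 17.066, 17.781, 17.050)),
    "family_pir": ((3.156, 2.399, 2.391, 2.196), (1.594, 1.531, 1.579, 1.486)),
    "bmi": ((31.044, 29.598, 29.130, 29.312), (7.841, 6.802, 7.107, 7.189)),
    # biomarkers
    "white_blood_cell_count": ((6.473, 6.771, 6.841, 7.209), (1.764, 1.964, 2.018, 2.188)),
    "lymphocyte_percent": ((33.292, 35.725, 31.323, 28.535), (8.656, 9.906, 8.787, 8.225)),
    "red_blood_cell_count": ((4.840, 4.936, 4.790, 4.738), (0.497, 0.530, 0.523, 0.548)),
    "red_cell_distribution_width": ((13.621, 13.791, 13.855, 13.938), (1.127, 1.216, 1.414, 1.540)),
    "hs_crp": ((3.354, 2.934, 4.120, 4.253), (5.812, 4.382, 8.717, 6.877)),
    "fasting_glucose": ((111.017, 112.968, 111.896, 109.282), (39.077, 47.280, 36.553, 31.795)),
    "alkaline_phosphatase": ((79.554, 78.850, 87.532, 83.037), (35.667, 38.296, 55.262, 44.595)),
    "hematocrit": ((42.525, 41.200, 41.416, 41.531), (3.682, 4.651, 4.154, 3.887)),
    # weekly activity minutes
    "vigorous_work": ((157.113, 1616.921, 97.946, 374.571), (410.032, 1397.569, 302.866, 763.235)),
    "moderate_work": ((399.781, 1164.685, 282.013, 469.306), (2358.913, 1074.212, 583.865, 799.639)),
    "walk_bicycle": ((55.881, 107.559, 64.515, 92.612), (214.567, 296.766, 273.906, 393.905)),
    "vigorous_recreational": ((63.457, 154.724, 41.636, 80.229), (143.852, 388.062, 116.055, 148.127)),
    "moderate_recreational": ((91.306, 194.803, 72.826, 123.674), (151.082, 379.348, 170.063, 251.381)),
    "sedentary": ((401.391, 266.378, 342.239, 340.653), (491.188, 181.333, 200.361, 182.587)),
    # daily nutrient intakes
    "protein": ((100.721, 61.721, 63.382, 130.382), (25.212, 26.146, 22.168, 45.261)),
    "carbohydrate": ((275.29, 201.988, 209.545, 375.904), (88.015, 101.539, 81.757, 151.098)),
    "dietary_fiber": ((20.998, 13.416, 14.016, 26.205), (9.225, 8.946, 7.283, 13.74)),
    "saturated_fat": ((36.03, 20.232, 20.822, 42.885), (13.238, 10.038, 9.542, 19.642)),
    "monounsaturated_fat": ((39.623, 21.828, 22.464, 44.745), (13.804, 11.603, 9.38, 19.276)),
    "polyunsaturated_fat": ((26.192, 14.012, 15.645, 29.443), (11.084, 7.952, 7.534, 14.586)),
    "cholesterol": ((467.902, 213.732, 228.522, 488.849), (200.961, 159.362, 127.902, 308.896)),
    "vitamin_e": ((11.729, 5.946, 6.789, 14.052), (5.621, 3.221, 3.534, 7.454)),
    "retinol": ((475.121, 221.047, 292.743, 827.102), (231.611, 166.408, 203.996, 603.779)),
    "vitamin_a": ((721.091, 364.181, 472.139, 1107.604), (371.743, 263.716, 349.309, 673.942)),
    "vitamin_b1": ((1.764, 1.186, 1.291, 2.807), (0.547, 0.56, 0.542, 1.07)),
    "vitamin_b2": ((2.426, 1.717, 1.531, 3.588), (0.746, 1.09, 0.631, 1.415)),
    "niacin": ((28.15, 21.106, 19.99, 45.233), (9.267, 12.314, 8.35, 17.739)),
    "vitamin_b6": ((2.279, 1.711, 1.569, 4.013), (0.735, 1.404, 0.769, 2.27)),
    "folate": ((421.431, 268.898, 311.854, 707.551), (143.556, 131.559, 146.824, 321.959)),
    "choline": ((466.792, 250.007, 252.747, 532.872), (131.847, 123.028, 99.883, 221.019)),
    "vitamin_b12": ((5.092, 3.636, 3.214, 10.362), (2.564, 3.419, 2.158, 9.103)),
    "vitamin_c": ((97.096, 67.35, 64.189, 123.535), (77.475, 75.682, 58.09, 111.315)),
    "vitamin_d": ((5.266, 2.865, 3.142, 10.206), (4.179, 2.88, 2.792, 8.11)),
    "vitamin_k": ((149.644, 83.16, 102.4, 155.814), (134.98, 96.272, 120.535, 151.289)),
    "calcium": ((1074.03, 683.284, 732.256, 1572.6), (382.539, 327.87, 340.822, 620.635)),
    "phosphorus": ((1691.055, 1022.347, 1056.046, 2227.816), (390.797, 392.88, 355.769, 711.208)),
    "magnesium": ((367.259, 246.764, 236.857, 467.706), (110.817, 107.479, 87.308, 172.313)),
    "iron": ((15.601, 10.243, 11.277, 25.696), (4.505, 5.386, 4.978, 10.212)),
    "zinc": ((13.008, 8.291, 8.259, 20.093), (3.811, 5.408, 3.438, 16.979)),
    "copper": ((1.484, 0.968, 0.941, 1.908), (0.546, 0.552, 0.367, 1.439)),
    "sodium": ((4215.527, 2632.803, 2801.813, 5269.396), (1293.447, 1151.671, 1044.642, 1953.755)),
    "potassium": ((3243.682, 2203.102, 2070.932, 4012.51), (825.286, 941.963, 733.943, 1302.872)),
    "selenium": ((142.409, 86.656, 90.351, 187.164), (44.964, 41.239, 35.262, 81.941)),
    "caffeine": ((182.076, 251.126, 116.212, 153.192), (188.95, 458.15, 138.925, 156.449)),
    "theobromine": ((55.2, 29.85, 25.052, 42.082), (84.219, 63.391, 41.983, 68.169)),
    "alcohol": ((12.491, 6.909, 6.408, 9.766), (32.238, 15.277, 18.449, 22.986)),
}

_DEFAULT_CATEGORICAL: dict[str, dict[str, tuple[float, ...]]] = {
    "gender": {
        "female": (0.406, 0.378, 0.595, 0.257),
        "male": (0.594, 0.622, 0.405, 0.743),
    },
    "marital_status": {
        "married": (0.631, 0.559, 0.488, 0.486),
        "widowed": (0.074, 0.039, 0.075, 0.024),
        "divorced": (0.087, 0.087, 0.116, 0.131),
        "separated": (0.025, 0.071, 0.042, 0.016),
        "never_married": (0.127, 0.142, 0.174, 0.200),
        "living_with_partner": (0.055, 0.102, 0.105, 0.143),
    },
    "education": {
        "less_than_9th": (0.057, 0.071, 0.086, 0.049),
        "grade_9_11": (0.093, 0.134, 0.113, 0.159),
        "high_school": (0.172, 0.236, 0.257, 0.245),
        "some_college": (0.363, 0.441, 0.293, 0.343),
        "college_graduate": (0.315, 0.118, 0.250, 0.204),
    },
}

_DEFAULT_BINARY = {"smoking_100": (0.463, 0.575, 0.409, 0.490)}


def default_config(n_patients: int = 2306, seed: int = 0) -> SynthConfig:
    """Bundled four-group template approximating the default cohort marginals."""
    return SynthConfig(
        n_patients=n_patients,
        group_weights=_DEFAULT_WEIGHTS,
        disease_prevalence=dict(_DEFAULT_PREVALENCE),
        continuous=dict(_DEFAULT_CONTINUOUS),
        categorical={k: dict(v) for k, v in _DEFAULT_CATEGORICAL.items()},
        binary=dict(_DEFAULT_BINARY),
        rng_seed=seed,
    )


def planted_config(
    n_patients: int,
    n_groups: int = 4,
    separation: float = 6.0,
    seed: int = 0,
    signature_prevalence: float = 0.95,
    background_prevalence: float = 0.35,
) -> SynthConfig:
    """Strongly separated planted-group template for recovery experiments.

    Each group gets its own pair of nutrient variables shifted by
    ``separation`` SDs, and a pair of "signature" diseases at high prevalence
    (so nearly every record survives the two-disease inclusion filter with
    little selection bias).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups == 4:
        # curated profile: group 0 leads on hypertension, group 3 trails on
        # CKD, group 2 is largest -> the naming rules resolve unambiguously
        weights: tuple[float, ...] = (0.20, 0.10, 0.55, 0.15)
        prevalence = {
            "hypertension": (0.95, 0.55, 0.75, 0.55),
            "dyslipidemia": (0.75, 0.85, 0.80, 0.70),
            "diabetes": (0.55, 0.50, 0.75, 0.55),
            "ckd": (0.50, 0.45, 0.55, 0.15),
            "hyperuricemia": (0.45, 0.80, 0.70, 0.35),
        }
    else:
        weights = tuple([1.0 / n_groups] * n_groups)
        prevalence = {}
        for i, disease in enumerate(DISEASES):
            prevalence[disease] = tuple(
                signature_prevalence
                if i in ((2 * g) % 5, (2 * g + 1) % 5)
                else background_prevalence
                for g in range(n_groups)
            )
    block_vars = NUTRIENT_VARS[: 2 * n_groups]
    continuous: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
        "age": (tuple([50.0] * n_groups), tuple([10.0] * n_groups)),
        "family_pir": (tuple([2.5] * n_groups), tuple([1.0] * n_groups)),
        "bmi": (tuple([29.0] * n_groups), tuple([5.0] * n_groups)),
    }
    for j, var in enumerate(block_vars):
        base, sd = 100.0, 10.0
        means = tuple(
            base + separation * sd if j // 2 == g else base for g in range(n_groups)
        )
        continuous[var] = (means, tuple([sd] * n_groups))
    categorical = {
        "gender": {"female": tuple([0.5] * n_groups), "male": tuple([0.5] * n_groups)},
        "marital_status": {
            lvl: tuple([1.0 / len(MARITAL_LEVELS)] * n_groups) for lvl in MARITAL_LEVELS
        },
        "education": {
            lvl: tuple([1.0 / len(EDUCATION_LEVELS)] * n_groups)
            for lvl in EDUCATION_LEVELS
        },
    }
    return SynthConfig(
        n_patients=n_patients,
        group_weights=weights,
        disease_prevalence=prevalence,
        continuous=continuous,
        categorical=categorical,
        binary={"smoking_100": tuple([0.4] * n_groups)},
        rng_seed=seed,
    )


# --------------------------------------------------------------------------
# Back-filling raw measurements consistent with drawn flags.

def _backfill_raw(flags: Mapping[str, bool], sex: str, rng: np.random.Generator) -> RawMeasurements:
    # Negative defaults sit strictly inside the normal ranges.
    sbp = float(rng.uniform(100.0, 138.0))
    dbp = float(rng.uniform(62.0, 88.0))
    dx_htn = False
    if flags["hypertension"]:
        route = rng.integers(3)
        if route == 0:
            sbp = float(rng.uniform(142.0, 190.0))
        elif route == 1:
            dbp = float(rng.uniform(92.0, 120.0))
        else:
            dx_htn = True

    tc = float(rng.uniform(3.2, 5.0))
    tg = float(rng.uniform(0.5, 1.6))
    ldl = float(rng.uniform(1.5, 3.2))
    hdl = float(rng.uniform(1.10, 2.20))
    if flags["dyslipidemia"]:
        route = rng.integers(4)
        if route == 0:
            tc = float(rng.uniform(5.2, 8.0))
        elif route == 1:
            tg = float(rng.uniform(1.75, 5.0))
        elif route == 2:
            ldl = float(rng.uniform(3.4, 6.0))
        else:
            hdl = float(rng.uniform(0.5, 1.02))

    fpg = float(rng.uniform(4.2, 6.7))
    ogtt: float | None = float(rng.uniform(4.5, 9.5))
    dx_dm = False
    if flags["diabetes"]:
        route = rng.integers(3)
        if route == 0:
            fpg = float(rng.uniform(7.1, 14.0))
        elif route == 1:
            ogtt = float(rng.uniform(11.2, 20.0))
        else:
            dx_dm = True

    acr = float(rng.uniform(1.0, 25.0))
    egfr = float(rng.uniform(70.0, 115.0))
    damage = False
    if flags["ckd"]:
        route = rng.integers(3)
        if route == 0:
            acr = float(rng.uniform(31.0, 300.0))
        elif route == 1:
            egfr = float(rng.uniform(15.0, 58.0))
        else:
            damage = True

    ua_cut = URIC_ACID_CUTOFF_MALE if sex == "male" else URIC_ACID_CUTOFF_FEMALE
    if flags["hyperuricemia"]:
        ua = float(rng.uniform(ua_cut + 5.0, ua_cut + 200.0))
    else:
        ua = float(rng.uniform(120.0, ua_cut - 5.0))

    return RawMeasurements(
        sex=sex,
        systolic_bp=sbp,
        diastolic_bp=dbp,
        dx_hypertension=dx_htn,
        total_cholesterol=tc,
        triglycerides=tg,
        ldl_c=ldl,
        hdl_c=hdl,
        fasting_glucose=fpg,
        ogtt_2h_glucose=ogtt,
        dx_diabetes=dx_dm,
        acr=acr,
        egfr=egfr,
        kidney_damage_over_3mo=damage,
        serum_uric_acid=ua,
    )


def generate_cohort(cfg: SynthConfig) -> list[PatientRecord]:
    """Draw ``cfg.n_patients`` records from the group mixture; fully seeded."""
    cfg.validate()
    n, k = cfg.n_patients, cfg.n_groups
    rng = np.random.default_rng(cfg.rng_seed)
    if n == 0:
        return []
    weights = np.asarray(cfg.group_weights, dtype=float)
    weights = weights / weights.sum()
    groups = rng.choice(k, size=n, p=weights)

    cont_values: dict[str, np.ndarray] = {}
    for name, (means, sds) in cfg.continuous.items():
        mu = np.asarray(means, dtype=float)[groups]
        sd = np.asarray(sds, dtype=float)[groups]
        lo, hi = CLIP_BOUNDS.get(name, (0.0, np.inf))
        cont_values[name] = np.clip(rng.normal(mu, sd), lo, hi)

    cat_values: dict[str, list[str]] = {}
    for name, level_probs in cfg.categorical.items():
        levels = list(level_probs)
        probs = np.asarray([level_probs[lvl] for lvl in levels], dtype=float)  # L x k
        probs = probs / probs.sum(axis=0, keepdims=True)
        draws = rng.random(n)
        cum = np.cumsum(probs[:, groups], axis=0)  # L x n
        idx = (draws[None, :] < cum).argmax(axis=0)
        cat_values[name] = [levels[i] for i in idx]

    bin_values: dict[str, np.ndarray] = {}
    for name, probs in cfg.binary.items():
        p = np.asarray(probs, dtype=float)[groups]
        bin_values[name] = rng.random(n) < p

    flag_draws: dict[str, np.ndarray] = {}
    for disease in DISEASES:
        probs = cfg.disease_prevalence.get(disease, tuple([0.0] * k))
        p = np.asarray(probs, dtype=float)[groups]
        flag_draws[disease] = rng.random(n) < p

    records: list[PatientRecord] = []
    for i in range(n):
        flags = {d: bool(flag_draws[d][i]) for d in DISEASES}
        sex = cat_values.get("gender", ["female"] * n)[i]
        raw = _backfill_raw(flags, sex, rng)
        rec = PatientRecord(
            id=f"P{i:06d}",
            age=float(cont_values["age"][i]) if "age" in cont_values else 50.0,
            gender=sex,
            marital_status=cat_values.get("marital_status", ["married"] * n)[i],
            education=cat_values.get("education", ["high_school"] * n)[i],
            family_pir=float(cont_values["family_pir"][i]) if "family_pir" in cont_values else 2.0,
            bmi=float(cont_values["bmi"][i]) if "bmi" in cont_values else 28.0,
            smoking_100=bool(bin_values.get("smoking_100", np.zeros(n, bool))[i]),
            activity_minutes={
                v: float(cont_values[v][i]) for v in ACTIVITY_VARS if v in cont_values
            },
            nutrient_intakes={
                v: float(cont_values[v][i]) for v in NUTRIENT_VARS if v in cont_values
            },
            biomarkers={
                v: float(cont_values[v][i]) for v in BIOMARKER_VARS if v in cont_values
            },
            diseases=flags,
            raw=raw,
            planted_group=int(groups[i]),
        )
        assert flag_diseases(raw) == flags  # round-trip invariant by construction
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# Cohort I/O: flat CSV/TSV with a JSON sidecar for the generating config.
#
# Column dictionary: scalar demographics by name; activity minutes prefixed
# "act_", nutrients "nut_", biomarkers "bio_", disease flags "dis_" (0/1),
# raw measurements "raw_" (booleans 0/1); categorical levels as strings.

_RAW_FIELDS = [f.name for f in dataclasses.fields(RawMeasurements)]
_RAW_BOOL = {"dx_hypertension", "dx_diabetes", "kidney_damage_over_3mo", "low_egfr_over_3mo"}


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "age": r.age,
            "gender": r.gender,
            "marital_status": r.marital_status,
            "education": r.education,
            "family_pir": r.family_pir,
            "bmi": r.bmi,
            "smoking_100": int(r.smoking_100),
        }
        row.update({f"act_{k}": v for k, v in r.activity_minutes.items()})
        row.update({f"nut_{k}": v for k, v in r.nutrient_intakes.items()})
        row.update({f"bio_{k}": v for k, v in r.biomarkers.items()})
        row.update({f"dis_{k}": int(v) for k, v in r.diseases.items()})
        if r.raw is not None:
            for name in _RAW_FIELDS:
                value = getattr(r.raw, name)
                if name in _RAW_BOOL:
                    value = int(value)
                row[f"raw_{name}"] = value
        row["planted_group"] = -1 if r.planted_group is None else r.planted_group
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    act_cols = [c for c in df.columns if c.startswith("act_")]
    nut_cols = [c for c in df.columns if c.startswith("nut_")]
    bio_cols = [c for c in df.columns if c.startswith("bio_")]
    raw_cols = [c for c in df.columns if c.startswith("raw_")]
    for _, row in df.iterrows():
        raw = None
        if raw_cols:
            kwargs = {}
            for c in raw_cols:
                name = c[4:]
                value = row[c]
                if name in _RAW_BOOL:
                    value = bool(int(value))
                elif name == "sex":
                    value = str(value)
                elif pd.isna(value):
                    value = None
                else:
                    value = float(value)
                kwargs[name] = value
            raw = RawMeasurements(**kwargs)
        planted = int(row["planted_group"]) if "planted_group" in row else -1
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                marital_status=str(row["marital_status"]),
                education=str(row["education"]),
                family_pir=float(row["family_pir"]),
                bmi=float(row["bmi"]),
                smoking_100=bool(int(row["smoking_100"])),
                activity_minutes={c[4:]: float(row[c]) for c in act_cols},
                nutrient_intakes={c[4:]: float(row[c]) for c in nut_cols},
                biomarkers={c[4:]: float(row[c]) for c in bio_cols},
                diseases={c[4:]: bool(int(row[c])) for c in df.columns if c.startswith("dis_")},
                raw=raw,
                planted_group=None if planted < 0 else planted,
            )
        )
    return records


def write_cohort(
    records: Sequence[PatientRecord],
    path: str | Path,
    config: SynthConfig | None = None,
    sep: str = ",",
) -> None:
    path = Path(path)
    cohort_to_frame(records).to_csv(path, sep=sep, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))


def read_cohort(path: str | Path, sep: str = ",") -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path, sep=sep))
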