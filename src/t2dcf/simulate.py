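"""Seeded synthetic balanced T2DM cohorts.

Real primary-care extracts behind this kind of risk model are not
redistributable, so the generator emulates the statistical structure the
method assumes: a balanced two-class cohort whose class-conditional
biomarker distributions overlap substantially, with hypertension more
prevalent in the high-risk class and demographics (sex split, age
means/SDs per sex and class) matching a typical primary-care T2DM
screening population.

Numeric features are independent truncated normals clipped to the schema's
plausibility bounds; an optional Gaussian-copula hook accepts a
user-supplied correlation matrix (identity by default).  Class-conditional
biomarker means straddle the clinical prediabetes threshold for fasting
blood sugar (5.6 mmol/L): the high-risk class sits above it, the low-risk
class below.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    Cohort,
    CohortSchema,
    LABEL_HIGH,
    LABEL_LOW,
    default_t2dm_schema,
)


@dataclass
class ClassParams:
    """Per-class sampling parameters (native units)."""

    biomarker_means: dict[str, float]
    biomarker_sds: dict[str, float]
    htn_prevalence: float
    female_fraction: float
    age_mean_female: float
    age_sd_female: float
    age_mean_male: float
    age_sd_male: float


@dataclass
class GeneratorConfig:
    """Cohort size, seed and class-conditional distributions.

    ``overlap_scale`` multiplies every biomarker SD: values toward 0 give a
    near-separable cohort, values above 1 increase class overlap.
    """

    n_per_class: int = 2791
    seed: int = 42
    high: ClassParams = None
    low: ClassParams = None
    overlap_scale: float = 1.0
    schema: CohortSchema = field(default_factory=default_t2dm_schema)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("schema")
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        d["high"] = ClassParams(**d["high"])
        d["low"] = ClassParams(**d["low"])
        return cls(**d)


#: Clinical prediabetes threshold for fasting blood sugar (mmol/L) used to
#: anchor the class-conditional FBS means.
FBS_PREDIABETES = 5.6


def default_t2dm_config(n_per_class: int = 2791, seed: int = 42) -> GeneratorConfig:
    """Default study conditions for the synthetic T2DM cohort.

    Demographics: high-risk class 54.1% female, age (F) 57+/-13 and (M)
    58+/-11 years; low-risk class 61.3% female, age (F) 58+/-11 and (M)
    60+/-11.  Biomarker means are documented assumptions typical of
    at-risk vs screening-negative primary-care populations, with the FBS
    means straddling the 5.6 mmol/L prediabetes threshold; hypertension is
    more prevalent in the high-risk class (0.45 vs 0.25), which keeps the
    non-hypertensive patient groups larger than the hypertensive ones.
    """
    high = ClassParams(
        biomarker_means={"FBS": 6.3, "BMI": 31.0, "sBP": 135.0, "HDL": 1.15,
                         "LDL": 3.1, "TG": 2.0, "TotalChol": 5.3},
        biomarker_sds={"FBS": 1.2, "BMI": 6.0, "sBP": 16.0, "HDL": 0.32,
                       "LDL": 0.95, "TG": 1.0, "TotalChol": 1.05},
        htn_prevalence=0.45,
        female_fraction=1510 / 2791,
        age_mean_female=57.0, age_sd_female=13.0,
        age_mean_male=58.0, age_sd_male=11.0,
    )
    low = ClassParams(
        biomarker_means={"FBS": 5.0, "BMI": 27.0, "sBP": 125.0, "HDL": 1.45,
                         "LDL": 2.9, "TG": 1.4, "TotalChol": 5.0},
        biomarker_sds={"FBS": 0.7, "BMI": 5.0, "sBP": 14.0, "HDL": 0.38,
                       "LDL": 0.9, "TG": 0.7, "TotalChol": 1.0},
        htn_prevalence=0.25,
        female_fraction=1710 / 2791,
        age_mean_female=58.0, age_sd_female=11.0,
        age_mean_male=60.0, age_sd_male=11.0,
    )
    return GeneratorConfig(n_per_class=n_per_class, seed=seed, high=high, low=low)


@dataclass
class GeneratorReport:
    class_counts: dict[str, int]
    htn_rates: dict[str, float]
    realized_means: dict[str, dict[str, float]]
    realized_sds: dict[str, dict[str, float]]


def _truncnorm(rng, mean, sd, lo, hi, size):
    if not lo <= mean <= hi or min(mean - lo, hi - mean) < -4 * sd:
        raise ValueError(
            f"mean {mean} infeasible for plausibility bounds [{lo}, {hi}]"
        )
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[Cohort, GeneratorReport]:
    """Draw a balanced cohort; deterministic per ``config.seed``."""
    config = config or default_t2dm_config()
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    frames = []
    report_means: dict[str, dict[str, float]] = {}
    report_sds: dict[str, dict[str, float]] = {}
    htn_rates: dict[str, float] = {}

    for label, params in ((LABEL_HIGH, config.high), (LABEL_LOW, config.low)):
        n = config.n_per_class
        sex = (rng.random(n) >= params.female_fraction).astype(float)  # 0=F
        htn = (rng.random(n) < params.htn_prevalence).astype(float)
        age_spec = schema["Age"]
        age = np.where(
            sex == 0,
            _truncnorm(rng, params.age_mean_female, params.age_sd_female,
                       age_spec.lower_bound, age_spec.upper_bound, n),
            _truncnorm(rng, params.age_mean_male, params.age_sd_male,
                       age_spec.lower_bound, age_spec.upper_bound, n),
        )
        cols = {"Age": age, "Sex": sex, "HTN": htn}
        for name, mean in params.biomarker_means.items():
            spec = schema[name]
            sd = params.biomarker_sds[name] * config.overlap_scale
            sd = max(sd, 1e-9)
            cols[name] = _truncnorm(rng, mean, sd, spec.lower_bound,
                                    spec.upper_bound, n)
        df = pd.DataFrame(cols)
        df["label"] = label
        frames.append(df)
        report_means[label] = {k: float(df[k].mean()) for k in params.biomarker_means}
        report_sds[label] = {k: float(df[k].std()) for k in params.biomarker_means}
        htn_rates[label] = float(htn.mean())

    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"P{i:05d}" for i in range(len(df))])
    cohort = Cohort(df, schema)
    report = GeneratorReport(
        class_counts={LABEL_HIGH: config.n_per_class, LABEL_LOW: config.n_per_class},
        htn_rates=htn_rates,
        realized_means=report_means,
        realized_sds=report_sds,
    )
    return cohort, report
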