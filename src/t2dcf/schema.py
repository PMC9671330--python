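"""Cohort schema, container, CSV I/O, scaling, splitting, and patient grouping.

The default schema describes the ten routinely collected primary-care
features used for one-year type-2-diabetes risk assessment: age, sex,
a hypertension diagnosis flag, and seven continuous biomarkers (fasting
blood sugar, BMI, systolic blood pressure, HDL, LDL, triglycerides and
total cholesterol).  Each feature carries a *role* that governs what a
counterfactual search may change:

``controllable``
    modifiable by lifestyle or treatment (the seven biomarkers);
``fixed``
    immutable patient attributes (age, sex);
``conditionally-fixed``
    hypertension: a chronic diagnosis that cannot be removed within the
    prediction window, although a non-hypertensive patient may in
    principle acquire it.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABEL_HIGH = "highT2DM"
LABEL_LOW = "lowT2DM"
LABELS = (LABEL_HIGH, LABEL_LOW)

#: Sex coding used throughout: 0 = female, 1 = male.
SEX_FEMALE = 0
SEX_MALE = 1

ROLE_CONTROLLABLE = "controllable"
ROLE_FIXED = "fixed"
ROLE_CONDITIONALLY_FIXED = "conditionally-fixed"
_ROLES = (ROLE_CONTROLLABLE, ROLE_FIXED, ROLE_CONDITIONALLY_FIXED)

GROUP_LABELS = ("F_HTN", "F_noHTN", "M_HTN", "M_noHTN")


class SchemaError(ValueError):
    """A file or record does not conform to the cohort schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: name, unit, value kind, actionability role and bounds.

    Bounds are plausibility limits in native units; they drive generator
    truncation and load-time warnings, never silent modification of data.
    """

    name: str
    unit: str
    kind: str  # "numeric" | "binary"
    role: str
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown feature role {self.role!r}")
        if self.kind == "numeric" and not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"{self.name}: lower_bound must be < upper_bound"
            )


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def names_with_role(self, role: str) -> list[str]:
        return [f.name for f in self.features if f.role == role]

    @property
    def controllable(self) -> list[str]:
        return self.names_with_role(ROLE_CONTROLLABLE)

    @property
    def fixed(self) -> list[str]:
        return self.names_with_role(ROLE_FIXED)

    def indices_of(self, names: Sequence[str]) -> np.ndarray:
        order = {n: i for i, n in enumerate(self.names)}
        return np.asarray([order[n] for n in names], dtype=int)

    def to_config(self) -> str:
        """Serialize as a flat key/value text block (one feature per line)."""
        lines = []
        for f in self.features:
            lines.append(
                f"{f.name} = unit:{f.unit} kind:{f.kind} role:{f.role} "
                f"bounds:{f.lower_bound},{f.upper_bound}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "CohortSchema":
        specs = []
        for raw in text.splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            name, _, rest = raw.partition("=")
            fields = dict(tok.split(":", 1) for tok in rest.split())
            lo, hi = (float(v) for v in fields["bounds"].split(","))
            specs.append(
                FeatureSpec(
                    name=name.strip(),
                    unit=fields["unit"],
                    kind=fields["kind"],
                    role=fields["role"],
                    lower_bound=lo,
                    upper_bound=hi,
                )
            )
        return cls(tuple(specs))


def default_t2dm_schema() -> CohortSchema:
    """The ten-feature T2DM risk schema with default plausibility bounds."""
    return CohortSchema(
        (
            FeatureSpec("Age", "years", "numeric", ROLE_FIXED, 30, 110),
            FeatureSpec("Sex", "0=female,1=male", "binary", ROLE_FIXED, 0, 1),
            FeatureSpec("HTN", "0/1", "binary", ROLE_CONDITIONALLY_FIXED, 0, 1),
            FeatureSpec("FBS", "mmol/L", "numeric", ROLE_CONTROLLABLE, 2, 20),
            FeatureSpec("BMI", "kg/m2", "numeric", ROLE_CONTROLLABLE, 12, 70),
            FeatureSpec("sBP", "mmHg", "numeric", ROLE_CONTROLLABLE, 70, 250),
            FeatureSpec("HDL", "mmol/L", "numeric", ROLE_CONTROLLABLE, 0.3, 4),
            FeatureSpec("LDL", "mmol/L", "numeric", ROLE_CONTROLLABLE, 0.3, 8),
            FeatureSpec("TG", "mmol/L", "numeric", ROLE_CONTROLLABLE, 0.2, 15),
            FeatureSpec("TotalChol", "mmol/L", "numeric", ROLE_CONTROLLABLE, 1, 12),
        )
    )


@dataclass
class Cohort:
    """A labeled patient table bound to a :class:`CohortSchema`.

    ``df`` holds one row per patient with columns ``id``, every schema
    feature in schema order, and ``label`` (``highT2DM``/``lowT2DM``).
    """

    df: pd.DataFrame
    schema: CohortSchema

    def __post_init__(self) -> None:
        required = ["id", *self.schema.names, "label"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort missing column(s): {missing}")
        bad = set(self.df["label"]) - set(LABELS)
        if bad:
            raise SchemaError(f"unknown label value(s): {sorted(bad)}")
        self.df = self.df[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix in schema order, native units, float64."""
        return self.df[self.schema.names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Label vector of strings."""
        return self.df["label"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask)].reset_index(drop=True), self.schema)

    def records(self) -> Iterable["PatientRecord"]:
        names = self.schema.names
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield PatientRecord(
                id=d["id"],
                values=np.array([float(d[n]) for n in names]),
                label=d["label"],
            )

    def out_of_bounds_report(self) -> pd.DataFrame:
        """Rows/features outside plausibility bounds (warning aid only)."""
        hits = []
        for f in self.schema:
            v = self.df[f.name].to_numpy(dtype=float)
            bad = (v < f.lower_bound) | (v > f.upper_bound)
            for i in np.nonzero(bad)[0]:
                hits.append({"row": int(i), "feature": f.name, "value": v[i]})
        return pd.DataFrame(hits, columns=["row", "feature", "value"])


@dataclass(frozen=True)
class PatientRecord:
    """A single patient: id, feature values in schema order, risk label."""

    id: object
    values: np.ndarray
    label: str


def load_cohort(path, schema: CohortSchema | None = None) -> Cohort:
    """Read a cohort CSV (columns ``id``, features, ``label``).

    Rows containing missing or unparsable feature values are rejected and
    reported in a :class:`SchemaError` naming the offending rows; a missing
    column raises immediately naming the column.
    """
    schema = schema or default_t2dm_schema()
    df = pd.read_csv(path, dtype={"id": str})
    for col in [*schema.names, "label"]:
        if col not in df.columns:
            raise SchemaError(f"input file is missing required column {col!r}")
    if "id" not in df.columns:
        df.insert(0, "id", [str(i) for i in range(len(df))])
    coerced = df[schema.names].apply(pd.to_numeric, errors="coerce")
    bad_rows = coerced.isna().any(axis=1)
    if bad_rows.any():
        rows = [int(i) for i in np.nonzero(bad_rows.to_numpy())[0]]
        raise SchemaError(
            f"rejected {len(rows)} row(s) with missing/unparsable values "
            f"(0-based data rows: {rows})"
        )
    df[schema.names] = coerced
    return Cohort(df, schema)


def save_cohort(cohort: Cohort, path) -> None:
    cohort.df.to_csv(path, index=False)


@dataclass
class ScalingTransform:
    """Per-feature min-max scaling fitted on a reference cohort.

    Features constant on the fitting cohort map to 0 so that downstream
    distances stay finite; binary features coded {0,1} are left unchanged.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def ranges(self) -> np.ndarray:
        r = self.maxs - self.mins
        return np.where(r > 0, r, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = (X - self.mins) / self.ranges
        const = self.maxs == self.mins
        if const.any():
            out[:, const] = 0.0
        return out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z * self.ranges + self.mins


def fit_scaler(cohort: Cohort) -> ScalingTransform:
    """Fit per-feature min/max over the cohort (binary features keep 0/1)."""
    if len(cohort) == 0:
        raise ValueError("cannot fit a scaler on an empty cohort")
    X = cohort.X
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    # binary features are pinned to the {0,1} codebook even if one level is
    # absent from the fitting cohort
    for j, f in enumerate(cohort.schema):
        if f.kind == "binary":
            mins[j], maxs[j] = 0.0, 1.0
    return ScalingTransform(cohort.schema.names, mins, maxs)


def split_stratified(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Label-stratified train/test split, deterministic per seed.

    Per-label train counts are ``round(n_label * train_fraction)`` so both
    partitions match the requested fraction within one record per label.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    y = cohort.y
    train_mask = np.zeros(len(cohort), dtype=bool)
    for lab in np.unique(y):
        idx = np.nonzero(y == lab)[0]
        if len(idx) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 records")
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = rng.permutation(idx)[:n_train]
        train_mask[chosen] = True
    return cohort.subset(train_mask), cohort.subset(~train_mask)


def group_of(sex: float, htn: float) -> str:
    """Map (Sex, HTN) to one of F_HTN, F_noHTN, M_HTN, M_noHTN."""
    female = int(round(sex)) == SEX_FEMALE
    hyper = int(round(htn)) == 1
    if female:
        return "F_HTN" if hyper else "F_noHTN"
    return "M_HTN" if hyper else "M_noHTN"


def group_labels(cohort_or_df, schema: CohortSchema | None = None) -> np.ndarray:
    """Vectorized :func:`group_of` over a Cohort or feature DataFrame."""
    if isinstance(cohort_or_df, Cohort):
        df = cohort_or_df.df
    else:
        df = cohort_or_df
    return np.asarray(
        [group_of(s, h) for s, h in zip(df["Sex"], df["HTN"])], dtype=object
    )
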