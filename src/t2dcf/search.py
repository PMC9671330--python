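"""Minimum-distance counterfactual search by Halton discretization.

For each admissible high-risk patient (a *factual*), the low-risk sphere is
discretized with a quasi-random Halton sequence over the controllable
biomarker subspace; candidates copy the factual's fixed attributes (age,
sex) and handle hypertension per policy.  The returned counterfactual is
the candidate inside the low-risk sphere and outside the high-risk sphere
that minimises the Euclidean distance to the factual in min-max-scaled
space — valid by construction.

The RBF kernel factorizes over disjoint coordinate blocks,
K = K_controllable * K_fixed, so the (L x n_support) kernel block over the
controllable dimensions is computed once per sphere and reused for every
factual; only the cheap fixed-coordinate factor varies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .schema import (
    Cohort,
    CohortSchema,
    LABEL_HIGH,
    PatientRecord,
    group_of,
)
from .svdd import MEMBERSHIP_ATOL, TCSVDDModel, rbf_kernel_matrix


@dataclass(frozen=True)
class SearchConfig:
    """Search settings: candidate count, skip, HTN policy, factual source.

    ``htn_policy``:
      * ``chronic_lock`` — a hypertensive factual keeps HTN=1 (chronic
        diagnosis); a non-hypertensive factual may take either value,
        doubling its candidate pool.
      * ``free`` — both HTN values are tried for every factual.

    ``epsilon``: optional upper bound on the scaled factual-candidate
    distance (similarity threshold); ``None`` disables the filter.
    """

    L: int = 10_000
    halton_skip: int = 0
    distance: str = "euclidean"
    htn_policy: str = "chronic_lock"
    factual_source: str = "train"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.htn_policy not in ("chronic_lock", "free"):
            raise ValueError(f"unknown htn_policy {self.htn_policy!r}")
        if self.factual_source not in ("train", "test", "all"):
            raise ValueError(f"unknown factual_source {self.factual_source!r}")


@dataclass
class CounterfactualPair:
    """A factual and its (possibly unavailable) counterfactual.

    ``counterfactual`` and ``delta`` are in native units; the distance is
    Euclidean in the scaled unit cube.  Fixed-role features are identical
    between factual and counterfactual whenever a counterfactual exists.
    """

    factual_id: object
    group: str
    factual: np.ndarray
    available: bool
    counterfactual: np.ndarray | None = None
    delta: np.ndarray | None = None
    scaled_distance: float | None = None


def halton_points(dim: int, count: int, skip: int = 0) -> np.ndarray:
    """First ``count`` Halton points in [0,1)^dim after ``skip`` points.

    Bases are the first ``dim`` primes; row t is the radical inverse of
    index skip+t+1 (the degenerate all-zero point at index 0 is never
    emitted), so dim=1 starts 1/2, 1/4, 3/4, ...
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    eng = qmc.Halton(d=dim, scramble=False)
    eng.fast_forward(1 + skip)
    return eng.random(count)


@dataclass
class FactualSet:
    """Admissible high-risk records: outside the (possibly reduced) S2."""

    cohort: Cohort
    indices: np.ndarray  # row indices into cohort.df

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def ids(self) -> np.ndarray:
        return self.cohort.ids[self.indices]


def _source_cohort(cohort_train: Cohort, cohort_test: Cohort | None, source: str) -> Cohort:
    if source == "train" or cohort_test is None:
        return cohort_train
    if source == "test":
        return cohort_test
    merged = pd.concat([cohort_train.df, cohort_test.df], ignore_index=True)
    return Cohort(merged, cohort_train.schema)


def select_factuals(
    model: TCSVDDModel,
    cohort: Cohort,
    config: SearchConfig | None = None,
) -> FactualSet:
    """High-risk records whose scaled vector lies outside the low-risk sphere.

    Records already inside S2 (or the reduced S2) sit in the overlap region
    and admit no meaningful recourse, so they are excluded.  Shrinking S2
    can only grow this set (the admissibility test is monotone in the
    radius), hence the reduced model yields at least as many factuals.
    """
    config = config or SearchConfig()
    is_high = cohort.y == LABEL_HIGH
    X = model.scale(cohort.X)
    inside_low = model.sphere_low.contains(X)
    admissible = is_high & ~inside_low
    return FactualSet(cohort=cohort, indices=np.nonzero(admissible)[0])


class _CandidateEngine:
    """Shared Halton grid and per-sphere controllable-block kernels."""

    def __init__(self, model: TCSVDDModel, config: SearchConfig):
        self.model = model
        self.config = config
        schema = model.schema
        ctrl = [f.name for f in schema if f.role == "controllable"]
        self.ctrl_idx = schema.indices_of(ctrl)
        self.fixed_idx = schema.indices_of(schema.fixed)
        self.htn_idx = int(schema.indices_of(["HTN"])[0]) if "HTN" in schema.names else None
        self.U = halton_points(len(ctrl), config.L, config.halton_skip)

        sigma = model.hyperparams.sigma
        # K = K_u * K_z over disjoint blocks: candidate-vs-support kernels
        # over controllable dims computed once, reused across factuals
        self._Ku = {}
        for name, sphere in (("high", model.sphere_high), ("low", model.sphere_low)):
            self._Ku[name] = rbf_kernel_matrix(
                self.U, sphere.ref_points[:, self.ctrl_idx], sigma
            )
        self.other_idx = np.asarray(
            [i for i in range(len(schema)) if i not in set(self.ctrl_idx)], dtype=int
        )

    def distance2_to_sphere(self, name: str, z_other: np.ndarray) -> np.ndarray:
        """d^2 from every Halton candidate (with fixed block z) to a sphere."""
        sphere = self.model.sphere_high if name == "high" else self.model.sphere_low
        sigma = self.model.hyperparams.sigma
        refs_other = sphere.ref_points[:, self.other_idx]
        kz = np.exp(-np.sum((refs_other - z_other) ** 2, axis=1) / sigma**2)
        w = sphere.beta * kz
        d2 = 1.0 - 2.0 * (self._Ku[name] @ w) + sphere.center_self_term
        return np.maximum(d2, 0.0)

    def htn_variants(self, factual_htn: float) -> list[float]:
        if self.config.htn_policy == "chronic_lock" and int(round(factual_htn)) == 1:
            return [1.0]
        return [float(int(round(factual_htn))), float(1 - int(round(factual_htn)))]


def generate_candidates(
    model: TCSVDDModel,
    factual: PatientRecord,
    config: SearchConfig | None = None,
    engine: _CandidateEngine | None = None,
) -> np.ndarray:
    """Scaled candidate vectors retained for one factual (may be empty).

    Candidates are Halton points over the controllable subspace with the
    factual's fixed features copied in and HTN expanded per policy, kept if
    inside the low-risk sphere and strictly outside the high-risk sphere.
    Rows are ordered by (Halton index, HTN variant with the factual's own
    value first).
    """
    config = config or SearchConfig()
    engine = engine or _CandidateEngine(model, config)
    retained, _, _ = _retained_for(engine, factual)
    return retained


def _retained_for(
    engine: _CandidateEngine, factual: PatientRecord
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Retained scaled candidates + their Halton indices + HTN flip flags."""
    model, config = engine.model, engine.config
    x_scaled = model.scale(factual.values)[0]
    z_template = x_scaled[engine.other_idx]

    blocks, idx_blocks, flip_blocks = [], [], []
    htn_pos_in_other = (
        int(np.nonzero(engine.other_idx == engine.htn_idx)[0][0])
        if engine.htn_idx is not None
        else None
    )
    factual_htn = x_scaled[engine.htn_idx] if engine.htn_idx is not None else 0.0
    variants = (
        engine.htn_variants(factual_htn) if engine.htn_idx is not None else [None]
    )
    for variant in variants:
        z = z_template.copy()
        if variant is not None:
            z[htn_pos_in_other] = variant
        d2_low = engine.distance2_to_sphere("low", z)
        d2_high = engine.distance2_to_sphere("high", z)
        # same membership rule as classify(), so retained candidates are
        # classified LOW by construction
        keep = (d2_low <= model.sphere_low.squared_radius + MEMBERSHIP_ATOL) & (
            d2_high > model.sphere_high.squared_radius + MEMBERSHIP_ATOL
        )
        if not keep.any():
            continue
        full = np.empty((int(keep.sum()), len(model.schema.names)))
        full[:, engine.other_idx] = z
        full[:, engine.ctrl_idx] = engine.U[keep]
        blocks.append(full)
        idx_blocks.append(np.nonzero(keep)[0])
        flip_blocks.append(
            np.full(int(keep.sum()), variant is not None and variant != factual_htn)
        )
    if not blocks:
        d = len(model.schema.names)
        return np.empty((0, d)), np.empty(0, dtype=int), np.empty(0, dtype=bool)
    order_key = np.concatenate(
        [idx + 0.5 * flips for idx, flips in zip(idx_blocks, flip_blocks)]
    )
    order = np.argsort(order_key, kind="stable")
    return (
        np.concatenate(blocks)[order],
        np.concatenate(idx_blocks)[order],
        np.concatenate(flip_blocks)[order],
    )


def find_counterfactual(
    model: TCSVDDModel,
    factual: PatientRecord,
    config: SearchConfig | None = None,
    engine: _CandidateEngine | None = None,
) -> CounterfactualPair:
    """Nearest retained candidate in scaled space; unavailable if none.

    Ties are broken by lowest Halton index (then the factual's own HTN
    value); the counterfactual is reported in native units via inverse
    scaling, with fixed features copied bit-identically from the factual.
    """
    config = config or SearchConfig()
    engine = engine or _CandidateEngine(model, config)
    grp = _group_of_record(model.schema, factual)
    cands, _, _ = _retained_for(engine, factual)
    if len(cands) == 0:
        return CounterfactualPair(
            factual_id=factual.id, group=grp, factual=factual.values,
            available=False,
        )
    x_scaled = model.scale(factual.values)[0]
    d = np.sqrt(np.sum((cands - x_scaled) ** 2, axis=1))
    if config.epsilon is not None:
        ok = d <= config.epsilon
        if not ok.any():
            return CounterfactualPair(
                factual_id=factual.id, group=grp, factual=factual.values,
                available=False,
            )
        # keep ordering: mask then argmin
        cands, d = cands[ok], d[ok]
    best = int(np.argmin(d))  # first minimum = lowest Halton index
    cf_scaled = cands[best]
    cf_native = model.scaler.inverse_transform(cf_scaled)[0]
    # fixed features are copied exactly (no scaling round-trip error)
    for j in engine.fixed_idx:
        cf_native[j] = factual.values[j]
    if engine.htn_idx is not None:
        cf_native[engine.htn_idx] = float(round(cf_scaled[engine.htn_idx]))
    return CounterfactualPair(
        factual_id=factual.id,
        group=grp,
        factual=factual.values,
        available=True,
        counterfactual=cf_native,
        delta=cf_native - factual.values,
        scaled_distance=float(d[best]),
    )


def _group_of_record(schema: CohortSchema, record: PatientRecord) -> str:
    names = schema.names
    sex = record.values[names.index("Sex")] if "Sex" in names else 0.0
    htn = record.values[names.index("HTN")] if "HTN" in names else 0.0
    return group_of(sex, htn)


def generate_all(
    model: TCSVDDModel,
    factuals: FactualSet,
    config: SearchConfig | None = None,
) -> list[CounterfactualPair]:
    """One :class:`CounterfactualPair` per factual, input order preserved."""
    config = config or SearchConfig()
    engine = _CandidateEngine(model, config)
    pairs = []
    df = factuals.cohort.df
    names = model.schema.names
    for i in factuals.indices:
        row = df.iloc[int(i)]
        rec = PatientRecord(
            id=row["id"],
            values=row[names].to_numpy(dtype=float),
            label=row["label"],
        )
        pairs.append(find_counterfactual(model, rec, config, engine))
    return pairs


def pairs_to_frame(pairs: list[CounterfactualPair], schema: CohortSchema) -> pd.DataFrame:
    """Flatten pairs into a table (factual/counterfactual/delta per feature)."""
    rows = []
    for p in pairs:
        row: dict = {
            "factual_id": p.factual_id,
            "group": p.group,
            "available": p.available,
            "scaled_distance": p.scaled_distance,
        }
        for j, name in enumerate(schema.names):
            row[f"factual_{name}"] = p.factual[j]
            row[f"cf_{name}"] = None if p.counterfactual is None else p.counterfactual[j]
            row[f"delta_{name}"] = None if p.delta is None else p.delta[j]
        rows.append(row)
    return pd.DataFrame(rows)


def save_pairs(pairs: list[CounterfactualPair], schema: CohortSchema, path) -> None:
    pairs_to_frame(pairs, schema).to_csv(path, index=False)


def load_pairs(path, schema: CohortSchema) -> list[CounterfactualPair]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        available = bool(row["available"])
        factual = np.array([row[f"factual_{n}"] for n in schema.names], dtype=float)
        cf = delta = None
        dist = None
        if available:
            cf = np.array([row[f"cf_{n}"] for n in schema.names], dtype=float)
            delta = np.array([row[f"delta_{n}"] for n in schema.names], dtype=float)
            dist = float(row["scaled_distance"])
        out.append(
            CounterfactualPair(
                factual_id=row["factual_id"], group=row["group"],
                factual=factual, available=available, counterfactual=cf,
                delta=delta, scaled_distance=dist,
            )
        )
    return out
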