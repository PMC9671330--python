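"""Counterfactual quality metrics.

Five properties summarise a batch of factual-counterfactual pairs:
availability (fraction of factuals with a returned counterfactual),
validity (fraction classified into the low-risk region), actionability
(fraction of immutable features left unchanged), similarity (scaled
distance as a fraction of the maximal distance sqrt(n_features) in the
unit cube) and discriminative power (cross-validated accuracy of a k-NN
classifier separating counterfactuals from real high-risk patients).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .schema import Cohort, CohortSchema, LABEL_HIGH
from .search import CounterfactualPair
from .svdd import LOW, TCSVDDModel, classify_scaled


@dataclass(frozen=True)
class EvaluationReport:
    availability: float
    validity: float
    actionability: float
    similarity_mean: float
    similarity_interval: tuple[float, float]
    discriminative_power: float
    htn_flips: int = 0
    group_counts: dict = dataclasses.field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["similarity_interval"] = list(self.similarity_interval)
        return d


def availability(pairs: list[CounterfactualPair]) -> float:
    """Fraction of factuals for which the search returned a counterfactual."""
    if not pairs:
        raise ValueError("no pairs supplied")
    return sum(p.available for p in pairs) / len(pairs)


def validity(model: TCSVDDModel, pairs: list[CounterfactualPair]) -> float:
    """Fraction of available counterfactuals the model classifies low-risk."""
    avail = [p for p in pairs if p.available]
    if not avail:
        raise ValueError("no available pairs")
    X = np.vstack([p.counterfactual for p in avail])
    outcomes = classify_scaled(model, model.scale(X))
    return float(np.mean(outcomes == LOW))


def actionability(
    pairs: list[CounterfactualPair], schema: CohortSchema
) -> tuple[float, int]:
    """Mean per-pair fraction of fixed features unchanged, plus HTN flips.

    Hypertension is conditionally fixed: a 0->1 change permitted under the
    chronic-lock policy is tallied separately, never as a violation.
    """
    avail = [p for p in pairs if p.available]
    if not avail:
        raise ValueError("no available pairs")
    fixed_idx = schema.indices_of(schema.fixed)
    htn_idx = schema.names.index("HTN") if "HTN" in schema.names else None
    fracs = []
    flips = 0
    for p in avail:
        unchanged = p.factual[fixed_idx] == p.counterfactual[fixed_idx]
        fracs.append(float(np.mean(unchanged)))
        if htn_idx is not None and p.factual[htn_idx] != p.counterfactual[htn_idx]:
            flips += 1
    return float(np.mean(fracs)), flips


def similarity(
    pairs: list[CounterfactualPair], n_features: int
) -> tuple[float, tuple[float, float]]:
    """Scaled distances as fractions of sqrt(n_features): mean and the
    2.5th-97.5th percentile interval of the per-pair distribution."""
    d = np.array([p.scaled_distance for p in pairs if p.available], dtype=float)
    if d.size == 0:
        raise ValueError("no available pairs")
    s = d / np.sqrt(n_features)
    lo, hi = np.percentile(s, [2.5, 97.5])
    return float(s.mean()), (float(lo), float(hi))


def discriminative_power(
    counterfactuals: np.ndarray,
    real_high: np.ndarray,
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified cross-validated k-NN accuracy, counterfactuals vs
    real high-risk points (both in scaled space)."""
    counterfactuals = np.atleast_2d(counterfactuals)
    real_high = np.atleast_2d(real_high)
    if len(counterfactuals) == 0 or len(real_high) == 0:
        raise ValueError("both point sets must be non-empty")
    X = np.vstack([counterfactuals, real_high])
    y = np.concatenate([np.zeros(len(counterfactuals)), np.ones(len(real_high))])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a fold contains a single class")
        clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
    return float(np.mean(accs))


def evaluate_pairs(
    model: TCSVDDModel,
    pairs: list[CounterfactualPair],
    cohort: Cohort,
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Full metric suite for a batch of pairs against a reference cohort."""
    avail = [p for p in pairs if p.available]
    schema = model.schema
    act, flips = actionability(pairs, schema)
    sim_mean, sim_iv = similarity(pairs, n_features=len(schema))
    cf_scaled = model.scale(np.vstack([p.counterfactual for p in avail]))
    high_scaled = model.scale(cohort.X[cohort.y == LABEL_HIGH])
    groups: dict[str, int] = {}
    for p in avail:
        groups[p.group] = groups.get(p.group, 0) + 1
    return EvaluationReport(
        availability=availability(pairs),
        validity=validity(model, pairs),
        actionability=act,
        similarity_mean=sim_mean,
        similarity_interval=sim_iv,
        discriminative_power=discriminative_power(
            cf_scaled, high_scaled, k=k, folds=folds, seed=seed
        ),
        htn_flips=flips,
        group_counts=groups,
    )
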