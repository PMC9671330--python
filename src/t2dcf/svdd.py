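"""Two-class support vector data description (TC-SVDD).

The classifier encloses each risk class in a minimum-volume hypersphere in
RBF feature space: sphere S1 for the high-risk class and sphere S2 for the
low-risk class, jointly minimising R1^2 + R2^2 subject to each class lying
inside its own sphere and outside the other's, with slack.  The objective
and constraints separate by sphere, so training solves two independent
"SVDD with negative examples" dual problems:

    min_alpha  sum_{ij} beta_i beta_j K(x_i, x_j)
    s.t.       sum_i beta_i = 1,   0 <= alpha_i <= C_i,

with signed weights beta_i = y_i alpha_i (y=+1 for the sphere's own class,
-1 for the excluded class); the linear dual term sum_i beta_i K_ii is
constant for an RBF kernel and is dropped.  Own-class slack is penalised
at C=1 per sphere (near-hard inclusion), cross-class intrusions at the
soft rate 1/(nu N_class): each sphere wraps its own class tightly while
tolerating a controlled fraction of the other class inside.  This is what
produces the characteristic region structure of the method -- a low-risk
sphere that covers most low-risk patients *and* a substantial share of
high-risk ones (a large training FNR), which the FNR-constrained radius
reduction then carves down.

A point belongs to a sphere when its feature-space distance to the centre
is at most the radius.  Points inside exactly one sphere are classified;
points inside both or neither fall in the overlap/outside region and the
classifier abstains (UNCLASSIFIED).

The dual is solved by sequential minimal optimisation with maximal-
violating-pair working-set selection, the standard decomposition approach
for kernel machines of this size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .schema import (
    Cohort,
    CohortSchema,
    LABEL_HIGH,
    LABEL_LOW,
    ScalingTransform,
    fit_scaler,
)

HIGH = "HIGH"
LOW = "LOW"
UNCLASSIFIED = "UNCLASSIFIED"


#: membership slack on squared distances, ~10x the default solver tolerance
MEMBERSHIP_ATOL = 1e-5


class SolverError(RuntimeError):
    """The dual optimisation failed to reach the requested tolerance."""


class FNRReductionError(RuntimeError):
    """Radius reduction hit the coverage floor before reaching the FNR target."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class SVDDHyperparams:
    """Kernel width, volume/error trade-off and per-sphere penalties.

    ``sigma`` applies to min-max-scaled features.  ``C1``/``C2`` penalise
    own-class slack of S1/S2 (default 1: near-hard inclusion of each
    sphere's own class).  ``C3``/``C4`` penalise excluded-class intrusions
    into S1/S2 and default to 1/(nu * N_own_class), computed at fit time;
    ``nu`` thus controls how much of the opposite class each sphere may
    swallow before exclusion slack becomes costly.
    """

    sigma: float = 5.0
    nu: float = 0.05
    C1: float = 1.0
    C2: float = 1.0
    C3: float | None = None
    C4: float | None = None
    tol: float = 1e-6
    max_iter: int = 2_000_000

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        for c in (self.C1, self.C2):
            if c < 0:
                raise ValueError("penalty weights must be non-negative")


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """K(x, y) = exp(-||x - y||^2 / sigma^2) for two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((x - y) ** 2) / sigma**2))


def rbf_kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise RBF kernel block exp(-||x - y||^2 / sigma^2)."""
    D2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), "sqeuclidean")
    return np.exp(-D2 / sigma**2)


def _solve_dual_smo(
    K: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, dict]:
    """SMO with maximal-violating-pair selection for the signed SVDD dual.

    Returns the box variables ``alpha`` (beta = y * alpha) and solver
    diagnostics.  Raises :class:`SolverError` on non-convergence.
    """
    n = len(y)
    alpha = np.zeros(n)
    # feasible start: spread the unit signed mass over own-class points
    targets = np.nonzero(y > 0)[0]
    cap = C[targets]
    if cap.sum() < 1.0 - 1e-12:
        raise SolverError("own-class box capacity below 1; dual infeasible")
    uniform = 1.0 / len(targets)
    if np.all(cap >= uniform):
        alpha[targets] = uniform
    else:  # greedy fill respecting tight boxes
        remaining = 1.0
        for i in targets:
            take = min(C[i], remaining)
            alpha[i] = take
            remaining -= take
            if remaining <= 0:
                break
    beta = y * alpha
    f = K @ beta

    it = 0
    gap = np.inf
    while it < max_iter:
        pos = y > 0
        at_zero = alpha <= 1e-14
        at_box = alpha >= C - 1e-14
        interior = ~(at_zero | at_box)
        # rho >= 2 f_i required by: own-class at box, excluded at zero, interior
        lo_mask = interior | (pos & at_box) | (~pos & at_zero)
        # rho <= 2 f_i required by: own-class at zero, excluded at box, interior
        hi_mask = interior | (pos & at_zero) | (~pos & at_box)
        if not lo_mask.any() or not hi_mask.any():
            break
        f_lo = np.where(lo_mask, f, -np.inf)
        f_hi = np.where(hi_mask, f, np.inf)
        i = int(np.argmax(f_lo))
        j = int(np.argmin(f_hi))
        gap = f[i] - f[j]
        if gap <= tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t_star = -gap / eta if eta > 1e-14 else -np.inf
        # lower bounds keeping both variables in their boxes (t <= 0)
        t_min_i = -alpha[i] if y[i] > 0 else alpha[i] - C[i]
        t_min_j = alpha[j] - C[j] if y[j] > 0 else -alpha[j]
        t = max(t_star, t_min_i, t_min_j)
        if t >= 0:
            break
        alpha[i] = np.clip(alpha[i] + y[i] * t, 0.0, C[i])
        alpha[j] = np.clip(alpha[j] - y[j] * t, 0.0, C[j])
        f += t * (K[:, i] - K[:, j])
        it += 1

    if gap > 10 * tol and it >= max_iter:
        raise SolverError(
            f"SMO did not converge: KKT gap {gap:.3e} after {it} iterations"
        )
    return alpha, {"iterations": it, "kkt_gap": float(max(gap, 0.0))}


@dataclass
class SVDDSphere:
    """One trained hypersphere: kernel expansion of the centre and radius.

    ``ref_points`` are the (scaled) training vectors with non-zero dual
    weight; ``beta`` the signed dual coefficients; ``center_self_term``
    caches sum_ij beta_i beta_j K(x_i, x_j).
    """

    ref_points: np.ndarray
    beta: np.ndarray
    squared_radius: float
    center_self_term: float
    sigma: float
    box_limits: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)

    def distance2(self, X: np.ndarray) -> np.ndarray:
        """Squared feature-space distance(s) from the centre, >= 0."""
        Kx = rbf_kernel_matrix(np.atleast_2d(X), self.ref_points, self.sigma)
        d2 = 1.0 - 2.0 * (Kx @ self.beta) + self.center_self_term
        return np.maximum(d2, 0.0)

    def contains(self, X: np.ndarray) -> np.ndarray:
        # slack of 10x the solver tolerance keeps boundary support vectors
        # (whose d^2 scatters around R^2 by the KKT gap) inside the region
        return self.distance2(X) <= self.squared_radius + MEMBERSHIP_ATOL


def kernel_distance2(sphere: SVDDSphere, x: np.ndarray) -> float | np.ndarray:
    """Squared feature-space distance from ``sphere``'s centre to ``x``."""
    d2 = sphere.distance2(x)
    return float(d2[0]) if np.ndim(x) == 1 else d2


_BOX_EPS_REL = 1e-6


def _build_sphere(
    X: np.ndarray,
    K: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    sigma: float,
    tol: float,
    max_iter: int,
) -> SVDDSphere:
    alpha, diag = _solve_dual_smo(K, y, C, tol, max_iter)
    beta = y * alpha
    self_term = float(beta @ K @ beta)
    d2_all = np.maximum(1.0 - 2.0 * (K @ beta) + self_term, 0.0)

    eps = _BOX_EPS_REL * C
    boundary = (alpha > np.maximum(eps, 1e-12)) & (alpha < C - eps)
    if boundary.any():
        r2 = float(np.median(d2_all[boundary]))
    else:  # degenerate: no interior-box support vector
        r2 = float(d2_all[y > 0].max())

    keep = alpha > 1e-12
    return SVDDSphere(
        ref_points=X[keep].copy(),
        beta=beta[keep].copy(),
        squared_radius=r2,
        center_self_term=self_term,
        sigma=sigma,
        box_limits=C[keep].copy(),
        diagnostics={**diag, "n_support": int(keep.sum()),
                     "n_boundary": int(boundary.sum()),
                     "alpha": alpha, "d2_train": d2_all,
                     "boundary_mask": boundary},
    )


@dataclass
class TCSVDDModel:
    """Two trained spheres plus the scaler/schema that define their space."""

    sphere_high: SVDDSphere
    sphere_low: SVDDSphere
    scaler: ScalingTransform
    schema: CohortSchema
    hyperparams: SVDDHyperparams
    reduced: bool = False
    tau: float | None = None
    coverage_floor: float | None = None
    reduction_trace: list = field(default_factory=list)

    def scale(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X)


def train_tc_svdd(train: Cohort, hyperparams: SVDDHyperparams | None = None) -> TCSVDDModel:
    """Fit the two-sphere model on a labeled cohort.

    Features are min-max scaled (scaler fitted on this cohort) before
    kernel evaluation.  Sphere S1 takes the high-risk class as its own
    points (slack penalty C1) and the low-risk class as excluded negatives
    (penalty C3, default 1/(nu N_high)); S2 is symmetric with C2/C4.
    """
    hp = hyperparams or SVDDHyperparams()
    labels = train.y
    n_high = int((labels == LABEL_HIGH).sum())
    n_low = int((labels == LABEL_LOW).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("training cohort must contain both risk classes")

    scaler = fit_scaler(train)
    X = scaler.transform(train.X)
    K = rbf_kernel_matrix(X, X, hp.sigma)

    C3 = hp.C3 if hp.C3 is not None else 1.0 / (hp.nu * n_high)
    C4 = hp.C4 if hp.C4 is not None else 1.0 / (hp.nu * n_low)
    is_high = labels == LABEL_HIGH

    y1 = np.where(is_high, 1.0, -1.0)
    C_1 = np.where(is_high, hp.C1, C3)
    sphere_high = _build_sphere(X, K, y1, C_1, hp.sigma, hp.tol, hp.max_iter)

    y2 = np.where(is_high, -1.0, 1.0)
    C_2 = np.where(is_high, C4, hp.C2)
    sphere_low = _build_sphere(X, K, y2, C_2, hp.sigma, hp.tol, hp.max_iter)

    return TCSVDDModel(
        sphere_high=sphere_high,
        sphere_low=sphere_low,
        scaler=scaler,
        schema=train.schema,
        hyperparams=dataclasses.replace(hp, C3=C3, C4=C4),
    )


def classify_scaled(model: TCSVDDModel, X_scaled: np.ndarray) -> np.ndarray:
    """Classify scaled vectors: HIGH / LOW / UNCLASSIFIED (abstention).

    A point inside exactly one sphere takes that sphere's class; a point
    inside both (class overlap) or neither (outside both descriptions) is
    left unclassified.
    """
    X_scaled = np.atleast_2d(X_scaled)
    in_high = model.sphere_high.contains(X_scaled)
    in_low = model.sphere_low.contains(X_scaled)
    out = np.full(len(X_scaled), UNCLASSIFIED, dtype=object)
    out[in_high & ~in_low] = HIGH
    out[in_low & ~in_high] = LOW
    return out


def classify(model: TCSVDDModel, x_scaled: np.ndarray) -> str:
    """Single-vector convenience wrapper around :func:`classify_scaled`."""
    return str(classify_scaled(model, np.atleast_2d(x_scaled))[0])


@dataclass(frozen=True)
class PerformanceReport:
    """Proportion-valued classification metrics with abstention accounting.

    Abstained points count in the accuracy denominator (they are neither
    correct nor errors) so sensitivity + FNR + fraction_unclassified_pos = 1
    and specificity + FPR + fraction_unclassified_neg = 1 hold exactly.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fnr: float
    fpr: float
    fraction_unclassified_positives: float
    fraction_unclassified_negatives: float
    counts: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("counts")
        return d


def evaluate(model: TCSVDDModel, cohort: Cohort) -> PerformanceReport:
    """Classification performance with the high-risk class as positive."""
    if len(cohort) == 0:
        raise ValueError("cannot evaluate on an empty cohort")
    outcomes = classify_scaled(model, model.scale(cohort.X))
    y = cohort.y
    pos = y == LABEL_HIGH
    neg = y == LABEL_LOW
    P, N = int(pos.sum()), int(neg.sum())
    tp = int((pos & (outcomes == HIGH)).sum())
    fn = int((pos & (outcomes == LOW)).sum())
    tn = int((neg & (outcomes == LOW)).sum())
    fp = int((neg & (outcomes == HIGH)).sum())

    def ratio(a: int, b: int) -> float:
        return a / b if b else 0.0

    return PerformanceReport(
        accuracy=ratio(tp + tn, P + N),
        sensitivity=ratio(tp, P),
        specificity=ratio(tn, N),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        fnr=ratio(fn, P),
        fpr=ratio(fp, N),
        fraction_unclassified_positives=ratio(P - tp - fn, P),
        fraction_unclassified_negatives=ratio(N - tn - fp, N),
        counts={"TP": tp, "FN": fn, "TN": tn, "FP": fp, "P": P, "N": N},
    )


def reduce_fnr(
    model: TCSVDDModel,
    train: Cohort,
    tau: float = 0.08,
    shrink_step: float = 0.01,
    coverage_floor: float = 0.35,
) -> TCSVDDModel:
    """Shrink the low-risk sphere until the training FNR drops to ``tau``.

    The centre and dual weights are frozen; only the squared radius is
    multiplied by (1 - shrink_step) per iteration, which makes the FNR
    trace provably non-increasing and nests the reduced region inside the
    original.  FNR here is the fraction of high-risk training points whose
    feature-space distance places them inside the low-risk sphere.  The
    procedure fails (with its trace attached) if the fraction of low-risk
    training points still covered falls below ``coverage_floor`` first.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    if not 0 < shrink_step < 1:
        raise ValueError("shrink_step must lie in (0, 1)")

    X = model.scale(train.X)
    pos = train.y == LABEL_HIGH
    d2 = model.sphere_low.distance2(X)
    r2 = model.sphere_low.squared_radius

    trace: list[dict] = []
    while True:
        inside = d2 <= r2 + MEMBERSHIP_ATOL
        fnr = float(inside[pos].mean())
        coverage = float(inside[~pos].mean())
        trace.append({"squared_radius": r2, "fnr": fnr, "coverage": coverage})
        if fnr <= tau:
            break
        if coverage < coverage_floor:
            raise FNRReductionError(
                f"low-risk coverage {coverage:.3f} fell below the floor "
                f"{coverage_floor} at FNR {fnr:.3f} > tau {tau}",
                trace,
            )
        r2 *= 1.0 - shrink_step

    reduced_sphere = dataclasses.replace(model.sphere_low, squared_radius=r2)
    return dataclasses.replace(
        model,
        sphere_low=reduced_sphere,
        reduced=True,
        tau=tau,
        coverage_floor=coverage_floor,
        reduction_trace=trace,
    )


# ---------------------------------------------------------------------------
# serialization


def _sphere_to_dict(s: SVDDSphere) -> dict:
    return {
        "ref_points": s.ref_points.tolist(),
        "beta": s.beta.tolist(),
        "squared_radius": s.squared_radius,
        "center_self_term": s.center_self_term,
        "sigma": s.sigma,
        "box_limits": None if s.box_limits is None else s.box_limits.tolist(),
    }


def _sphere_from_dict(d: dict) -> SVDDSphere:
    return SVDDSphere(
        ref_points=np.asarray(d["ref_points"], dtype=float),
        beta=np.asarray(d["beta"], dtype=float),
        squared_radius=float(d["squared_radius"]),
        center_self_term=float(d["center_self_term"]),
        sigma=float(d["sigma"]),
        box_limits=None if d["box_limits"] is None
        else np.asarray(d["box_limits"], dtype=float),
    )


def save_model(model: TCSVDDModel, path) -> None:
    """Write the model (spheres, scaler, schema, hyperparameters) as JSON."""
    hp = dataclasses.asdict(model.hyperparams)
    payload = {
        "sphere_high": _sphere_to_dict(model.sphere_high),
        "sphere_low": _sphere_to_dict(model.sphere_low),
        "scaler": {
            "feature_names": model.scaler.feature_names,
            "mins": model.scaler.mins.tolist(),
            "maxs": model.scaler.maxs.tolist(),
        },
        "schema": model.schema.to_config(),
        "hyperparams": hp,
        "reduced": model.reduced,
        "tau": model.tau,
        "coverage_floor": model.coverage_floor,
        "reduction_trace": model.reduction_trace,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TCSVDDModel:
    with open(path) as fh:
        d = json.load(fh)
    scaler = ScalingTransform(
        feature_names=list(d["scaler"]["feature_names"]),
        mins=np.asarray(d["scaler"]["mins"], dtype=float),
        maxs=np.asarray(d["scaler"]["maxs"], dtype=float),
    )
    return TCSVDDModel(
        sphere_high=_sphere_from_dict(d["sphere_high"]),
        sphere_low=_sphere_from_dict(d["sphere_low"]),
        scaler=scaler,
        schema=CohortSchema.from_config(d["schema"]),
        hyperparams=SVDDHyperparams(**d["hyperparams"]),
        reduced=bool(d["reduced"]),
        tau=d["tau"],
        coverage_floor=d["coverage_floor"],
        reduction_trace=list(d["reduction_trace"]),
    )
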