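"""Independent brute-force counterfactual search used as a test oracle.

Re-derives everything from first principles with an explicit per-candidate
loop: Halton candidates over the controllable subspace, fixed features
copied from the factual, HTN variants per policy, kernel distances to each
sphere recomputed from scratch per candidate, minimum Euclidean distance
with first-seen tie-breaking.  Shares no code path with the optimized
search beyond the Halton generator and the trained model's coefficients.
"""

from __future__ import annotations

import numpy as np

from t2dcf.schema import PatientRecord
from t2dcf.search import SearchConfig, halton_points
from t2dcf.svdd import MEMBERSHIP_ATOL, TCSVDDModel


def _d2_sphere(sphere, c: np.ndarray, sigma: float) -> float:
    # full-vector kernel row against the sphere's expansion, recomputed
    # per candidate (no block factorization or cross-factual reuse)
    k = np.exp(-np.sum((sphere.ref_points - c) ** 2, axis=1) / sigma**2)
    s = float(sphere.beta @ k)
    return max(1.0 - 2.0 * s + sphere.center_self_term, 0.0)


def naive_find_counterfactual(
    model: TCSVDDModel, factual: PatientRecord, config: SearchConfig
):
    """Returns (scaled counterfactual vector | None, scaled distance | None)."""
    schema = model.schema
    names = schema.names
    ctrl_idx = schema.indices_of(schema.controllable)
    htn_idx = names.index("HTN") if "HTN" in names else None
    sigma = model.hyperparams.sigma

    x = model.scale(factual.values)[0]
    U = halton_points(len(ctrl_idx), config.L, config.halton_skip)

    if htn_idx is None:
        variants = [None]
    elif config.htn_policy == "chronic_lock" and round(x[htn_idx]) == 1:
        variants = [1.0]
    else:
        own = float(round(x[htn_idx]))
        variants = [own, 1.0 - own]

    best, best_d = None, np.inf
    for t in range(config.L):
        for variant in variants:
            c = x.copy()
            c[ctrl_idx] = U[t]
            if variant is not None:
                c[htn_idx] = variant
            d2_low = _d2_sphere(model.sphere_low, c, sigma)
            d2_high = _d2_sphere(model.sphere_high, c, sigma)
            if d2_low > model.sphere_low.squared_radius + MEMBERSHIP_ATOL:
                continue
            if d2_high <= model.sphere_high.squared_radius + MEMBERSHIP_ATOL:
                continue
            d = float(np.sqrt(np.sum((c - x) ** 2)))
            if config.epsilon is not None and d > config.epsilon:
                continue
            if d < best_d:
                best, best_d = c, d
    if best is None:
        return None, None
    return best, best_d
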