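import dataclasses
import itertools

import numpy as np
import pytest

from conftest import cohort_2d
from t2dcf.schema import fit_scaler
from t2dcf.simulate import default_t2dm_config, generate_cohort
from t2dcf.schema import split_stratified
from t2dcf.svdd import (
    HIGH,
    LOW,
    MEMBERSHIP_ATOL,
    UNCLASSIFIED,
    FNRReductionError,
    PerformanceReport,
    SVDDHyperparams,
    SVDDSphere,
    TCSVDDModel,
    classify_scaled,
    evaluate,
    kernel_distance2,
    rbf_kernel,
    rbf_kernel_matrix,
    reduce_fnr,
    train_tc_svdd,
)


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([0.3, 0.7, 0.1])
        assert rbf_kernel(x, x, sigma=5.0) == 1.0

    def test_hand_evaluated_value(self):
        # ||x-y||^2 = 25 with sigma = 5 -> exp(-1)
        x = np.zeros(1)
        y = np.array([5.0])
        assert rbf_kernel(x, y, 5.0) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 6))
            assert rbf_kernel(x, y, 2.0) == pytest.approx(rbf_kernel(y, x, 2.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestTraining:
    def test_separated_blobs_fully_classified(self, separated_blobs):
        cohort, model = separated_blobs
        outcomes = classify_scaled(model, model.scale(cohort.X))
        assert (outcomes[cohort.y == "highT2DM"] == HIGH).all()
        assert (outcomes[cohort.y == "lowT2DM"] == LOW).all()

    def test_identical_clouds_abstain(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (40, 2))
        cohort = cohort_2d(X, X + rng.normal(0, 1e-9, X.shape))
        model = train_tc_svdd(cohort, SVDDHyperparams(sigma=0.8))
        p = evaluate(model, cohort)
        assert p.sensitivity < 0.7 and p.specificity < 0.7
        assert (p.fraction_unclassified_positives
                + p.fraction_unclassified_negatives) > 0

    def test_nested_annulus_kernel_separable(self):
        rng = np.random.default_rng(11)
        n = 60
        theta = rng.uniform(0, 2 * np.pi, n)
        radius = rng.uniform(2.0, 2.5, n)
        ring = np.c_[radius * np.cos(theta), radius * np.sin(theta)]
        core = rng.normal(0, 0.5, (n, 2))
        cohort = cohort_2d(ring, core)
        model = train_tc_svdd(cohort, SVDDHyperparams(sigma=0.5))
        assert evaluate(model, cohort).accuracy > 0.9

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        cohort = cohort_2d(rng.normal(size=(10, 2)), rng.normal(size=(0, 2)))
        with pytest.raises(ValueError):
            train_tc_svdd(cohort)

    def test_dual_constraints_hold(self, separated_blobs):
        _, model = separated_blobs
        for sphere in (model.sphere_high, model.sphere_low):
            alpha = np.abs(sphere.beta)
            assert (alpha >= -1e-12).all()
            assert (alpha <= sphere.box_limits + 1e-10).all()
            assert sphere.beta.sum() == pytest.approx(1.0, abs=1e-9)


class TestKernelDistance:
    def test_single_point_sphere_zero_at_center(self):
        p = np.array([[0.2, 0.8]])
        sphere = SVDDSphere(
            ref_points=p, beta=np.array([1.0]), squared_radius=0.0,
            center_self_term=1.0, sigma=1.0,
        )
        assert kernel_distance2(sphere, p[0]) == pytest.approx(0.0, abs=1e-12)

    def test_non_negative_on_random_probes(self, separated_blobs):
        _, model = separated_blobs
        rng = np.random.default_rng(5)
        probes = rng.uniform(-0.5, 1.5, size=(1000, 2))
        for sphere in (model.sphere_high, model.sphere_low):
            assert (sphere.distance2(probes) >= 0).all()

    def test_boundary_support_vectors_on_sphere(self, separated_blobs):
        # KKT: duals strictly inside the box lie on the sphere surface
        _, model = separated_blobs
        for sphere in (model.sphere_high, model.sphere_low):
            mask = sphere.diagnostics["boundary_mask"]
            if not mask.any():
                continue
            d2 = sphere.diagnostics["d2_train"][mask]
            np.testing.assert_allclose(d2, sphere.squared_radius, atol=1e-4)


class TestClassifyRules:
    @staticmethod
    def _point_sphere(center, r2):
        return SVDDSphere(
            ref_points=np.atleast_2d(center), beta=np.array([1.0]),
            squared_radius=r2, center_self_term=1.0, sigma=1.0,
        )

    def _model(self):
        from t2dcf.schema import ScalingTransform
        from conftest import schema_2d
        scaler = ScalingTransform(["f1", "f2"], np.zeros(2), np.ones(2))
        return TCSVDDModel(
            sphere_high=self._point_sphere([0.0, 0.0], 0.5),
            sphere_low=self._point_sphere([1.0, 1.0], 0.5),
            scaler=scaler, schema=schema_2d(),
            hyperparams=SVDDHyperparams(sigma=1.0),
        )

    def test_membership_rules(self):
        model = self._model()
        assert classify_scaled(model, np.array([[0.0, 0.0]]))[0] == HIGH
        assert classify_scaled(model, np.array([[1.0, 1.0]]))[0] == LOW
        # midpoint is inside both spheres -> abstain
        assert classify_scaled(model, np.array([[0.5, 0.5]]))[0] == UNCLASSIFIED
        # far corner is outside both -> abstain
        assert classify_scaled(model, np.array([[30.0, -30.0]]))[0] == UNCLASSIFIED


class _StubModel:
    """Model stand-in whose classifications are injected by the test."""

    def __init__(self, outcomes):
        self._outcomes = np.asarray(outcomes, dtype=object)
        self.sphere_high = self.sphere_low = None

    def scale(self, X):
        return X


class TestEvaluate:
    @staticmethod
    def _balanced_cohort(n_per_class=100):
        rng = np.random.default_rng(1)
        return cohort_2d(rng.normal(0, 1, (n_per_class, 2)),
                         rng.normal(0, 1, (n_per_class, 2)))

    def _run(self, monkeypatch, outcomes):
        import t2dcf.svdd as svdd_mod
        cohort = self._balanced_cohort()
        stub = _StubModel(outcomes)
        monkeypatch.setattr(svdd_mod, "classify_scaled",
                            lambda model, X: stub._outcomes)
        return evaluate(stub, cohort)

    def test_abstention_stays_in_accuracy_denominator(self, monkeypatch):
        # per-class rates 48% sensitivity / 91% specificity on a balanced
        # cohort average to 69.5% accuracy under the abstention convention
        out = ([HIGH] * 48 + [LOW] * 34 + [UNCLASSIFIED] * 18
               + [LOW] * 91 + [HIGH] * 2 + [UNCLASSIFIED] * 7)
        p = self._run(monkeypatch, out)
        assert p.accuracy == pytest.approx(0.695)
        assert p.sensitivity == pytest.approx(0.48)
        assert p.specificity == pytest.approx(0.91)
        assert p.fnr == pytest.approx(0.34)
        assert p.fpr == pytest.approx(0.02)
        assert p.ppv == pytest.approx(48 / 50)
        assert p.npv == pytest.approx(91 / 125)

    def test_all_unclassified(self, monkeypatch):
        p = self._run(monkeypatch, [UNCLASSIFIED] * 200)
        assert p.accuracy == 0 and p.sensitivity == 0 and p.fnr == 0

    def test_perfect_separation(self, separated_blobs):
        cohort, model = separated_blobs
        p = evaluate(model, cohort)
        assert p.accuracy == 1.0 and p.fnr == 0.0 and p.fpr == 0.0

    def test_rate_identities_hold_exactly(self, separated_blobs):
        cohort, model = separated_blobs
        for c in (cohort,):
            p = evaluate(model, c)
            assert (p.sensitivity + p.fnr + p.fraction_unclassified_positives
                    == pytest.approx(1.0, abs=1e-12))
            assert (p.specificity + p.fpr + p.fraction_unclassified_negatives
                    == pytest.approx(1.0, abs=1e-12))

    def test_empty_cohort_rejected(self, separated_blobs):
        cohort, model = separated_blobs
        with pytest.raises(ValueError):
            evaluate(model, cohort.subset(np.zeros(len(cohort), dtype=bool)))


@pytest.fixture(scope="module")
def overlap_model():
    cohort, _ = generate_cohort(default_t2dm_config(n_per_class=300, seed=42))
    train, _ = split_stratified(cohort, 0.7, seed=42)
    return train, train_tc_svdd(train)


class TestFNRReduction:
    def test_tau_one_is_a_no_op(self, overlap_model):
        train, model = overlap_model
        reduced = reduce_fnr(model, train, tau=1.0)
        assert len(reduced.reduction_trace) == 1
        assert reduced.sphere_low.squared_radius == model.sphere_low.squared_radius
        assert reduced.reduced

    def test_trace_fnr_monotone_non_increasing(self, overlap_model):
        train, model = overlap_model
        reduced = reduce_fnr(model, train, tau=0.08)
        fnrs = [step["fnr"] for step in reduced.reduction_trace]
        assert all(a >= b - 1e-12 for a, b in zip(fnrs, fnrs[1:]))
        assert fnrs[-1] <= 0.08

    def test_region_nesting(self, overlap_model):
        train, model = overlap_model
        reduced = reduce_fnr(model, train, tau=0.08)
        assert (reduced.sphere_low.squared_radius
                <= model.sphere_low.squared_radius)
        X = model.scale(train.X)
        inside_red = reduced.sphere_low.contains(X)
        inside_orig = model.sphere_low.contains(X)
        assert (inside_orig | ~inside_red).all()

    def test_coverage_floor_violation_carries_trace(self, overlap_model):
        train, model = overlap_model
        with pytest.raises(FNRReductionError) as exc:
            reduce_fnr(model, train, tau=1e-9, coverage_floor=0.99)
        assert exc.value.trace


class TestGridSearchOracle:
    """Small separable instance: exhaustive search over centres expressed as
    convex combinations of training points matches the solver objective."""

    def test_objective_matches_brute_force(self):
        rng = np.random.default_rng(21)
        Xh = rng.normal([0, 0], 0.4, (4, 2))
        Xl = rng.normal([6, 6], 0.4, (4, 2))
        cohort = cohort_2d(Xh, Xl)
        sigma = 1.0
        model = train_tc_svdd(
            cohort, SVDDHyperparams(sigma=sigma, C1=50.0, C2=50.0)
        )
        solver_obj = (model.sphere_high.squared_radius
                      + model.sphere_low.squared_radius)

        Z = model.scale(cohort.X)
        labels = cohort.y
        oracle_obj = 0.0
        for lab in ("highT2DM", "lowT2DM"):
            P = Z[labels == lab]
            K = rbf_kernel_matrix(P, P, sigma)
            best = np.inf
            steps = np.arange(0, 21)
            for combo in itertools.product(steps, repeat=len(P) - 1):
                if sum(combo) > 20:
                    continue
                w = np.array([*combo, 20 - sum(combo)]) / 20.0
                # ||phi(x_i) - sum_j w_j phi(x_j)||^2 via the kernel
                d2 = 1.0 - 2.0 * (K @ w) + w @ K @ w
                best = min(best, d2.max())
            oracle_obj += best
        assert solver_obj == pytest.approx(oracle_obj, rel=0.02)


def test_model_serialization_round_trip(tmp_path, separated_blobs):
    from t2dcf.svdd import load_model, save_model
    cohort, model = separated_blobs
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    probes = np.random.default_rng(0).uniform(0, 1, (50, 2))
    for a, b in ((model.sphere_high, back.sphere_high),
                 (model.sphere_low, back.sphere_low)):
        np.testing.assert_allclose(a.distance2(probes), b.distance2(probes))
        assert a.squared_radius == b.squared_radius
    assert (classify_scaled(back, probes) == classify_scaled(model, probes)).all()
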