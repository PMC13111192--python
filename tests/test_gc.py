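"""Signed-path GC estimator: oracle equivalence, nulls, signs, criteria."""

import numpy as np
import pytest

from cascnet.gc import (
    GCConfig,
    GCEstimate,
    batched_lag1_paths,
    gc_to_z,
    passes_joint_criterion,
    signed_gc_bivariate,
    signed_gc_multivariate,
)


def _normal_equations_fit(x, y, standardize=True):
    """Independent reference: explicit lagged design + (X'X)b = X'y solve."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if standardize:
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
    X = np.column_stack([np.ones(len(x) - 1), y[:-1], x[:-1]])
    return np.linalg.solve(X.T @ X, X.T @ y[1:])


class TestBivariate:
    def test_matches_normal_equations_on_random_instances(self, rng):
        for _ in range(100):
            T = int(rng.integers(10, 41))
            x = rng.standard_normal(T)
            y = rng.standard_normal(T)
            est = signed_gc_bivariate(x, y)
            ref = _normal_equations_fit(x, y)
            got = np.array([est.intercept, est.ar_coeff, est.gc])
            assert np.max(np.abs(got - ref)) < 1e-8

    def test_perfect_lag_copy_gives_unit_path(self, rng):
        x = rng.standard_normal(30)
        y = np.empty(30)
        y[0] = rng.standard_normal()
        y[1:] = x[:-1]
        est = signed_gc_bivariate(x, y, GCConfig(standardize_series=False))
        assert est.gc == pytest.approx(1.0, abs=1e-8)
        assert est.ar_coeff == pytest.approx(0.0, abs=1e-8)

    def test_white_noise_pairs_center_on_zero(self, rng):
        vals = [
            signed_gc_bivariate(rng.standard_normal(30), rng.standard_normal(30)).gc
            for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_scale_invariance_under_standardization(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        base = signed_gc_bivariate(x, y).gc
        scaled = signed_gc_bivariate(5.0 * x - 3.0, -0.2 * y + 11.0, ).gc
        # y flipped in sign: path coefficient flips with it
        assert abs(abs(scaled) - abs(base)) < 1e-10

    def test_unidirectional_planting_is_asymmetric(self, rng):
        fwd, bwd = [], []
        for _ in range(200):
            x = rng.standard_normal(38)
            y = 0.8 * np.concatenate([[0.0], x[:-1]]) + 0.3 * rng.standard_normal(38)
            fwd.append(abs(signed_gc_bivariate(x, y).gc))
            bwd.append(abs(signed_gc_bivariate(y, x).gc))
        assert np.mean(fwd) > np.mean(bwd)

    @pytest.mark.parametrize(
        "bad",
        [
            lambda rng: (rng.standard_normal(5), rng.standard_normal(5)),
            lambda rng: ((v := rng.standard_normal(20)), v.copy()),
        ],
        ids=["too_short", "identical_series"],
    )
    def test_degenerate_inputs_rejected(self, rng, bad):
        x, y = bad(rng)
        with pytest.raises(ValueError):
            signed_gc_bivariate(x, y)

    def test_higher_model_order_rejected(self):
        with pytest.raises(ValueError, match="model_order"):
            GCConfig(model_order=2)


class TestMultivariate:
    def test_single_source_reduces_to_bivariate(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        biv = signed_gc_bivariate(x, y)
        mv = signed_gc_multivariate(x[:, None], y)[0]
        assert mv.gc == pytest.approx(biv.gc, abs=1e-10)
        assert mv.ar_coeff == pytest.approx(biv.ar_coeff, abs=1e-10)

    def test_matches_normal_equations_multisource(self, rng):
        for _ in range(50):
            T = int(rng.integers(14, 41))
            K = int(rng.integers(2, min(8, T - 6)))
            X = rng.standard_normal((T, K))
            y = rng.standard_normal(T)
            ests = signed_gc_multivariate(X, y)
            Xs = (X - X.mean(0)) / X.std(0)
            ys = (y - y.mean()) / y.std()
            D = np.column_stack([np.ones(T - 1), ys[:-1], Xs[:-1]])
            ref = np.linalg.solve(D.T @ D, D.T @ ys[1:])
            assert np.max(np.abs(np.array([e.gc for e in ests]) - ref[2:])) < 1e-8

    def test_pure_noise_source_is_conditionally_null(self, rng):
        vals = []
        for _ in range(300):
            x1 = rng.standard_normal(38)
            x2 = rng.standard_normal(38)
            y = 0.8 * np.concatenate([[0.0], x1[:-1]]) + 0.3 * rng.standard_normal(38)
            ests = signed_gc_multivariate(np.column_stack([x1, x2]), y)
            vals.append(ests[1].gc)
        assert abs(np.mean(vals)) < 0.05

    def test_common_driver_attenuated_by_conditioning(self, rng):
        """A hidden driver inflates the bivariate path; conditioning shrinks it."""
        biv, mv = [], []
        for _ in range(200):
            z = np.empty(38)
            z[0] = rng.standard_normal()
            for t in range(1, 38):
                z[t] = 0.7 * z[t - 1] + rng.standard_normal()
            x = 0.8 * np.concatenate([[0.0], z[:-1]]) + 0.3 * rng.standard_normal(38)
            y = 0.8 * np.concatenate([[0.0], z[:-1]]) + 0.3 * rng.standard_normal(38)
            biv.append(abs(signed_gc_bivariate(x, y).gc))
            mv.append(abs(signed_gc_multivariate(np.column_stack([x, z]), y)[0].gc))
        assert np.mean(mv) < np.mean(biv)

    def test_too_many_sources_refused(self, rng):
        with pytest.raises(ValueError, match="unfittable"):
            signed_gc_multivariate(rng.standard_normal((12, 8)), rng.standard_normal(12))

    def test_collinear_sources_named(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="collinear"):
            signed_gc_multivariate(
                X, rng.standard_normal(30), source_names=["left", "right"],
                config=None,
            )


class TestZConversion:
    def test_reconstruction_against_two_pass_oracle(self, rng):
        gc = rng.standard_normal(200) * 0.3
        z = gc_to_z(gc)
        mean = sum(gc) / len(gc)
        sd = np.sqrt(sum((v - mean) ** 2 for v in gc) / len(gc))
        assert np.max(np.abs(z - (gc - mean) / sd)) < 1e-12
        assert abs(z.mean()) < 1e-10
        assert z.std() == pytest.approx(1.0, abs=1e-10)

    def test_value_at_map_mean_is_zero(self, rng):
        gc = rng.standard_normal(50)
        gc[0] = gc[1:].mean() * 0  # place one value exactly at 0, then recenter
        gc = gc - gc.mean() + 0.2
        z = gc_to_z(gc)
        at_mean = np.argmin(np.abs(gc - gc.mean()))
        assert abs(z[at_mean]) == np.min(np.abs(z))

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="zero variance|constant"):
            gc_to_z(np.full(20, 0.39))

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            gc_to_z(rng.standard_normal(5))


class TestJointCriterion:
    @pytest.mark.parametrize(
        "gc,z,expected",
        [
            (-1.47, -14.51, True),  # strong negative path survives two-sided
            (0.39, 5.0, False),  # strict inequality on gc
            (2.0, 3.75, False),  # strict inequality on z
            (0.40, 3.76, True),
            (-0.40, 3.76, True),
        ],
    )
    def test_two_sided_magnitude_rule(self, gc, z, expected):
        est = GCEstimate(source="s", target="t", gc=gc, z=z)
        assert passes_joint_criterion(est) is expected

    def test_one_sided_mode_requires_positive(self):
        cfg = GCConfig(two_sided=False)
        neg = GCEstimate(source="s", target="t", gc=-1.47, z=-14.51)
        pos = GCEstimate(source="s", target="t", gc=1.4, z=13.6)
        assert not passes_joint_criterion(neg, cfg)
        assert passes_joint_criterion(pos, cfg)


def test_batched_paths_equal_scalar_fits(rng):
    T, N = 24, 40
    P = rng.standard_normal((T, N))
    Y = rng.standard_normal((T, N))
    # batched solver assumes pre-standardized inputs, like the voxel stage
    P = (P - P.mean(0)) / P.std(0)
    Y = (Y - Y.mean(0)) / Y.std(0)
    got = batched_lag1_paths(P, Y)
    cfg = GCConfig(standardize_series=False)
    ref = np.array([signed_gc_bivariate(P[:, i], Y[:, i], cfg).gc for i in range(N)])
    assert np.max(np.abs(got - ref)) < 1e-8
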