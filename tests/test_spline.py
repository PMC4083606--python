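"""PCA frames, least-squares spline fits, discretisation and AIC."""

import math
import warnings

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly

from helixgeom import (
    GeometryError,
    HelixSpec,
    ValidationError,
    aic_score,
    best_degree_by_aic,
    compute_frame,
    evaluate_spline,
    fit_spline,
    generate_helix,
)

from conftest import identity_frame, make_trace, random_rotation


def normal_equation_fit(z, y, degree):
    """Independent least-squares oracle: explicit normal equations."""
    V = np.vander(z, degree + 1, increasing=True)
    return np.linalg.solve(V.T @ V, V.T @ y)


class TestComputeFrame:
    def test_axis_aligned_line(self):
        tr = make_trace([[i * 1.5, 0.0, 0.0] for i in range(6)])
        frame = compute_frame(tr)
        assert np.allclose(frame.axes[0], [1, 0, 0], atol=1e-12)
        assert frame.eigenvalues[0] > 0
        assert np.allclose(frame.eigenvalues[1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalues_match_independent_eigensolve(self, seed):
        rng = np.random.default_rng(seed)
        tr = make_trace(rng.normal(size=(20, 3)) * [5.0, 2.0, 0.7])
        frame = compute_frame(tr)
        X = tr.coords - tr.coords.mean(axis=0)
        cov = X.T @ X / (len(X) - 1)
        ref = np.sort(np.linalg.eig(cov).eigenvalues.real)[::-1]
        assert np.allclose(frame.eigenvalues, ref, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_axes_orthonormal_right_handed(self, seed):
        rng = np.random.default_rng(100 + seed)
        tr = make_trace(rng.normal(size=(15, 3)) * [4.0, 1.5, 0.5])
        frame = compute_frame(tr)
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-10)

    def test_pc1_points_n_to_c(self):
        tr = generate_helix(HelixSpec(n_residues=24))
        frame = compute_frame(tr)
        assert np.dot(tr.coords[-1] - tr.coords[0], frame.axes[0]) > 0

    def test_rotation_equivariance(self):
        # bend breaks the lateral eigenvalue tie of an ideal helix so PC2/PC3
        # are well determined and must co-rotate with the data
        tr = generate_helix(
            HelixSpec(n_residues=24, seed=2, axis_bend_coeffs=((0, 0, 0.03), ()))
        )
        frame = compute_frame(tr)
        R = random_rotation(np.random.default_rng(7))
        rotated = make_trace(tr.coords @ R.T + np.array([3.0, -5.0, 1.0]))
        frame_r = compute_frame(rotated)
        # sign conventions are equivariant too, so axes map exactly
        assert np.allclose(frame_r.axes, frame.axes @ R.T, atol=1e-9)
        assert np.allclose(frame_r.eigenvalues, frame.eigenvalues, atol=1e-9)

    def test_coincident_points_degenerate(self):
        tr = make_trace(np.ones((5, 3)))
        with pytest.raises(GeometryError, match="coincident"):
            compute_frame(tr)


class TestFitSpline:
    def test_collinear_points_give_zero_coefficients(self):
        tr = generate_helix(HelixSpec(n_residues=12, helix_radius=0.0))
        model = fit_spline(tr, compute_frame(tr), 3)
        assert np.allclose(model.coeffs_f2, 0.0, atol=1e-10)
        assert np.allclose(model.coeffs_f3, 0.0, atol=1e-10)
        assert model.rss == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_recovery_against_normal_equation_oracle(self):
        z = np.linspace(-15, 15, 25)
        tr = make_trace(np.column_stack([z, 0.01 * z**2, -0.004 * z**2]))
        model = fit_spline(tr, identity_frame(), 2)
        assert np.allclose(model.coeffs_f2, [0, 0, 0.01], atol=1e-8)
        assert np.allclose(model.coeffs_f3, [0, 0, -0.004], atol=1e-8)
        assert np.allclose(
            model.coeffs_f2, normal_equation_fit(z, 0.01 * z**2, 2), atol=1e-8
        )

    @pytest.mark.parametrize("degree", [1, 2, 3, 4])
    def test_random_instances_match_normal_equation_oracle(self, degree):
        rng = np.random.default_rng(degree)
        for _ in range(25):
            n = rng.integers(degree + 3, 40)
            z = np.sort(rng.uniform(-20, 20, n))
            true2 = rng.normal(scale=0.05, size=degree + 1)
            true3 = rng.normal(scale=0.05, size=degree + 1)
            y2 = npoly.polyval(z, true2) + rng.normal(scale=0.1, size=n)
            y3 = npoly.polyval(z, true3) + rng.normal(scale=0.1, size=n)
            tr = make_trace(np.column_stack([z, y2, y3]))
            model = fit_spline(tr, identity_frame(), degree)
            assert np.allclose(model.coeffs_f2, normal_equation_fit(z, y2, degree),
                               atol=1e-8)
            assert np.allclose(model.coeffs_f3, normal_equation_fit(z, y3, degree),
                               atol=1e-8)

    def test_rss_nonincreasing_in_degree(self):
        tr = generate_helix(HelixSpec(n_residues=30, noise_sigma=0.2, seed=8))
        frame = compute_frame(tr)
        rss = [fit_spline(tr, frame, m).rss for m in (2, 3, 4)]
        assert rss[0] >= rss[1] >= rss[2] >= 0

    def test_rigid_motion_leaves_rss_and_span_invariant(self):
        tr = generate_helix(HelixSpec(n_residues=30, noise_sigma=0.15, seed=9))
        model = fit_spline(tr, compute_frame(tr), 3)
        R = random_rotation(np.random.default_rng(3))
        moved = make_trace(tr.coords @ R.T + np.array([10.0, -4.0, 2.0]))
        model_m = fit_spline(moved, compute_frame(moved), 3)
        assert model_m.rss == pytest.approx(model.rss, rel=1e-6)
        assert model_m.z_max - model_m.z_min == pytest.approx(
            model.z_max - model.z_min, rel=1e-6
        )

    def test_too_few_points_rejected(self):
        tr = make_trace(np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)]))
        with pytest.raises(ValidationError, match="at least"):
            fit_spline(tr, identity_frame(), 3)

    def test_duplicate_z_rank_deficiency(self):
        coords = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0.0]]
        )
        with pytest.raises(GeometryError, match="rank"):
            fit_spline(make_trace(coords), identity_frame(), 2)


class TestEvaluateSpline:
    def _line_model(self):
        tr = generate_helix(HelixSpec(n_residues=21, helix_radius=0.0))
        return fit_spline(tr, compute_frame(tr), 2)

    def test_two_points_are_the_endpoints(self):
        model = self._line_model()
        curve = evaluate_spline(model, 2)
        local = model.frame.to_local(curve.points_global)
        assert local[0, 0] == pytest.approx(model.z_min, abs=1e-10)
        assert local[1, 0] == pytest.approx(model.z_max, abs=1e-10)

    def test_straight_line_arc_length(self):
        model = self._line_model()
        curve = evaluate_spline(model, 1500)
        assert curve.arc_lengths[-1] == pytest.approx(
            model.z_max - model.z_min, abs=1e-9
        )
        assert np.all(np.diff(curve.arc_lengths) >= 0)

    def test_global_points_round_trip_through_frame(self):
        tr = generate_helix(HelixSpec(n_residues=24, noise_sigma=0.1, seed=12))
        model = fit_spline(tr, compute_frame(tr), 3)
        curve = evaluate_spline(model, 100)
        local = model.frame.to_local(curve.points_global)
        z = np.linspace(model.z_min, model.z_max, 100)
        assert np.allclose(local[:, 0], z, atol=1e-10)
        assert np.allclose(local[:, 1], npoly.polyval(z, model.coeffs_f2), atol=1e-10)
        assert np.allclose(local[:, 2], npoly.polyval(z, model.coeffs_f3), atol=1e-10)

    def test_arclength_spacing_uniform(self):
        tr = generate_helix(
            HelixSpec(n_residues=30, helix_radius=0.0,
                      axis_bend_coeffs=((0, 0, 0.02), ()))
        )
        model = fit_spline(tr, compute_frame(tr), 2)
        curve = evaluate_spline(model, 200, spacing="arclength")
        seg = np.diff(curve.arc_lengths)
        assert seg.max() - seg.min() < 1e-3 * seg.mean() + 1e-6

    def test_m_below_two_rejected(self):
        with pytest.raises(ValidationError, match="M"):
            evaluate_spline(self._line_model(), 1)


class TestAIC:
    def _model(self, rss, m, n_points=30):
        tr = generate_helix(HelixSpec(n_residues=n_points, noise_sigma=0.1, seed=1))
        base = fit_spline(tr, compute_frame(tr), m)
        return type(base)(
            degree_m=m, coeffs_f2=base.coeffs_f2, coeffs_f3=base.coeffs_f3,
            z_min=base.z_min, z_max=base.z_max, frame=base.frame,
            rss=rss, n_points=n_points,
        )

    def test_penalty_monotone_at_equal_rss(self):
        assert aic_score(self._model(5.0, 2)) < aic_score(self._model(5.0, 4))

    def test_halving_rss_drops_aic_by_n_ln2(self):
        n = 2 * 30
        delta = aic_score(self._model(4.0, 2)) - aic_score(self._model(2.0, 2))
        assert delta == pytest.approx(n * math.log(2), rel=1e-12)

    def test_perfect_fit_returns_neg_inf_with_warning(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert aic_score(self._model(0.0, 2)) == -math.inf

    def test_aic_selects_true_quadratic_degree(self):
        """Monte-Carlo: quadratic-bent noisy helices, AIC picks m=2 >= 90/100."""
        wins = 0
        for rep in range(100):
            spec = HelixSpec(
                n_residues=36,
                axis_bend_coeffs=((0, 0, 0.01), (0, 0, -0.004)),
                noise_sigma=0.15,
                seed=2000 + rep,
            )
            tr = generate_helix(spec)
            frame = compute_frame(tr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models = [fit_spline(tr, frame, m) for m in (2, 3, 4)]
                wins += best_degree_by_aic(models) == 2
        assert wins >= 90
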