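"""GPA, centroid size, bilateral symmetry, allometry and shape prediction."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from crossfence.core_io import LandmarkConfiguration
from crossfence.morphometrics import (
    AlignmentError,
    allometry_model,
    bilateral_symmetry,
    centroid_size,
    gpa,
    mirror_config,
    predicted_shape,
    procrustes_distance,
)
from crossfence.synthetic_data import (
    default_population_specs,
    gen_landmarks,
    gen_specimens,
    symmetric_template,
)


def reference_gpa_oracle(arrays, tol=1e-12, max_iter=500):
    """Independent consensus via reference-based ordinary Procrustes fits.

    Centres/scales every configuration, then repeatedly aligns each one to
    the running mean with scipy's orthogonal Procrustes solution and
    re-averages, which converges to the same optimum as simultaneous GPA
    on well-conditioned instances.
    """
    zs = []
    for a in arrays:
        c = a - a.mean(axis=0)
        zs.append(c / np.sqrt(np.sum(c**2)))
    ref = zs[0]
    for _ in range(max_iter):
        rotated = []
        for z in zs:
            r, _ = orthogonal_procrustes(z, ref)
            rotated.append(z @ r)
        new = np.mean(rotated, axis=0)
        new /= np.sqrt(np.sum(new**2))
        if np.sqrt(np.sum((new - ref) ** 2)) < tol:
            ref = new
            break
        ref = new
    return np.stack(rotated), ref


def _random_rigid(rng, scale=True):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    t = rng.uniform(-10, 10, 3)
    return lambda x: s * x @ q + t


class TestCentroidSize:
    def test_hand_computed_square(self):
        coords = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        assert centroid_size(coords) == pytest.approx(2 * np.sqrt(2.0), rel=1e-12)

    def test_homogeneity_and_translation_invariance(self, rng):
        coords = rng.normal(size=(7, 3))
        cs = centroid_size(coords)
        assert centroid_size(2 * coords) == pytest.approx(2 * cs, rel=1e-12)
        assert centroid_size(coords + [5.0, -3.0, 9.9]) == pytest.approx(cs, rel=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((5, 3)))


class TestGPA:
    def _configs(self, rng, n=3, k=10, spread=0.1):
        base = rng.normal(size=(k, 3))
        out = []
        for i in range(n):
            out.append(LandmarkConfiguration(f"s{i}", base + spread * rng.normal(size=(k, 3))))
        return out

    def test_identical_configs_distance_zero(self, rng):
        base = rng.normal(size=(8, 3))
        aligned = gpa([LandmarkConfiguration("a", base), LandmarkConfiguration("b", base.copy())])
        d = procrustes_distance(aligned.procrustes_coords[0], aligned.procrustes_coords[1])
        assert d < 1e-10

    def test_rigid_transform_removed(self, rng):
        base = rng.normal(size=(9, 3))
        moved = _random_rigid(rng)(base)
        aligned = gpa([LandmarkConfiguration("a", base), LandmarkConfiguration("b", moved)])
        assert procrustes_distance(*aligned.procrustes_coords) < 1e-8

    def test_output_invariant_to_input_transforms(self, rng):
        configs = self._configs(rng, n=4)
        ref = gpa(configs)
        moved = [
            LandmarkConfiguration(c.specimen_id, _random_rigid(rng)(c.coordinates))
            for c in configs
        ]
        res = gpa(moved)
        # compare in a common frame: rotate one consensus onto the other
        r, _ = orthogonal_procrustes(res.consensus, ref.consensus)
        assert np.linalg.det(r) > 0
        for a, b in zip(res.procrustes_coords, ref.procrustes_coords):
            assert np.max(np.abs(a @ r - b)) < 1e-8

    def test_alignment_invariants(self, rng):
        res = gpa(self._configs(rng, n=5))
        for x in res.procrustes_coords:
            assert np.max(np.abs(x.mean(axis=0))) < 1e-8
            assert np.sqrt(np.sum(x**2)) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            res.consensus, res.procrustes_coords.mean(axis=0), atol=1e-8
        )

    def test_matches_reference_oracle(self, rng):
        configs = self._configs(rng, n=3, k=10)
        mine = gpa(configs)
        _, oracle_consensus = reference_gpa_oracle([c.coordinates for c in configs])
        mine_unit = mine.consensus / np.sqrt(np.sum(mine.consensus**2))
        r, _ = orthogonal_procrustes(oracle_consensus, mine_unit)
        assert np.max(np.abs(oracle_consensus @ r - mine_unit)) < 1e-6

    def test_degenerate_configuration_named(self, rng):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        good = rng.normal(size=(5, 3))
        with pytest.raises(AlignmentError, match="bad"):
            gpa([LandmarkConfiguration("good", good), LandmarkConfiguration("bad", line)])

    def test_distance_is_metric_on_aligned_shapes(self, rng):
        res = gpa(self._configs(rng, n=3))
        a, b, c = res.procrustes_coords
        assert procrustes_distance(a, b) == pytest.approx(procrustes_distance(b, a))
        assert procrustes_distance(a, c) <= (
            procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12
        )


class TestBilateralSymmetry:
    def _symmetric_configs(self, rng, n=6, k=12, asym_sd=0.0):
        specs = default_population_specs(exact_sex_counts=True)
        records = gen_specimens(specs, seed=3).head(n)
        return gen_landmarks(records, template_k=k, asym_sd=asym_sd, seed=4)

    def test_mirroring_is_involution(self, rng):
        template, pairing = symmetric_template(12)
        noisy = template + 0.05 * rng.normal(size=template.shape)
        np.testing.assert_array_equal(mirror_config(mirror_config(noisy, pairing), pairing), noisy)

    def test_symmetric_input_has_zero_asymmetric_component(self, rng):
        res = bilateral_symmetry(self._symmetric_configs(rng, asym_sd=0.0))
        assert np.max(np.abs(res.asymmetric_component)) < 1e-9

    def test_components_reconstruct_aligned_coordinates(self, rng):
        res = bilateral_symmetry(self._symmetric_configs(rng, asym_sd=0.01))
        np.testing.assert_allclose(
            res.symmetric_component + res.asymmetric_component,
            res.procrustes_coords,
            atol=1e-12,
        )
        # orthogonal decomposition of squared norms (unit-size shapes)
        total = np.sum(res.procrustes_coords**2, axis=(1, 2))
        parts = np.sum(res.symmetric_component**2, axis=(1, 2)) + np.sum(
            res.asymmetric_component**2, axis=(1, 2)
        )
        np.testing.assert_allclose(total, parts, atol=1e-8)

    def test_asymmetric_norm_linear_in_perturbation(self):
        template, pairing = symmetric_template(12)
        rng = np.random.default_rng(8)
        direction = np.zeros_like(template)
        left, right = pairing.pairs[0]
        v = rng.normal(size=3)
        direction[left] = v
        direction[right] = -(v * np.array([-1.0, 1.0, 1.0]))
        norms = []
        eps_grid = [0.001, 0.002, 0.004]
        for eps in eps_grid:
            configs = [
                LandmarkConfiguration("base", template * 100.0),
                LandmarkConfiguration("pert", (template + eps * direction) * 100.0),
            ]
            res = bilateral_symmetry(configs, pairing=pairing)
            norms.append(float(np.sqrt(np.sum(res.asymmetric_component[1] ** 2))))
        ratios = np.diff(np.log(norms)) / np.diff(np.log(eps_grid))
        np.testing.assert_allclose(ratios, 1.0, atol=0.05)

    def test_midline_off_plane_warns(self):
        template, pairing = symmetric_template(12)
        coords = template.copy() * 100.0
        coords[pairing.midline[0], 0] += 30.0  # push a midline point off x=0
        configs = [
            LandmarkConfiguration("warped", coords),
            LandmarkConfiguration("clean", template * 100.0),
        ]
        with pytest.warns(UserWarning, match="midsagittal"):
            bilateral_symmetry(configs, pairing=pairing)


@pytest.fixture(scope="module")
def fitted():
    specs = default_population_specs(exact_sex_counts=True)
    records = gen_specimens(specs, seed=13).head(60).reset_index(drop=True)
    landmarks = gen_landmarks(records, allometric_vector_scale=0.2, ind_sd=0.003,
                              asym_sd=0.001, seed=14)
    shapes = bilateral_symmetry(landmarks)
    fit = allometry_model(shapes, records, response="shape", n_perm=200, seed=15)
    return records, shapes, fit


class TestAllometry:
    def test_size_term_detected(self, fitted):
        _, _, fit = fitted
        assert fit.p["log_centroid_size"] <= 0.05
        assert fit.r_squared["log_centroid_size"] > 0.1

    def test_pes_response_uses_same_engine(self, fitted):
        records, shapes, _ = fitted
        res = allometry_model(shapes, records, response="pes", n_perm=100, seed=16)
        assert res.p["log_centroid_size"] <= 0.05

    def test_decoupled_sizes_destroy_size_association(self, fitted):
        """Permuting centroid sizes against the shapes (a negative control)
        collapses the size term's explained variance."""
        import dataclasses

        records, shapes, fit = fitted
        rng = np.random.default_rng(17)
        hits = 0
        for i in range(10):
            broken = dataclasses.replace(
                shapes, centroid_sizes=rng.permutation(shapes.centroid_sizes)
            )
            res = allometry_model(broken, records, response="shape", n_perm=100, seed=18 + i)
            hits += res.r_squared["log_centroid_size"] > 0.5 * fit.r_squared["log_centroid_size"]
        assert hits <= 2

    def test_prediction_at_mean_returns_mean_shape(self, fitted):
        _, shapes, fit = fitted
        at = {"log_centroid_size": fit.design_info["covariate_means"]["log_centroid_size"]}
        pred = predicted_shape(fit, at)
        np.testing.assert_allclose(pred, shapes.symmetric_component.mean(axis=0), atol=1e-9)

    def test_size_predictions_track_generating_allometric_vector(self):
        from scipy.linalg import orthogonal_procrustes

        specs = default_population_specs(exact_sex_counts=True)
        records = gen_specimens(specs, seed=23).head(50).reset_index(drop=True)
        landmarks = gen_landmarks(records, allometric_vector_scale=0.25, ind_sd=0.0,
                                  asym_sd=0.0, seed=24)
        shapes = bilateral_symmetry(landmarks)
        fit = allometry_model(shapes, records, response="shape", n_perm=10, seed=25)
        lo, hi = fit.design_info["covariate_range"]
        sex_mean = fit.design_info["covariate_means"]["sex"]
        diff = predicted_shape(fit, {"log_centroid_size": hi, "sex": sex_mean}) - predicted_shape(
            fit, {"log_centroid_size": lo, "sex": sex_mean}
        )
        # move into the template frame before comparing directions
        template, pairing = symmetric_template(12)
        r, _ = orthogonal_procrustes(shapes.consensus, template)
        diff_t = (diff @ r).ravel()
        vec_rng = np.random.default_rng(86420 + 12)
        from crossfence.synthetic_data import _symmetrize

        allo = _symmetrize(vec_rng.normal(size=(12, 3)), pairing)
        allo -= allo.mean(axis=0)
        allo = allo.ravel() / np.linalg.norm(allo)
        cos = abs(float(diff_t @ allo) / np.linalg.norm(diff_t))
        assert cos > 0.9

    def test_zero_allometry_predictions_coincide(self):
        specs = default_population_specs(exact_sex_counts=True)
        records = gen_specimens(specs, seed=33).head(50).reset_index(drop=True)
        landmarks = gen_landmarks(records, allometric_vector_scale=0.0, ind_sd=0.004,
                                  asym_sd=0.0, seed=34)
        shapes = bilateral_symmetry(landmarks)
        fit = allometry_model(shapes, records, response="shape", n_perm=10, seed=35)
        lo, hi = fit.design_info["covariate_range"]
        sex_mean = fit.design_info["covariate_means"]["sex"]
        d = predicted_shape(fit, {"log_centroid_size": hi, "sex": sex_mean}) - predicted_shape(
            fit, {"log_centroid_size": lo, "sex": sex_mean}
        )
        typical = np.sqrt(np.mean(shapes.symmetric_component.var(axis=0)))
        assert np.sqrt(np.mean(d**2)) < 2 * typical

    def test_extrapolation_warns(self, fitted):
        _, _, fit = fitted
        lo, hi = fit.design_info["covariate_range"]
        with pytest.warns(UserWarning, match="extrapolates"):
            predicted_shape(fit, {"log_centroid_size": hi + (hi - lo), "sex": "male"})
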