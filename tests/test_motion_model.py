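"""Boundary PCA motion model: decomposition, fitting, residuals."""

import numpy as np
import pytest

from pelvimotion.core import DisplacementField, LabelMaskSet
from pelvimotion.motion_model import (
    BoundaryIndexSet,
    MotionModel,
    build_model,
    cumulative_variance,
    extract_boundary,
    fit_field,
    optimal_weights,
    reconstruct,
    residuals,
)


# ---------------------------------------------------------------- helpers
def _mask_set(mask, spacing=(1.0, 1.0, 1.0)):
    return LabelMaskSet(
        {"prostate": mask, "bladder": np.zeros_like(mask) | mask,
         "rectum": mask}, spacing_mm=spacing
    )


def _field_from_boundary(boundary, values):
    """Dense field carrying the given 3N boundary values (zero elsewhere)."""
    vec = np.zeros(tuple(boundary.grid_shape) + (3,))
    i, j, k = boundary.indices.T
    vec[i, j, k] = np.asarray(values).reshape(-1, 3)
    return DisplacementField(vec, spacing_mm=boundary.spacing_mm)


@pytest.fixture(scope="module")
def box_boundary():
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[3:8, 3:8, 3:8] = True  # 5x5x5 solid box
    return extract_boundary(_mask_set(mask), "joint")


def _planted(rng, boundary, n_fields=5, n_modes=2):
    """Training fields x_mean + sum_m a_m^t P_m with orthonormal modes.

    The coefficient samples are centred and decorrelated in-sample, so the
    planted per-mode sample variances are exactly the PCA eigenvalues.
    """
    n = 3 * len(boundary)
    basis = np.linalg.qr(rng.normal(size=(n, n_modes)))[0].T
    mean = rng.normal(scale=0.5, size=n)
    coeff = rng.normal(size=(n_fields, n_modes))
    coeff -= coeff.mean(axis=0)
    coeff = np.linalg.qr(coeff)[0]  # orthogonal columns, still zero-mean
    sds = np.array([2.0, 0.7, 0.35, 0.2][:n_modes])
    coeff = coeff * sds * np.sqrt(n_fields - 1)
    obs = mean + coeff @ basis
    fields = [_field_from_boundary(boundary, row) for row in obs]
    return fields, mean, basis, coeff


# ------------------------------------------------------ boundary extraction
class TestExtractBoundary:
    def test_solid_box_has_98_boundary_voxels(self, box_boundary):
        assert len(box_boundary) == 98

    def test_single_voxel_mask(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 2, 3] = True
        bnd = extract_boundary(_mask_set(mask), "joint")
        np.testing.assert_array_equal(bnd.indices, [[1, 2, 3]])

    def test_empty_mask_rejected(self):
        empty = np.zeros((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            extract_boundary(_mask_set(empty), "joint")

    def test_joint_scope_is_union_of_organ_boundaries(self, coarse_series):
        masks = coarse_series[0].masks
        joint = extract_boundary(masks, "joint")
        union = set()
        for name in masks.names():
            organ = extract_boundary(masks, name)
            union.update(map(tuple, organ.indices))
        assert union == set(map(tuple, joint.indices))


# ----------------------------------------------------------------- build
class TestBuildModel:
    def test_identical_training_fields_have_zero_variance(self, box_boundary, rng):
        values = rng.normal(size=3 * len(box_boundary))
        f = _field_from_boundary(box_boundary, values)
        model = build_model([f, f, f], box_boundary)
        np.testing.assert_allclose(model.mean_displacement, values, atol=1e-12)
        assert model.n_components == 0

    def test_two_fields_give_rank_one(self, box_boundary, rng):
        x1 = rng.normal(size=3 * len(box_boundary))
        x2 = rng.normal(size=3 * len(box_boundary))
        model = build_model(
            [_field_from_boundary(box_boundary, x) for x in (x1, x2)],
            box_boundary,
        )
        assert model.n_components == 1
        direction = (x1 - x2) / np.linalg.norm(x1 - x2)
        dot = abs(float(model.components[0] @ direction))
        assert dot == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(cumulative_variance(model), [1.0])

    def test_planted_modes_recovered(self, box_boundary, rng):
        """Subspace and eigenvalues of two planted orthonormal modes."""
        fields, mean, basis, coeff = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        np.testing.assert_allclose(model.mean_displacement, mean, atol=1e-10)
        # principal angles between recovered and planted 2D subspaces
        svals = np.linalg.svd(model.components[:2] @ basis.T, compute_uv=False)
        assert np.arccos(np.clip(svals.min(), -1, 1)) < 1e-6
        expected = np.sort(np.var(coeff, axis=0, ddof=1))[::-1]
        np.testing.assert_allclose(
            model.eigenvalues[:2], expected, rtol=1e-8
        )

    def test_orthonormal_components(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary, n_fields=5, n_modes=2)
        model = build_model(fields, box_boundary)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)

    def test_eigenvalues_descending(self, coarse_fields, coarse_series):
        boundary = extract_boundary(coarse_series[0].masks, "joint")
        model = build_model(coarse_fields[1:6], boundary)
        assert np.all(np.diff(model.eigenvalues) <= 0)

    def test_scale_equivariance(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary)
        model1 = build_model(fields, box_boundary)
        scaled = [
            DisplacementField(3.0 * f.vectors, spacing_mm=f.spacing_mm)
            for f in fields
        ]
        model3 = build_model(scaled, box_boundary)
        np.testing.assert_allclose(
            model3.eigenvalues, 9.0 * model1.eigenvalues, rtol=1e-10
        )
        for c1, c3 in zip(model1.components, model3.components):
            assert abs(float(c1 @ c3)) == pytest.approx(1.0, abs=1e-10)

    def test_fewer_than_two_fields_rejected(self, box_boundary, rng):
        f = _field_from_boundary(
            box_boundary, rng.normal(size=3 * len(box_boundary))
        )
        with pytest.raises(ValueError, match="at least 2"):
            build_model([f], box_boundary)


# ------------------------------------------------- reconstruct / weights
class TestReconstructAndWeights:
    def test_zero_weights_return_mean(self, box_boundary, rng):
        fields, mean, *_ = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        np.testing.assert_array_equal(
            reconstruct(model, np.zeros(model.n_components)),
            model.mean_displacement,
        )

    def test_training_fields_reproduced_exactly(self, box_boundary, rng):
        """PCA completeness: every training field rebuilt to machine
        precision from all components and its optimal weights."""
        fields, *_ = _planted(rng, box_boundary, n_fields=5, n_modes=4)
        model = build_model(fields, box_boundary)
        for f in fields:
            w = optimal_weights(model, f)
            recon = reconstruct(model, w)
            np.testing.assert_allclose(
                recon, box_boundary.sample(f), atol=1e-8
            )

    def test_single_component_weight_recovered(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        probe = _field_from_boundary(
            box_boundary, model.mean_displacement + 2.5 * model.components[0]
        )
        w = optimal_weights(model, probe)
        assert w[0] == pytest.approx(2.5, abs=1e-10)
        np.testing.assert_allclose(w[1:], 0.0, atol=1e-10)

    def test_reconstruction_stays_in_component_span(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary, n_modes=3)
        model = build_model(fields, box_boundary)
        k = 2
        out = reconstruct(model, rng.normal(size=k), k)
        centred = out - model.mean_displacement
        proj = model.components[:k].T @ (model.components[:k] @ centred)
        assert np.linalg.norm(centred - proj) < 1e-10

    def test_weights_match_grid_search_minimizer(self, box_boundary, rng):
        """Each optimal weight agrees with a dense 1-D grid search over
        that weight's value (scored by the mean squared residual, the
        quantity the projection provably minimizes)."""
        fields, *_ = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        probe = _field_from_boundary(
            box_boundary, rng.normal(scale=1.5, size=3 * len(box_boundary))
        )
        w_opt = optimal_weights(model, probe)
        step = 0.02
        for n in range(model.n_components):
            candidates = np.arange(w_opt[n] - 1.0, w_opt[n] + 1.0, step)
            scores = []
            for c in candidates:
                w = w_opt.copy()
                w[n] = c
                res = residuals(
                    reconstruct(model, w), probe, box_boundary, squared=True
                )
                scores.append(res.mean())
            best = candidates[int(np.argmin(scores))]
            assert abs(best - w_opt[n]) <= step

    def test_weights_beat_random_perturbations(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        probe = _field_from_boundary(
            box_boundary, rng.normal(scale=1.5, size=3 * len(box_boundary))
        )
        w_opt = optimal_weights(model, probe)
        base = residuals(
            reconstruct(model, w_opt), probe, box_boundary, squared=True
        ).mean()
        for _ in range(200):
            perturbed = w_opt + rng.normal(scale=0.3, size=len(w_opt))
            score = residuals(
                reconstruct(model, perturbed), probe, box_boundary,
                squared=True,
            ).mean()
            assert score >= base - 1e-12

    def test_k_exceeding_components_rejected(self, box_boundary, rng):
        fields, *_ = _planted(rng, box_boundary)
        model = build_model(fields, box_boundary)
        with pytest.raises(ValueError, match="exceeds"):
            reconstruct(model, np.zeros(9), 9)
        with pytest.raises(ValueError, match="exceeds"):
            optimal_weights(model, fields[0], 9)


# --------------------------------------------------------------- residuals
class TestResiduals:
    def test_exact_match_gives_zero(self, box_boundary, rng):
        values = rng.normal(size=3 * len(box_boundary))
        res = residuals(
            values, _field_from_boundary(box_boundary, values), box_boundary
        )
        np.testing.assert_array_equal(res, 0.0)

    def test_pythagorean_single_voxel(self, box_boundary):
        ref = np.zeros(3 * len(box_boundary))
        model_field = ref.copy()
        model_field[3:6] = (3.0, 4.0, 0.0)
        res = residuals(
            model_field, _field_from_boundary(box_boundary, ref), box_boundary
        )
        assert res[1] == 5.0 and res[0] == 0.0
        squared = residuals(
            model_field, _field_from_boundary(box_boundary, ref),
            box_boundary, squared=True,
        )
        assert squared[1] == 25.0

    def test_length_mismatch_rejected(self, box_boundary):
        with pytest.raises(ValueError, match="mismatch"):
            residuals(np.zeros(7), np.zeros(3 * len(box_boundary)), box_boundary)

    def test_mean_squared_residual_monotone_in_k(
        self, coarse_series, coarse_fields
    ):
        """On every phantom validation field the mean squared residual —
        the objective minimized by the projection weights — never
        increases when another component is added."""
        boundary = extract_boundary(coarse_series[0].masks, "joint")
        model = build_model(coarse_fields[1:6], boundary)
        for field in coarse_fields[6:]:
            means = []
            for k in range(model.n_components + 1):
                w = optimal_weights(model, field, k)
                res = residuals(
                    reconstruct(model, w, k), field, boundary, squared=True
                )
                means.append(res.mean())
            assert np.all(np.diff(means) <= 1e-12)


# ---------------------------------------------------------- misc contract
class TestCumulativeVariance:
    def test_partial_sums(self):
        np.testing.assert_allclose(
            cumulative_variance(np.array([3.0, 1.0])), [0.75, 1.0]
        )
        np.testing.assert_allclose(
            cumulative_variance(np.array([4.0, 0.0, 0.0])), [1.0, 1.0, 1.0]
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cumulative_variance(np.zeros(3))


def test_model_roundtrip(tmp_path, box_boundary, rng):
    fields, *_ = _planted(rng, box_boundary)
    model = build_model(fields, box_boundary)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = MotionModel.load(path)
    np.testing.assert_array_equal(loaded.boundary.indices, model.boundary.indices)
    np.testing.assert_array_equal(loaded.components, model.components)
    np.testing.assert_array_equal(loaded.eigenvalues, model.eigenvalues)
    np.testing.assert_array_equal(
        loaded.mean_displacement, model.mean_displacement
    )
    assert loaded.n_training == model.n_training
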