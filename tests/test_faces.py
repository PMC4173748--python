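"""Procrustes alignment, GPA, Delaunay meshing, piecewise-affine warping, averaging."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from scipy.optimize import minimize

from cdlskit.facegen import (
    FaceSimConfig,
    SimilarityTransform2D,
    default_template,
    generate_faces,
    render_face,
)
from cdlskit.faces import (
    average_appearance,
    build_average_face,
    canonical_rotation,
    delaunay_mesh,
    generalized_procrustes,
    piecewise_affine_warp,
    place_in_frame,
    procrustes_align,
    _normalise,
)


def brute_force_procrustes_distance(source, target):
    """Independent oracle: numeric minimisation over (theta, log s, tx, ty)."""

    def cost(params):
        th, logs, tx, ty = params
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = np.exp(logs) * source @ R.T + np.array([tx, ty])
        return ((moved - target) ** 2).sum()

    best = np.inf
    for th0 in np.linspace(-np.pi, np.pi, 8, endpoint=False):
        res = minimize(cost, [th0, 0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return np.sqrt(best / len(source))


class TestProcrustesAlign:
    def test_identity(self, template):
        aligned, tf, d = procrustes_align(template, template)
        assert d == pytest.approx(0.0, abs=1e-10)
        assert tf.scale == pytest.approx(1.0)
        assert np.allclose(tf.rotation, np.eye(2), atol=1e-12)

    def test_recovers_similarity_transform(self, template):
        tf_true = SimilarityTransform2D(30.0, 1.7, (5.0, -3.0))
        target = tf_true.apply(template)
        aligned, tf, d = procrustes_align(template, target)
        assert d < 1e-8
        assert tf.scale == pytest.approx(1.7, abs=1e-8)
        assert np.allclose(aligned, target, atol=1e-6)

    def test_never_reflects(self, template):
        mirrored = template * np.array([-1.0, 1.0])
        _, tf, d = procrustes_align(template, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        assert d > 1.0  # a reflection would give ~0; proper rotations cannot

    def test_distance_matches_numeric_minimisation(self, template, rng):
        target = template + rng.normal(0, 1.0, template.shape)
        _, _, d = procrustes_align(template, target)
        oracle = brute_force_procrustes_distance(template, target)
        assert d == pytest.approx(oracle, abs=1e-6)

    def test_collinear_source_rejected(self):
        line = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_align(line, line + 1.0)


class TestGeneralizedProcrustes:
    def test_copies_of_one_shape(self, template):
        g = generalized_procrustes([template] * 5)
        assert g.converged
        _, _, d = procrustes_align(g.mean_shape, template)
        assert d < 1e-9
        for a in g.aligned:
            assert np.allclose(a, g.mean_shape, atol=1e-9)

    def test_mean_recovery_under_similarity_noise(self, template, rng):
        shapes = []
        for _ in range(50):
            s = template + rng.normal(0, 2.0, template.shape)
            tf = SimilarityTransform2D(
                rng.uniform(-15, 15), rng.uniform(0.8, 1.25), tuple(rng.uniform(-20, 20, 2))
            )
            shapes.append(tf.apply(s))
        g = generalized_procrustes(shapes)
        aligned, _, _ = procrustes_align(g.mean_shape, template)
        rms = np.sqrt(((aligned - template) ** 2).sum(axis=1).mean())
        assert rms < 0.5

    def test_two_shape_mean_equidistant(self, template, rng):
        a = template + rng.normal(0, 2.0, template.shape)
        b = template + rng.normal(0, 2.0, template.shape)
        g = generalized_procrustes([a, b], tol=1e-12)
        _, _, da = procrustes_align(a, g.mean_shape)
        _, _, db = procrustes_align(b, g.mean_shape)
        assert da == pytest.approx(db, abs=1e-6)

    def test_mean_is_fixed_point(self, template, rng):
        shapes = [template + rng.normal(0, 2.0, template.shape) for _ in range(10)]
        g1 = generalized_procrustes(shapes)
        g2 = generalized_procrustes(g1.aligned)
        rms = np.sqrt(((g2.mean_shape - g1.mean_shape) ** 2).sum(axis=1).mean())
        assert rms < 1e-6

    def test_invariant_to_transforming_one_input(self, template, rng):
        shapes = [template + rng.normal(0, 2.0, template.shape) for _ in range(8)]
        g1 = generalized_procrustes(shapes)
        shapes[3] = SimilarityTransform2D(40.0, 2.0, (100.0, -50.0)).apply(shapes[3])
        g2 = generalized_procrustes(shapes)
        rms = np.sqrt(((g2.mean_shape - g1.mean_shape) ** 2).sum(axis=1).mean())
        assert rms < 1e-6

    def test_needs_two_shapes(self, template):
        with pytest.raises(ValueError):
            generalized_procrustes([template])


def circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    centre = np.array([ux, uy])
    return centre, np.linalg.norm(a - centre)


class TestDelaunayMesh:
    def test_three_points_one_triangle(self):
        mesh = delaunay_mesh([[0, 0], [1, 0], [0, 1]])
        assert mesh.triangles.shape == (1, 3)

    def test_unit_square_two_triangles(self):
        mesh = delaunay_mesh([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert mesh.triangles.shape == (2, 3)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            delaunay_mesh(pts)

    def test_empty_circumcircle_property_on_template(self, template):
        # exhaustive brute-force check over all (triangle, vertex) pairs
        mesh = delaunay_mesh(template)
        for tri in mesh.triangles:
            centre, radius = circumcircle(*template[tri])
            others = np.setdiff1d(np.arange(36), tri)
            dists = np.linalg.norm(template[others] - centre, axis=1)
            assert (dists >= radius - 1e-7).all()


class TestPiecewiseAffineWarp:
    def test_identity_warp(self, template):
        img = render_face(template, 256)
        mesh = delaunay_mesh(template)
        warped, mask = piecewise_affine_warp(img, template, mesh, output_shape=img.shape)
        interior = binary_erosion(mask, iterations=2)
        assert np.abs(warped - img)[interior].max() < 1e-6

    def test_pure_translation(self, template):
        img = render_face(template, 256)
        shift = np.array([10.0, 0.0])
        mesh = delaunay_mesh(template)
        # source landmarks shifted: output pixel p samples img at p + shift
        shifted_img = render_face(template + shift, 256)
        warped, mask = piecewise_affine_warp(shifted_img, template + shift, mesh, output_shape=img.shape)
        interior = binary_erosion(mask, iterations=2)
        assert np.abs(warped - img)[interior].max() < 1e-6

    def test_single_triangle_matches_affine_oracle(self):
        # on a linear-ramp image, bilinear sampling is exact, so the warp must
        # equal the closed-form affine map computed by a direct 2x3 solve
        tgt = np.array([[10.0, 10.0], [90.0, 20.0], [40.0, 90.0]])
        src = np.array([[20.0, 15.0], [80.0, 30.0], [30.0, 75.0]])
        a, b, c = 0.2, 0.005, 0.003
        yy, xx = np.mgrid[0:100, 0:100]
        img = a + b * xx + c * yy
        mesh = delaunay_mesh(tgt)
        warped, mask = piecewise_affine_warp(img, src, mesh, output_shape=(100, 100))
        # closed-form: solve [x', y'] = A @ [x, y, 1] from the 3 correspondences
        M = np.column_stack([tgt, np.ones(3)])
        A = np.linalg.solve(M, src)  # (3, 2)
        pix = np.column_stack([xx[mask], yy[mask], np.ones(mask.sum())])
        sxy = pix @ A
        expected = a + b * sxy[:, 0] + c * sxy[:, 1]
        assert np.abs(warped[mask] - expected).max() < 1e-9

    def test_degenerate_source_triangle_identified(self):
        tgt = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        src = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])  # collapsed
        mesh = delaunay_mesh(tgt)
        with pytest.raises(ValueError, match="degenerate source triangle"):
            piecewise_affine_warp(np.zeros((20, 20)), src, mesh)

    def test_intensity_range_preserved(self, template, rng):
        img = rng.uniform(0.2, 0.9, (256, 256))
        src = template + rng.normal(0, 3.0, template.shape)
        mesh = delaunay_mesh(template)
        warped, mask = piecewise_affine_warp(img, src, mesh, output_shape=img.shape)
        assert warped[mask].min() >= img.min() - 1e-12
        assert warped[mask].max() <= img.max() + 1e-12

    def test_matches_skimage_piecewise_affine(self, template):
        # independent cross-check against scikit-image's implementation,
        # compared away from triangle edges where triangulations may differ
        from skimage.transform import PiecewiseAffineTransform, warp

        img = render_face(template, 128, illumination=1.0)
        tpl = default_template(128)
        src = tpl + np.array([3.0, -2.0])
        mesh = delaunay_mesh(tpl)
        ours, mask = piecewise_affine_warp(img, src, mesh, output_shape=img.shape)
        tform = PiecewiseAffineTransform.from_estimate(tpl, src)
        theirs = warp(img, inverse_map=tform, output_shape=img.shape, order=1)
        interior = binary_erosion(mask, iterations=3)
        diff = np.abs(ours - theirs)[interior]
        assert np.median(diff) < 1e-9
        assert np.mean(diff) < 1e-3


class TestAverageAppearance:
    def test_copies_average_to_same_raster(self, rng):
        img = rng.uniform(size=(32, 32))
        mean, cov = average_appearance([img] * 4)
        assert np.allclose(mean, img)
        assert (cov == 4).all()

    def test_two_constant_rasters(self):
        mean, _ = average_appearance([np.zeros((8, 8)), np.full((8, 8), 100.0)])
        assert np.allclose(mean, 50.0)

    def test_masked_coverage(self):
        m1 = np.zeros((4, 4), dtype=bool)
        m1[:2] = True
        imgs = [np.ones((4, 4)), np.full((4, 4), 3.0)]
        mean, cov = average_appearance(imgs, [m1, np.ones((4, 4), bool)])
        assert mean[0, 0] == 2.0  # both cover
        assert mean[3, 0] == 3.0  # only second covers
        assert cov[0, 0] == 2 and cov[3, 0] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_appearance([])


def canonical_frame_constellation(size=256):
    """A constellation that is a fixed point of the GPA+placement frame."""
    tpl = default_template(size)
    m = _normalise(tpl)
    mc = m @ canonical_rotation(m).T
    return place_in_frame(mc, size)


class TestBuildAverageFace:
    def test_identical_faces_average_to_the_face(self):
        # with the constellation already in the canonical reference frame the
        # pipeline reduces to an identity warp, so the average IS the face
        C = canonical_frame_constellation(256)
        img = render_face(C, 256)
        avg = build_average_face([img, img], [C, C], size=256)
        interior = binary_erosion(avg.coverage == 2, iterations=2)
        assert np.abs(avg.appearance - img)[interior].max() < 1e-6
        assert np.allclose(avg.mean_constellation, C, atol=1e-6)

    def test_single_face_rejected(self, template):
        with pytest.raises(ValueError):
            build_average_face([np.zeros((64, 64))], [template])

    def test_group_separation_exceeds_within_group_noise(self):
        # groups generated with distinct landmark offsets yield average shapes
        # further apart than either group's mean is from a replicate of itself
        offset = np.zeros((36, 2))
        offset[13:19, 1] += 8.0
        offset[31:35, 1] -= 7.0
        cfg_a = FaceSimConfig(seed=11, landmark_noise_sd=2.0)
        cfg_a2 = FaceSimConfig(seed=12, landmark_noise_sd=2.0)
        cfg_b = FaceSimConfig(seed=13, landmark_noise_sd=2.0, group_offsets={"B": offset})
        fa = generate_faces(cfg_a, {"A": 16})
        fa2 = generate_faces(cfg_a2, {"A": 16})
        fb = generate_faces(cfg_b, {"B": 16})

        def mean_shape(faces):
            return generalized_procrustes([f.landmarks for f in faces]).mean_shape

        ma, ma2, mb = mean_shape(fa), mean_shape(fa2), mean_shape(fb)
        _, _, d_between = procrustes_align(ma, mb)
        _, _, d_within = procrustes_align(ma, ma2)
        assert d_between > 3 * d_within

    def test_mean_appearance_correlates_with_template_rendering(self):
        # 30 noisy faces: the average appearance must correlate strongly with
        # the zero-noise rendering on the canonical frame
        cfg = FaceSimConfig(seed=21, landmark_noise_sd=2.0, texture_jitter=0.05,
                            illumination_jitter=0.05, image_size=128,
                            template=default_template(128))
        faces = generate_faces(cfg, {"A": 30})
        avg = build_average_face([f.image for f in faces], [f.landmarks for f in faces], size=128)
        C = canonical_frame_constellation(128)
        reference = render_face(C, 128)
        interior = binary_erosion(avg.coverage == avg.n, iterations=2)
        r = np.corrcoef(avg.appearance[interior], reference[interior])[0, 1]
        assert r > 0.95

    def test_pipeline_invariant_to_global_similarity(self):
        # re-rendering every face from globally transformed landmarks must
        # leave the average appearance unchanged up to resampling error
        cfg = FaceSimConfig(seed=7, texture_jitter=0.0, illumination_jitter=0.0,
                            image_size=128, template=default_template(128),
                            landmark_noise_sd=2.0)
        faces = generate_faces(cfg, {"A": 5})
        avg1 = build_average_face([f.image for f in faces], [f.landmarks for f in faces], size=128)
        G = SimilarityTransform2D(6.0, 0.95, (4.0, -3.0), pivot=(64.0, 64.0))
        lms = [G.apply(f.landmarks) for f in faces]
        imgs = [render_face(lm, 128) for lm in lms]
        avg2 = build_average_face(imgs, lms, size=128)
        both = (avg1.coverage == avg1.n) & (avg2.coverage == avg2.n)
        interior = binary_erosion(both, iterations=3)
        diff = np.abs(avg1.appearance - avg2.appearance)[interior]
        assert diff.max() < 0.1  # bilinear resampling of the sharpest feature
        assert np.sqrt((diff**2).mean()) < 0.03
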