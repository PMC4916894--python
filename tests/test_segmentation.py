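"""Otsu thresholding, boundary tracing, GVF, and snake evolution."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

import laminafluct as lf
from laminafluct.contours import hausdorff_to_ellipse, point_to_ellipse_distances
from laminafluct.errors import DegenerateImageError, ParameterError
from laminafluct.segmentation import EdgeMap, _internal_matrix

from oracles import between_class_variance, otsu_bruteforce


def test_otsu_two_level_example():
    img = np.array([[1.0, 1, 1], [1, 9, 9]])
    thr, mask = lf.otsu_threshold(img)
    assert 1 < thr < 9
    assert mask.mask.sum() == 2
    assert mask.threshold == thr


def test_otsu_constant_image_rejected():
    with pytest.raises(DegenerateImageError):
        lf.otsu_threshold(np.full((4, 4), 3.0))


@pytest.mark.parametrize("trial", range(5))
def test_otsu_matches_exhaustive_variance_maximizer(trial):
    rng = np.random.default_rng(trial)
    vals = np.concatenate([
        rng.integers(0, 120, rng.integers(30, 150)),
        rng.integers(100, 256, rng.integers(30, 150)),
    ]).astype(float)
    thr, _ = lf.otsu_threshold(np.atleast_2d(vals))
    o_thr, _ = otsu_bruteforce(list(vals))
    v = between_class_variance(list(vals), thr)
    v_o = between_class_variance(list(vals), o_thr)
    assert v == pytest.approx(v_o, rel=1e-12)


def test_otsu_mask_area_matches_true_ellipse(noiseless_uniform):
    spec, stack, _ = noiseless_uniform
    dapi = lf.max_intensity_projection(stack, "counterstain")
    _, mask = lf.otsu_threshold(dapi)
    a, b = spec.semi_axes
    assert mask.mask.sum() == pytest.approx(np.pi * a * b, rel=0.05)


def test_initial_boundary_square_and_min_area():
    mask = np.zeros((9, 9), dtype=bool)
    mask[3:6, 3:6] = True
    (contour,) = lf.initial_boundary(mask, min_area=4, n_points=16)
    assert contour.n_points == 16
    assert contour.is_ccw()
    assert np.allclose(contour.points.mean(axis=0), [4.0, 4.0], atol=0.3)
    mask[0, 0] = True  # second blob below min_area
    assert len(lf.initial_boundary(mask, min_area=4, n_points=16)) == 1
    with pytest.raises(DegenerateImageError):
        lf.initial_boundary(np.zeros((5, 5), dtype=bool), min_area=1)


def test_initial_boundary_recovers_ellipse(noiseless_uniform):
    spec, _, _ = noiseless_uniform
    h, w = spec.image_size
    yy, xx = np.indices((h, w), dtype=float)
    cy, cx = spec.center
    a, b = spec.semi_axes
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    (contour,) = lf.initial_boundary(mask, min_area=100)
    d = point_to_ellipse_distances(contour.points, spec.center, spec.semi_axes, spec.orientation)
    assert d.mean() <= 1.0


def test_edge_map_constant_and_step():
    assert np.all(lf.edge_map(np.full((6, 6), 2.0)).data == 0)
    step = np.zeros((16, 16))
    step[:, 8:] = 1.0
    em = lf.edge_map(step, sigma=1.0, mode="gradient")
    assert em.data.max() == 1.0
    ridge_cols = em.data.argmax(axis=1)
    assert np.all((ridge_cols == 7) | (ridge_cols == 8))


def test_edge_map_ridge_mode_tracks_rim_centerline():
    """In ridge mode the edge-map crest along each normal sits on the rim centerline."""
    spec = lf.uniform_spec(noise=lf.NoiseModel.none(), psf_sigma=0.0, seed=0)
    stack, truth = lf.generate_nucleus_image(spec)
    em = lf.edge_map(stack.data[1, 0], sigma=1.0, mode="ridge")
    pts = truth.contour.points[::60]
    center = np.array(spec.center)
    offsets = np.arange(-3.0, 3.0001, 0.1)
    for p in pts:
        n = p - center
        n = n / np.hypot(*n)
        line = p[None, :] + offsets[:, None] * n[None, :]
        vals = map_coordinates(em.data, [line[:, 0], line[:, 1]], order=1)
        assert abs(offsets[np.argmax(vals)]) <= 1.0


def gvf_bruteforce(f, mu, dt, n_iter):
    """Independent GVF iteration with explicit neighbor indexing (nearest-edge padding)."""
    fy, fx = np.gradient(f)
    mag2 = fx**2 + fy**2
    u, v = fy.copy(), fx.copy()
    pad = lambda A: np.pad(A, 1, mode="edge")
    for _ in range(n_iter):
        out = []
        for comp, g in ((u, fy), (v, fx)):
            P = pad(comp)
            lap = P[:-2, 1:-1] + P[2:, 1:-1] + P[1:-1, :-2] + P[1:-1, 2:] - 4 * comp
            out.append(comp + dt * (mu * lap - mag2 * (comp - g)))
        u, v = out
    return u, v


def test_gvf_zero_input_zero_output_and_init():
    zero = EdgeMap(np.zeros((8, 8)), sigma=0)
    field = lf.compute_gvf(zero, n_iterations=25)
    assert np.all(field.gy == 0) and np.all(field.gx == 0)
    rng = np.random.default_rng(1)
    f = rng.random((8, 8))
    field0 = lf.compute_gvf(EdgeMap(f, 0), n_iterations=0)
    gy, gx = np.gradient(f)
    assert np.array_equal(field0.gy, gy) and np.array_equal(field0.gx, gx)


def test_gvf_matches_bruteforce_iteration_and_points_at_edge():
    f = np.zeros((12, 12))
    f[:, 6] = 1.0  # a vertical edge ridge
    field = lf.compute_gvf(EdgeMap(f, 0), mu=0.2, dt=1.0, n_iterations=10)
    u, v = gvf_bruteforce(f, 0.2, 1.0, 10)
    assert np.allclose(field.gy, u) and np.allclose(field.gx, v)
    # x-component points toward the ridge from both sides (skip pad-affected frame rows)
    assert np.all(field.gx[2:-2, 1:5] > 0)
    assert np.all(field.gx[2:-2, 8:11] < 0)


def test_gvf_initialization_linear_in_edge_gradient():
    # the field is initialized with the raw edge gradient, so before any
    # diffusion step it scales exactly with a scaled edge map
    rng = np.random.default_rng(2)
    f = rng.random((10, 10))
    one = lf.compute_gvf(EdgeMap(f, 0), n_iterations=0)
    three = lf.compute_gvf(EdgeMap(3 * f, 0), n_iterations=0)
    assert np.allclose(three.gx, 3 * one.gx)
    assert np.allclose(three.gy, 3 * one.gy)


def test_gvf_stability_guard():
    with pytest.raises(ParameterError):
        lf.compute_gvf(EdgeMap(np.zeros((4, 4)), 0), mu=1.0, dt=1.0)


def test_snake_zero_iterations_is_identity():
    contour = lf.NucleusContour(lf.ellipse_points((10, 10), (5, 4), 0, 20))
    field = lf.GVFField(np.zeros((21, 21)), np.zeros((21, 21)), 0.2, 1.0, 0)
    params = lf.SnakeParams(n_iterations=0)
    out = lf.evolve_snake(contour, field, params)
    assert np.array_equal(out.points, contour.points)


def test_snake_curve_shortening_without_external_force():
    """kappa=0, alpha>0, beta=0: each implicit step strictly shrinks the polygon."""
    rng = np.random.default_rng(3)
    pts = lf.ellipse_points((25, 25), (12, 8), 0.5, 10) + rng.normal(0, 0.5, (10, 2))
    field = lf.GVFField(np.zeros((50, 50)), np.zeros((50, 50)), 0.2, 1.0, 0)
    params = lf.SnakeParams(alpha=0.3, beta=0.0, gamma=1.0, kappa=0.0, n_iterations=1, resample_every=0)
    contour = lf.NucleusContour(pts)
    perims = [contour.perimeter()]
    for _ in range(8):
        contour = lf.evolve_snake(contour, field, params)
        perims.append(contour.perimeter())
    assert all(b < a for a, b in zip(perims, perims[1:]))


def test_snake_single_step_matches_direct_solve():
    """One semi-implicit step equals an independently assembled linear solve."""
    rng = np.random.default_rng(4)
    n = 12
    pts = lf.ellipse_points((20, 20), (8, 6), 0.2, n)
    gy = rng.normal(0, 0.1, (40, 40))
    gx = rng.normal(0, 0.1, (40, 40))
    field = lf.GVFField(gy, gx, 0.2, 1.0, 0)
    p = lf.SnakeParams(alpha=0.2, beta=0.7, gamma=1.3, kappa=0.9, n_iterations=1, resample_every=0)
    out = lf.evolve_snake(lf.NucleusContour(pts), field, p)
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = 2 * p.alpha + 6 * p.beta
        A[i, (i - 1) % n] += -(p.alpha + 4 * p.beta)
        A[i, (i + 1) % n] += -(p.alpha + 4 * p.beta)
        A[i, (i - 2) % n] += p.beta
        A[i, (i + 2) % n] += p.beta
    fy = map_coordinates(gy, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    fx = map_coordinates(gx, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
    y = np.linalg.solve(A + p.gamma * np.eye(n), p.gamma * pts[:, 0] + p.kappa * fy)
    x = np.linalg.solve(A + p.gamma * np.eye(n), p.gamma * pts[:, 1] + p.kappa * fx)
    assert np.allclose(out.points, np.column_stack([y, x]), atol=1e-9)


def test_snake_fixed_point_on_circular_ridge():
    """A circle initialized on a circular edge ridge stays put under the GVF force."""
    h = w = 64
    yy, xx = np.indices((h, w), dtype=float)
    r = np.hypot(yy - 32, xx - 32)
    ridge = np.exp(-0.5 * ((r - 20) / 2.0) ** 2)
    em = lf.edge_map(ridge, sigma=1.0, mode="ridge")
    gvf = lf.compute_gvf(em, n_iterations=40)
    circle = lf.NucleusContour(lf.ellipse_points((32, 32), (20, 20), 0, 60))
    params = lf.SnakeParams(alpha=0.0, beta=0.0, gamma=1.0, kappa=1.0, n_iterations=50, resample_every=0)
    out = lf.evolve_snake(circle, gvf, params)
    rms = np.sqrt(np.mean(np.sum((out.points - circle.points) ** 2, axis=1)))
    assert rms <= 0.5


def test_segment_nuclei_end_to_end(noiseless_uniform):
    spec, stack, _ = noiseless_uniform
    contours = lf.segment_nuclei(stack)
    assert len(contours) == 1
    c = contours[0]
    assert c.n_points == 200
    assert np.isfinite(c.points).all()
    assert c.is_ccw()
    d = point_to_ellipse_distances(c.points, spec.center, spec.semi_axes, spec.orientation)
    assert d.mean() <= 1.0
    assert hausdorff_to_ellipse(c, spec.center, spec.semi_axes, spec.orientation) <= 2.0


def test_segment_blank_image_warns_and_returns_empty():
    blank = lf.ImageStack(np.zeros((3, 1, 32, 32)), roles={"counterstain": 0, "reference": 1, "test": 2})
    with pytest.warns(UserWarning):
        assert lf.segment_nuclei(blank) == []
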