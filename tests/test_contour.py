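"""Unit vector field construction, endpoint heatmaps, field walking and
contour metrics, checked against closed forms and brute-force oracles."""

import numpy as np
import pytest

from sijkit.contour import (
    Heatmap,
    Polyline,
    VectorField2D,
    WalkParams,
    build_endpoint_heatmaps,
    build_target_uvf,
    closest_point_rms,
    distance_to_polyline,
    error_quantiles,
    gaussian_heatmap,
    nearest_vertex,
    resample_polyline,
    sample_field,
    suggest_sigma,
    walk_contour,
)
from conftest import random_open_polyline


# ------------------------------------------------------------------
# nearest_vertex
# ------------------------------------------------------------------


def test_nearest_vertex_examples():
    poly = Polyline([[5, 3], [5, 7]])
    assert nearest_vertex((9, 3), poly) == (0, 4.0)
    assert nearest_vertex((5, 7), poly) == (1, 0.0)
    # ties break toward the lowest index
    assert nearest_vertex((5, 5), poly)[0] == 0
    with pytest.raises(ValueError):
        nearest_vertex((0, 0), Polyline.absent())


def test_nearest_vertex_matches_brute_force(rng):
    poly = Polyline(rng.uniform(0, 20, (7, 2)))
    for p in rng.uniform(-5, 25, (50, 2)):
        idx, d = nearest_vertex(p, poly)
        dists = [np.linalg.norm(v - p) for v in poly.vertices]
        assert idx == int(np.argmin(dists))
        assert d == pytest.approx(min(dists))


# ------------------------------------------------------------------
# build_target_uvf
# ------------------------------------------------------------------


def test_uvf_points_to_nearest_vertex_off_contour():
    fld = build_target_uvf(Polyline([[5, 3], [5, 7]]), (12, 12))
    assert np.allclose([fld.ux[3, 9], fld.uy[3, 9]], [-1.0, 0.0])


def test_uvf_on_contour_points_to_next_vertex():
    fld = build_target_uvf(Polyline([[2, 2], [6, 2]]), (10, 10))
    assert np.allclose([fld.ux[2, 2], fld.uy[2, 2]], [1.0, 0.0])
    # past the last vertex the band reuses the final segment direction
    assert np.allclose([fld.ux[2, 6], fld.uy[2, 6]], [1.0, 0.0])


def test_uvf_matches_brute_force_and_unit_norm(rng):
    poly = Polyline(np.array([[3.0, 2.5], [8.0, 7.0], [12.0, 13.0]]))
    radius = 0.75
    fld = build_target_uvf(poly, (16, 16), on_contour_radius=radius)
    assert np.allclose(fld.norms(), 1.0, atol=1e-6)
    for y in range(16):
        for x in range(16):
            p = np.array([x, y], dtype=float)
            if distance_to_polyline(p[None], poly)[0] > radius:
                dists = np.linalg.norm(poly.vertices - p, axis=1)
                expect = poly.vertices[np.argmin(dists)] - p
                expect = expect / np.linalg.norm(expect)
                assert np.allclose([fld.ux[y, x], fld.uy[y, x]], expect, atol=1e-9)


def test_uvf_rejects_degenerate_polyline():
    with pytest.raises(ValueError):
        build_target_uvf(Polyline([[4, 4], [4, 4]]), (8, 8))


# ------------------------------------------------------------------
# endpoint heatmaps
# ------------------------------------------------------------------


def test_heatmap_peak_value_and_closed_form():
    poly = Polyline([[4, 4], [10, 12]])
    src, snk = build_endpoint_heatmaps(poly, (16, 16), sigma=2.0)
    assert src.value_at((4, 4)) == pytest.approx(1.0)
    assert src.values[4, 4] == pytest.approx(1.0)  # integer peak is on-grid
    assert src.value_at((6, 4)) == pytest.approx(np.exp(-0.5))
    assert snk.value_at((10, 12)) == pytest.approx(1.0)


def test_heatmaps_swap_under_reversal():
    poly = Polyline([[4, 4], [7, 8], [10, 12]])
    src, snk = build_endpoint_heatmaps(poly, (16, 16), sigma=2.0)
    rsrc, rsnk = build_endpoint_heatmaps(poly.reverse(), (16, 16), sigma=2.0)
    assert np.array_equal(src.values, rsnk.values)
    assert np.array_equal(snk.values, rsrc.values)


def test_heatmap_rejects_bad_sigma():
    with pytest.raises(ValueError):
        gaussian_heatmap((2, 2), (8, 8), sigma=0.0)


def test_suggest_sigma_rules():
    assert suggest_sigma(area=400.0, area_coeff=0.05) == pytest.approx(1.0)
    assert suggest_sigma(contour_length=40.0, length_coeff=0.05) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        suggest_sigma()


# ------------------------------------------------------------------
# sample_field
# ------------------------------------------------------------------


def test_sample_field_constant_and_nodes(rng):
    fld = VectorField2D(np.ones((8, 8)), np.zeros((8, 8)))
    assert np.allclose(sample_field(fld, (3.7, 2.2)), [1, 0])
    poly = random_open_polyline(rng, size=16)
    fld = build_target_uvf(poly, (16, 16))
    assert np.allclose(
        sample_field(fld, (5.0, 9.0)), [fld.ux[9, 5], fld.uy[9, 5]], atol=1e-12
    )


def test_sample_field_matches_bilinear_formula(rng):
    ux = rng.normal(size=(10, 10))
    uy = rng.normal(size=(10, 10))
    fld = VectorField2D(ux, uy)
    for _ in range(100):
        x, y = rng.uniform(0, 9, 2)
        x0, y0 = int(x), int(y)
        x0, y0 = min(x0, 8), min(y0, 8)
        fx, fy = x - x0, y - y0
        vx = (
            ux[y0, x0] * (1 - fx) * (1 - fy)
            + ux[y0, x0 + 1] * fx * (1 - fy)
            + ux[y0 + 1, x0] * (1 - fx) * fy
            + ux[y0 + 1, x0 + 1] * fx * fy
        )
        vy = (
            uy[y0, x0] * (1 - fx) * (1 - fy)
            + uy[y0, x0 + 1] * fx * (1 - fy)
            + uy[y0 + 1, x0] * (1 - fx) * fy
            + uy[y0 + 1, x0 + 1] * fx * fy
        )
        expect = np.array([vx, vy]) / np.hypot(vx, vy)
        assert np.allclose(sample_field(fld, (x, y)), expect, atol=1e-9)


def test_sample_field_errors():
    fld = VectorField2D(np.ones((4, 4)), np.zeros((4, 4)))
    with pytest.raises(ValueError):
        sample_field(fld, (5.0, 1.0))
    opp = VectorField2D(np.array([[1.0, -1.0]] * 2), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        sample_field(opp, (0.5, 0.5))


# ------------------------------------------------------------------
# walk_contour
# ------------------------------------------------------------------


def _straight_setup():
    fld = VectorField2D(np.ones((12, 12)), np.zeros((12, 12)))
    src = gaussian_heatmap((2, 5), (12, 12), sigma=0.8)
    snk = gaussian_heatmap((9, 5), (12, 12), sigma=0.8)
    return fld, src, snk


def test_walk_straight_line_field():
    fld, src, snk = _straight_setup()
    out = walk_contour(fld, src, snk, WalkParams(step_length=1.0))
    assert out.converged and not out.out_of_bounds
    expect = np.stack([np.arange(2.0, 10.0), np.full(8, 5.0)], axis=1)
    assert np.allclose(out.vertices, expect, atol=1e-9)


def test_walk_steps_have_unit_magnitude(rng):
    poly = random_open_polyline(rng)
    fld = build_target_uvf(poly, (64, 64))
    sigma = suggest_sigma(contour_length=poly.length(), length_coeff=0.05)
    src, snk = build_endpoint_heatmaps(poly, (64, 64), sigma)
    out = walk_contour(fld, src, snk)
    steps = np.linalg.norm(np.diff(out.vertices[:-1], axis=0), axis=1)
    assert np.allclose(steps, 1.0, atol=1e-9)


def test_walk_absent_when_source_below_threshold():
    fld, src, snk = _straight_setup()
    out = walk_contour(
        fld, Heatmap(src.values * 0.1, src.peak, src.sigma), snk, WalkParams()
    )
    assert not out.present


def test_walk_out_of_bounds_flag():
    fld = VectorField2D(np.ones((8, 8)), np.zeros((8, 8)))
    src = gaussian_heatmap((5, 4), (8, 8), sigma=1.0)
    snk = gaussian_heatmap((5, 0), (8, 8), sigma=0.5)  # unreachable going right
    out = walk_contour(fld, src, snk, WalkParams(stop_radius=0.25))
    assert out.out_of_bounds and not out.converged


def test_walk_recovers_known_curved_polyline(rng):
    wins = 0
    for _ in range(20):
        poly = random_open_polyline(rng, n_range=(10, 11))
        fld = build_target_uvf(poly, (64, 64))
        sigma = suggest_sigma(contour_length=poly.length(), length_coeff=0.05)
        src, snk = build_endpoint_heatmaps(poly, (64, 64), sigma)
        out = walk_contour(fld, src, snk)
        if out.present and len(out) > 1 and closest_point_rms(out, poly) < 1.0:
            wins += 1
    assert wins >= 18


def test_walk_reversed_polyline_gives_reversed_contour(rng):
    poly = random_open_polyline(rng, n_range=(8, 9))
    shape = (64, 64)
    sigma = suggest_sigma(contour_length=poly.length(), length_coeff=0.05)

    def walked(p):
        fld = build_target_uvf(p, shape)
        src, snk = build_endpoint_heatmaps(p, shape, sigma)
        return walk_contour(fld, src, snk)

    fwd, bwd = walked(poly), walked(poly.reverse())
    assert fwd.converged and bwd.converged
    # vertex sets match within 1 px Hausdorff distance
    from scipy.spatial import cKDTree

    d1, _ = cKDTree(bwd.vertices).query(fwd.vertices)
    d2, _ = cKDTree(fwd.vertices).query(bwd.vertices)
    # the first unit step away from an integer argmax start can sit
    # exactly 1 px from the opposite direction's vertex set
    assert max(d1.max(), d2.max()) <= 1.0 + 1e-9
    # and the endpoints swap
    assert np.linalg.norm(fwd.vertices[0] - bwd.vertices[-1]) < 2.0
    assert np.linalg.norm(fwd.vertices[-1] - bwd.vertices[0]) < 2.0


# ------------------------------------------------------------------
# closest_point_rms
# ------------------------------------------------------------------


def test_rms_identity_and_uniform_offset():
    line = Polyline(np.stack([np.linspace(0, 20, 50), np.zeros(50)], axis=1))
    assert closest_point_rms(line, line) == 0.0
    shifted = Polyline(line.vertices + [0.0, 2.0])
    assert closest_point_rms(shifted, line) == pytest.approx(2.0)
    assert closest_point_rms(shifted, line, spacing_mm=0.5) == pytest.approx(1.0)


def test_rms_matches_brute_force_and_reorder_invariance(rng):
    for _ in range(30):
        pred = Polyline(rng.uniform(0, 30, (int(rng.integers(2, 13)), 2)))
        gt = Polyline(rng.uniform(0, 30, (int(rng.integers(2, 13)), 2)))
        expect = np.sqrt(
            np.mean(
                [
                    min(np.sum((g - p) ** 2) for p in pred.vertices)
                    for g in gt.vertices
                ]
            )
        )
        assert closest_point_rms(pred, gt) == pytest.approx(expect)
        shuffled = Polyline(pred.vertices[rng.permutation(len(pred))])
        assert closest_point_rms(shuffled, gt) == pytest.approx(expect)


def test_rms_requires_present_polylines():
    line = Polyline([[0, 0], [1, 0]])
    with pytest.raises(ValueError):
        closest_point_rms(Polyline.absent(), line)
    with pytest.raises(ValueError):
        closest_point_rms(line, Polyline.absent())


# ------------------------------------------------------------------
# error_quantiles
# ------------------------------------------------------------------


def test_quantiles_examples_and_monotonicity(rng):
    errors = np.arange(1, 101, dtype=float)
    table = dict(error_quantiles(errors, [0.5, 1.0]))
    assert table[0.5] == pytest.approx(50.5)
    assert table[1.0] == pytest.approx(100.0)
    grid = [0.1, 0.3, 0.5, 0.7, 0.9, 0.95]
    sample = rng.exponential(2.0, 1000)
    got = error_quantiles(sample, grid)
    vals = [v for _, v in got]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    # independent sort-and-interpolate oracle
    s = np.sort(sample)
    for q, v in got:
        pos = (len(s) - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expect = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert v == pytest.approx(expect)


def test_quantiles_input_validation():
    with pytest.raises(ValueError):
        error_quantiles([], [0.5])
    with pytest.raises(ValueError):
        error_quantiles([1.0], [0.5, 0.3])
    with pytest.raises(ValueError):
        error_quantiles([1.0], [0.0, 0.5])


# ------------------------------------------------------------------
# resampling helper
# ------------------------------------------------------------------


def test_resample_polyline_preserves_endpoints_and_arclength_positions():
    poly = Polyline([[0, 0], [4, 0], [4, 3]])  # lengths 4 and 3
    res = resample_polyline(poly, 8)
    assert np.allclose(res.vertices[0], [0, 0])
    assert np.allclose(res.vertices[-1], [4, 3])
    # total length 7 -> uniform stations each 1 apart along the path
    stations = np.linspace(0, 7, 8)
    for t, v in zip(stations, res.vertices):
        if t <= 4:
            assert np.allclose(v, [t, 0.0])
        else:
            assert np.allclose(v, [4.0, t - 4.0])
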