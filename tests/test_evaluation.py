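"""Metrics, clinical parameter geometry, and group statistics.

Oracles: closed-form circumscribed circles, exhaustive permutation
enumeration for the rank test, direct sorted-interpolation quantiles.
"""

import itertools

import numpy as np
import pytest

from ssmrec.evaluation import (
    EXPECTED_REGIONS,
    LandmarkSet,
    acetabular_diameter,
    clinical_parameters,
    compare_parameters,
    distance_map,
    fit_circle_radius,
    mann_whitney_u,
    polyline_length,
    quadrilateral_slope,
    rmse,
    summarize,
)
from ssmrec.registration import CorrespondedShape


def random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(size=3) * 10


# -- RMSE / distance map ------------------------------------------------


def test_rmse_closed_forms():
    a = CorrespondedShape([[0, 0, 0]])
    b = CorrespondedShape([[3, 4, 0]])
    assert rmse(a, a) == 0.0
    assert rmse(a, b) == pytest.approx(5.0)
    a2 = CorrespondedShape([[0, 0, 0], [0, 0, 0]])
    b2 = CorrespondedShape([[1, 0, 0], [7, 0, 0]])
    assert rmse(a2, b2) == pytest.approx(5.0)  # sqrt((1+49)/2)
    assert rmse(a2, b2) == rmse(b2, a2)
    with pytest.raises(ValueError):
        rmse(a2, b2, indices=[])


def test_rmse_is_a_metric_on_random_triples(rng):
    for _ in range(25):
        x, y, z = (CorrespondedShape(rng.normal(size=(10, 3))) for _ in range(3))
        assert rmse(x, y) == pytest.approx(rmse(y, x))
        assert rmse(x, z) <= rmse(x, y) + rmse(y, z) + 1e-12
        assert rmse(x, x) == 0.0


def test_distance_map_consistency(rng):
    a = CorrespondedShape(rng.normal(size=(30, 3)))
    b = CorrespondedShape(a.coordinates + [2.0, 0.0, 0.0])
    dm = distance_map(a, b)
    np.testing.assert_allclose(dm.per_vertex_distance, 2.0)
    assert dm.rmse == pytest.approx(rmse(a, b))
    assert dm.max >= dm.rmse >= 0
    zero = distance_map(a, a)
    assert zero.max == 0.0


# -- polyline and circle fits -------------------------------------------


def test_polyline_lengths():
    assert polyline_length([[0, 0, 0], [3, 4, 0]]) == pytest.approx(5.0)
    square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
    assert polyline_length(square) == pytest.approx(3.0)
    assert polyline_length(square[::-1]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        polyline_length([[0, 0, 0]])


def test_circumscribed_circle_exact():
    assert fit_circle_radius([[0, 0, 0], [2, 0, 0], [1, 1, 0]]) == pytest.approx(1.0)


def test_tilted_circle_exact_fit(rng):
    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    pts = np.column_stack([40 * np.cos(theta), 40 * np.sin(theta), np.zeros(12)])
    R, t = random_rigid(rng)
    assert fit_circle_radius(pts @ R.T + t) == pytest.approx(40.0, abs=1e-6)


def test_circle_fit_noise_simulation(rng):
    errs = []
    for _ in range(200):
        theta = np.linspace(0.3, 2.2, 12)
        pts = np.column_stack([40 * np.cos(theta), 40 * np.sin(theta), np.zeros(12)])
        pts += rng.normal(scale=0.5, size=pts.shape)
        errs.append(abs(fit_circle_radius(pts) - 40.0))
    assert np.median(errs) < 2.0


def test_collinear_points_rejected():
    with pytest.raises(ValueError):
        fit_circle_radius([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])


def test_circle_fit_rigid_invariance(rng):
    theta = np.linspace(0.2, 2.8, 9)
    pts = np.column_stack([17 * np.cos(theta), 17 * np.sin(theta), np.zeros(9)])
    pts += rng.normal(scale=0.3, size=pts.shape)
    r0 = fit_circle_radius(pts)
    R, t = random_rigid(rng)
    assert fit_circle_radius(pts @ R.T + t) == pytest.approx(r0, abs=1e-9)


def test_acetabular_diameter_cases():
    theta = np.linspace(0, 2 * np.pi, 4, endpoint=False)
    pts = np.column_stack([25 * np.cos(theta), 25 * np.sin(theta), np.zeros(4)])
    assert acetabular_diameter(pts) == pytest.approx(50.0)
    s = 2.0
    square = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], dtype=float)
    assert acetabular_diameter(square) == pytest.approx(s * np.sqrt(2))
    perm = square[[2, 0, 3, 1]]
    assert acetabular_diameter(perm) == pytest.approx(acetabular_diameter(square))
    with pytest.raises(ValueError):
        acetabular_diameter(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float))


# -- slope --------------------------------------------------------------


def test_slope_reference_cases(rng):
    grid = np.array([[x, y, 0.0] for x in range(4) for y in range(3)])
    assert quadrilateral_slope(grid, [0, 0, 1]) == pytest.approx(0.0, abs=1e-9)
    a = np.deg2rad(45)
    tilted = grid @ np.array(
        [[np.cos(a), 0, -np.sin(a)], [0, 1, 0], [np.sin(a), 0, np.cos(a)]]
    ).T
    assert quadrilateral_slope(tilted, [0, 0, 1]) == pytest.approx(45.0, abs=1e-9)
    assert quadrilateral_slope(tilted, [0, 0, -1]) == pytest.approx(45.0, abs=1e-9)
    with pytest.raises(ValueError):
        quadrilateral_slope(np.array([[float(i), 0, 0] for i in range(12)]), [0, 0, 1])


# -- landmark sets and parameters ---------------------------------------


def test_landmark_set_validation(template_small):
    lm = template_small.landmarks
    assert sum(len(v) for v in lm.regions.values()) == 66
    for name, count in EXPECTED_REGIONS.items():
        assert len(lm.regions[name]) == count
    bad = {k: v.copy() for k, v in lm.regions.items()}
    bad["acetabular_diameter"] = bad["acetabular_diameter"][:3]
    with pytest.raises(ValueError):
        LandmarkSet(regions=bad)
    with pytest.raises(ValueError):
        LandmarkSet(regions={k: v for k, v in lm.regions.items() if k != "weight_bearing_dome"})


def test_landmark_json_roundtrip(tmp_path, template_small):
    lm = template_small.landmarks
    path = tmp_path / "lm.json"
    lm.to_json(path)
    back = LandmarkSet.from_json(path)
    for name in EXPECTED_REGIONS:
        np.testing.assert_array_equal(back.regions[name], lm.regions[name])
    np.testing.assert_allclose(back.reference_axis, lm.reference_axis)


def test_clinical_parameters_recover_constructed_truth(template_small):
    shape = CorrespondedShape(template_small.mesh.vertices)
    params = clinical_parameters(shape, template_small.landmarks)
    truth = template_small.true_parameters
    for key, value in params.as_dict().items():
        assert value == pytest.approx(truth.as_dict()[key], abs=1e-6), key


def test_clinical_parameters_deterministic_and_rigid_invariant(template_small, rng):
    shape = CorrespondedShape(template_small.mesh.vertices)
    lm = template_small.landmarks
    p1 = clinical_parameters(shape, lm)
    p2 = clinical_parameters(shape, lm)
    assert p1.as_dict() == p2.as_dict()
    R, t = random_rigid(rng)
    moved = CorrespondedShape(shape.coordinates @ R.T + t)
    p3 = clinical_parameters(moved, lm, reference_axis=R @ lm.reference_axis)
    for key, value in p3.as_dict().items():
        assert value == pytest.approx(p1.as_dict()[key], abs=1e-6), key


def test_compare_parameters(template_small):
    shape = CorrespondedShape(template_small.mesh.vertices)
    p = clinical_parameters(shape, template_small.landmarks)
    zeros = compare_parameters(p, p)
    assert all(v == 0.0 for v in zeros.values())
    import dataclasses

    q = dataclasses.replace(p, iliopectineal_length=p.iliopectineal_length - 3.0)
    d1 = compare_parameters(p, q)
    d2 = compare_parameters(q, p)
    assert d1["iliopectineal_length"] == pytest.approx(3.0)
    assert d1 == d2


# -- statistics ---------------------------------------------------------


def quantile_oracle(values, q):
    """Linear interpolation between order statistics (type-7)."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_summarize_cases_and_oracle(rng):
    s = summarize([1, 2, 3])
    assert s["median"] == 2.0
    same = summarize([5.0] * 7)
    assert same["q75"] - same["q25"] == 0.0
    for _ in range(20):
        vals = rng.normal(size=rng.integers(2, 21))
        s = summarize(vals)
        assert s["median"] == pytest.approx(quantile_oracle(vals, 0.5))
        assert s["q25"] == pytest.approx(quantile_oracle(vals, 0.25))
        assert s["q75"] == pytest.approx(quantile_oracle(vals, 0.75))
    with pytest.raises(ValueError):
        summarize([])


def mann_whitney_oracle(a, b):
    """Exhaustive permutation two-sided p for the U statistic (no ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)
    mu = na * len(b) / 2.0

    def u_stat(group_a, group_b):
        return sum((x > y) + 0.5 * (x == y) for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def test_mann_whitney_exact_small_case():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_mann_whitney_identical_groups():
    _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_mann_whitney_matches_permutation_oracle(rng):
    for na in range(1, 7):
        for nb in range(1, 7):
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 0.5
            u, p = mann_whitney_u(a, b)
            u_oracle, p_oracle = mann_whitney_oracle(a, b)
            assert u == pytest.approx(u_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-9)


def test_mann_whitney_empty_group():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])
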