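"""Elliptic Fourier descriptor unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from helpers import square_contour
from otomorph.efd import (
    Contour,
    EFDCoefficients,
    compute_efd,
    mirror_contour,
    normalize_efd,
    power_spectrum,
    reconstruct_contour,
    resample_contour,
    select_harmonics,
)
from otomorph.efd import _unmirror_contour
from otomorph.synthdata import ContourParams, generate_contour


def _rotate(points, deg):
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ R.T


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def test_circle_is_pure_first_harmonic(circle_contour):
    e = compute_efd(circle_contour, 2)
    a1, b1, c1, d1 = e.coeffs[0]
    assert a1 == pytest.approx(1.0, abs=1e-6)
    assert d1 == pytest.approx(1.0, abs=1e-6)
    assert abs(b1) < 1e-6 and abs(c1) < 1e-6
    assert np.all(np.abs(e.coeffs[1]) < 1e-6)
    assert abs(e.a0) < 1e-6 and abs(e.c0) < 1e-6


def test_ellipse_closed_form_uniform_parametrization(ellipse_contour):
    # sampled at equal generating angles, so the analytical coefficients
    # apply in the uniform (per-sample) parametrization
    e = compute_efd(ellipse_contour, 2, parametrization="uniform")
    assert e.coeffs[0, 0] == pytest.approx(2.0, abs=1e-6)
    assert e.coeffs[0, 3] == pytest.approx(1.0, abs=1e-6)
    assert abs(e.coeffs[0, 1]) < 1e-6 and abs(e.coeffs[0, 2]) < 1e-6


def test_square_matches_dense_quadrature_oracle():
    # exact Fourier integrals of the polygon vs. brute-force quadrature on a
    # very fine arc-length grid
    sq = square_contour(100)
    N = 8
    e = compute_efd(sq, N)
    M = 400_000
    s = (np.arange(M) + 0.5) * 4.0 / M  # perimeter 4, midpoint rule
    closed = np.vstack([sq.points, sq.points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    knots = np.concatenate([[0.0], np.cumsum(seg)])
    x = np.interp(s, knots, closed[:, 0])
    y = np.interp(s, knots, closed[:, 1])
    for n in range(1, N + 1):
        cosn = np.cos(2.0 * np.pi * n * s / 4.0)
        sinn = np.sin(2.0 * np.pi * n * s / 4.0)
        w = 2.0 / M
        assert e.coeffs[n - 1, 0] == pytest.approx(np.sum(x * cosn) * w, abs=1e-6)
        assert e.coeffs[n - 1, 1] == pytest.approx(np.sum(x * sinn) * w, abs=1e-6)
        assert e.coeffs[n - 1, 2] == pytest.approx(np.sum(y * cosn) * w, abs=1e-6)
        assert e.coeffs[n - 1, 3] == pytest.approx(np.sum(y * sinn) * w, abs=1e-6)


# ---------------------------------------------------------------------------
# normalization invariances
# ---------------------------------------------------------------------------


def test_normalization_invariances(notched_contour):
    base = normalize_efd(compute_efd(notched_contour, 10)).coeffs
    pts = notched_contour.points

    rotated = Contour(points=_rotate(pts, 37.0))
    got = normalize_efd(compute_efd(rotated, 10)).coeffs
    assert np.abs(got - base).max() < 1e-8

    scaled = Contour(points=2.5 * pts)
    got = normalize_efd(compute_efd(scaled, 10)).coeffs
    assert np.abs(got - base).max() < 1e-9

    translated = Contour(points=pts + np.array([123.0, -45.0]))
    got = normalize_efd(compute_efd(translated, 10)).coeffs
    assert np.abs(got - base).max() < 1e-9

    shifted = Contour(points=np.roll(pts, 40, axis=0))
    got = normalize_efd(compute_efd(shifted, 10)).coeffs
    assert np.abs(got - base).max() < 1e-6


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    h=hst.floats(0.5, 1.5),
    d=hst.floats(0.0, 0.5),
    t0=hst.floats(0.0, 2.0 * np.pi),
    angle=hst.floats(0.0, 360.0),
    scale=hst.floats(0.1, 10.0),
    shift=hst.integers(0, 255),
)
def test_normalized_efd_similarity_invariance_property(h, d, t0, angle, scale, shift):
    """Normalized coefficients are invariant under any similarity transform
    plus starting-point shift, for arbitrary outline-model shapes."""
    c = generate_contour(ContourParams(s=1.0, h=h, d=d, t0=t0, w=0.4, K=256))
    base = normalize_efd(compute_efd(c, 8)).coeffs
    pts = scale * _rotate(np.roll(c.points, shift, axis=0), angle) + np.array([3.0, -7.0])
    got = normalize_efd(compute_efd(Contour(points=pts), 8)).coeffs
    assert np.abs(got - base).max() < 1e-6


def test_normalized_first_harmonic_is_canonical(notched_contour):
    e = normalize_efd(compute_efd(notched_contour, 6))
    assert e.coeffs[0, 0] == 1.0
    assert e.coeffs[0, 1] == 0.0 and e.coeffs[0, 2] == 0.0
    assert e.normalized


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------


def test_mirror_involution_and_guard(notched_contour):
    right = Contour(points=notched_contour.points.copy(), side="right")
    mirrored = mirror_contour(right)
    assert mirrored.side == "left"
    back = _unmirror_contour(mirrored)
    assert np.abs(back.points - right.points).max() < 1e-12
    with pytest.raises(ValueError, match="side"):
        mirror_contour(mirrored)


def test_mirrored_symmetric_shape_has_identical_efd(ellipse_contour):
    right = Contour(points=ellipse_contour.points.copy(), side="right")
    a = normalize_efd(compute_efd(mirror_contour(right), 8)).coeffs
    b = normalize_efd(compute_efd(ellipse_contour, 8)).coeffs
    assert np.abs(a - b).max() < 1e-9


def test_mirrored_notch_equals_reflected_parameters():
    """Mirroring a notched outline is the same shape as regenerating it with
    the notch at the reflected angular position (t0 -> pi - t0)."""
    t0 = 2.2
    c = generate_contour(ContourParams(s=1.0, h=0.8, d=0.25, t0=t0, w=0.3, K=512))
    mirrored = mirror_contour(Contour(points=c.points, side="right"))
    reflected = generate_contour(
        ContourParams(s=1.0, h=0.8, d=0.25, t0=np.pi - t0, w=0.3, K=512)
    )
    a = normalize_efd(compute_efd(mirrored, 10)).coeffs
    b = normalize_efd(compute_efd(reflected, 10)).coeffs
    assert np.abs(a - b).max() < 1e-6


def test_mirror_commutes_with_reconstruction(notched_contour):
    right = Contour(points=notched_contour.points.copy(), side="right")
    rec_of_mirror = reconstruct_contour(compute_efd(mirror_contour(right), 12), 512).points
    rec = reconstruct_contour(compute_efd(notched_contour, 12), 512).points
    cx = notched_contour.points[:, 0].mean()  # the mirroring axis
    reflected = rec.copy()
    reflected[:, 0] = 2.0 * cx - reflected[:, 0]
    # same point set up to traversal bookkeeping: directed Hausdorff distance
    d2 = ((rec_of_mirror[:, None, :] - reflected[None, :, :]) ** 2).sum(-1)
    assert np.sqrt(d2.min(axis=1).max()) < 1e-3


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resample_circle_and_idempotence(circle_contour):
    res = resample_contour(circle_contour, 64)
    radii = np.hypot(res.points[:, 0], res.points[:, 1])
    assert np.abs(radii - radii[0]).max() < 1e-6
    again = resample_contour(res, 64)
    assert np.abs(again.points - res.points).max() < 1e-9
    assert abs(res.perimeter() - circle_contour.perimeter()) < 1e-3 * circle_contour.perimeter()


def test_resample_square_side_counts():
    sq = square_contour(57)  # uneven original spacing across sides
    res = resample_contour(sq, 400)
    pts = res.points
    eps = 1e-9
    sides = {
        "bottom": np.abs(pts[:, 1]) < eps,
        "right": np.abs(pts[:, 0] - 1.0) < eps,
        "top": np.abs(pts[:, 1] - 1.0) < eps,
        "left": np.abs(pts[:, 0]) < eps,
    }
    for name, mask in sides.items():
        # corners belong to two sides; allow the +/-1 bookkeeping margin
        assert 99 <= mask.sum() <= 101, name


def test_resample_rejects_degenerate_inputs(circle_contour):
    with pytest.raises(ValueError, match=">= 32"):
        resample_contour(circle_contour, 16)


# ---------------------------------------------------------------------------
# power spectrum and harmonic selection
# ---------------------------------------------------------------------------


def test_power_spectrum_ellipse(ellipse_contour):
    e = compute_efd(ellipse_contour, 5, parametrization="uniform")
    sp = power_spectrum(e)
    assert sp.power[0] == pytest.approx(2.5, abs=1e-6)  # (4 + 1) / 2
    assert sp.cumulative[0] == pytest.approx(1.0, abs=1e-6)
    assert sp.cumulative[-1] == 1.0
    assert np.all(np.diff(sp.cumulative) >= -1e-15)


def test_power_spectrum_matches_direct_formula(notched_contour):
    e = compute_efd(notched_contour, 12)
    sp = power_spectrum(e)
    direct = np.array([(a * a + b * b + c * c + d * d) / 2.0 for a, b, c, d in e.coeffs])
    assert np.abs(sp.power - direct).max() < 1e-12
    assert np.abs(sp.cumulative - np.cumsum(direct) / direct.sum()).max() < 1e-12


def test_select_harmonics_rules(ellipse_contour, notched_contour):
    sp_ell = power_spectrum(compute_efd(ellipse_contour, 8, parametrization="uniform"))
    assert select_harmonics(sp_ell, 0.99999) == 1
    assert select_harmonics(sp_ell, 0.0) == 1

    sp = power_spectrum(compute_efd(notched_contour, 40))
    n_sel = select_harmonics(sp, 0.99999)
    # independent cumulative-sum oracle
    frac = np.cumsum(sp.power) / sp.power.sum()
    oracle = int(np.argmax(frac >= 0.99999)) + 1
    assert n_sel == oracle
    assert 1 < n_sel < 40

    with pytest.raises(ValueError, match="higher maximum harmonic"):
        select_harmonics(power_spectrum(compute_efd(notched_contour, 3)), 1.0)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def test_reconstruct_circle_roundtrip(circle_contour):
    rec = reconstruct_contour(compute_efd(circle_contour, 1), 256)
    radii = np.hypot(rec.points[:, 0], rec.points[:, 1])
    assert np.abs(radii - 1.0).max() < 1e-6


def test_square_reconstruction_error_nonincreasing():
    sq = square_contour(100)
    errors = []
    for N in (1, 2, 4, 8, 16):
        rec = reconstruct_contour(compute_efd(sq, N), sq.n_points).points
        errors.append(np.sqrt(((rec - sq.points) ** 2).sum(axis=1).mean()))
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))


def test_reconstruction_at_selected_harmonics_is_tight(notched_contour):
    c = resample_contour(notched_contour, 512)
    sp = power_spectrum(compute_efd(c, 60))
    n_sel = select_harmonics(sp, 0.99999)
    rec = reconstruct_contour(compute_efd(c, n_sel), 512).points
    rms = np.sqrt(((rec - c.points) ** 2).sum(axis=1).mean())
    mean_radius = np.hypot(*(c.points - c.centroid()).T).mean()
    assert rms <= 0.005 * mean_radius


def test_parseval_consistency_roundtrip(notched_contour):
    """Spectrum is preserved by reconstruct-then-decompose (same parameter)."""
    e = compute_efd(notched_contour, 10, parametrization="uniform")
    rec = reconstruct_contour(e, 32768)
    e2 = compute_efd(rec, 10, parametrization="uniform")
    sp1 = power_spectrum(e)
    sp2 = power_spectrum(e2)
    assert np.abs(sp1.power - sp2.power).max() < 1e-6


# ---------------------------------------------------------------------------
# error paths
# ---------------------------------------------------------------------------


def test_error_paths(circle_contour):
    with pytest.raises(ValueError, match="alias"):
        compute_efd(circle_contour, circle_contour.n_points)
    with pytest.raises(ValueError, match=">= 32"):
        Contour(points=np.random.default_rng(0).normal(size=(10, 2)))
    with pytest.raises(ValueError, match="duplicate"):
        pts = circle_contour.points.copy()
        pts[5] = pts[4]
        Contour(points=pts)
    with pytest.raises(ValueError, match="all-zero"):
        power_spectrum(EFDCoefficients(coeffs=np.zeros((3, 4))))
    with pytest.raises(ValueError, match="already normalized"):
        e = normalize_efd(compute_efd(circle_contour, 2))
        normalize_efd(e)
    with pytest.raises(ValueError, match=">= 32"):
        reconstruct_contour(compute_efd(circle_contour, 2), 8)
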