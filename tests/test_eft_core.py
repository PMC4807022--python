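"""Elliptic Fourier core: forward transform against a quadrature oracle,
normalization invariances, inverse reconstruction, mean shapes."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedmorph.eft_core import (
    EFTCoefficients,
    eft_forward,
    eft_inverse,
    harmonic_power_profile,
    mean_outline,
    normalize,
    retained_vector,
)

from conftest import smooth_outline


def quadrature_eft(points, n_harmonics, oversample=400):
    """Independent oracle: direct trapezoid Fourier integrals of the
    piecewise-linear arclength parameterization of the polygon."""
    pts = np.asarray(points, float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]
    # dense sampling of the chain parameterization
    td = np.linspace(0.0, T, oversample * len(pts), endpoint=False)
    xd = np.interp(td, t, closed[:, 0])
    yd = np.interp(td, t, closed[:, 1])
    out = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        c = np.cos(2 * np.pi * n * td / T)
        s = np.sin(2 * np.pi * n * td / T)
        out[n - 1] = [
            2 * np.mean(xd * c), 2 * np.mean(xd * s),
            2 * np.mean(yd * c), 2 * np.mean(yd * s),
        ]
    return out


def test_forward_matches_quadrature_oracle(rng):
    pts = smooth_outline(rng)
    got = eft_forward(pts, 8).harmonics
    want = quadrature_eft(pts, 8)
    assert np.abs(got - want).max() < 1e-6


def test_circle_first_harmonic(rng):
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    c = eft_forward(np.column_stack([np.cos(t), np.sin(t)]), 8)
    assert np.allclose(c.harmonics[0], [1, 0, 0, 1], atol=1e-4)
    p = c.power()
    assert p[1:].max() < 1e-12 * p[0]


def test_ellipse_first_harmonic_and_leakage():
    # under the chain (arclength) parameterization an elongated ellipse is
    # only approximately a pure first harmonic; leakage stays below 1%
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    c = eft_forward(np.column_stack([2 * np.cos(t), np.sin(t)]), 8)
    A1, B1, C1, D1 = c.harmonics[0]
    assert A1 == pytest.approx(2.0, rel=0.1)
    assert D1 == pytest.approx(1.0, rel=0.1)
    assert abs(B1) < 1e-10 and abs(C1) < 1e-10
    p = c.power()
    assert p[1:].sum() < 0.01 * p[0]


def test_forward_offset_recovers_centroid_position(rng):
    pts = smooth_outline(rng) + np.array([3.0, -2.0])
    c = eft_forward(pts, 16)
    rec = eft_inverse(c, 512)
    assert np.abs(rec.mean(axis=0) - pts.mean(axis=0)).max() < 0.05


@pytest.mark.parametrize("shift", [0, 17, 40])
@pytest.mark.parametrize("angle_deg", [0.0, 73.0, 191.0])
def test_normalization_invariance(rng, shift, angle_deg):
    pts = smooth_outline(rng)
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = (np.roll(pts, shift, axis=0) @ R.T) * 2.5 + np.array([5.0, -3.0])
    n0 = normalize(eft_forward(pts, 10)).harmonics
    n1 = normalize(eft_forward(moved, 10)).harmonics
    assert np.abs(n0 - n1).max() < 1e-6


_BASE_SHAPE = smooth_outline(np.random.default_rng(77), n_points=80)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 10.0),
    angle=st.floats(0.0, 2 * np.pi),
    dx=st.floats(-5.0, 5.0),
    shift=st.integers(0, 79),
)
def test_similarity_invariance_property(scale, angle, dx, shift):
    """Normalized coefficients are a similarity invariant of the outline."""
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    moved = (np.roll(_BASE_SHAPE, shift, axis=0) @ R.T) * scale + np.array([dx, 1.0])
    n0 = normalize(eft_forward(_BASE_SHAPE, 9)).harmonics
    n1 = normalize(eft_forward(moved, 9)).harmonics
    assert np.abs(n0 - n1).max() < 1e-6


def test_normalized_first_harmonic_canonical(rng):
    pts = smooth_outline(rng, aspect=1.8)
    n = normalize(eft_forward(pts, 10))
    A1, B1, C1, D1 = n.harmonics[0]
    assert A1 == pytest.approx(1.0, abs=1e-9)
    assert abs(B1) < 1e-6 and abs(C1) < 1e-6
    assert abs(D1) < 1.0  # residual aspect of the first ellipse


def test_mirror_image_preserves_power_flips_signs(rng):
    pts = smooth_outline(rng)
    mirrored = (pts * np.array([1.0, -1.0]))[::-1]  # keep counterclockwise
    n0 = normalize(eft_forward(pts, 10))
    n1 = normalize(eft_forward(mirrored, 10))
    assert np.allclose(np.sort(n0.power()), np.sort(n1.power()), rtol=1e-6, atol=1e-12)
    assert not np.allclose(n0.harmonics, n1.harmonics, atol=1e-8) or np.allclose(
        pts, (pts * [1, -1])[::-1]
    )


def test_normalize_rejects_double_normalization_and_zero_power():
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    c = eft_forward(np.column_stack([np.cos(t), np.sin(t)]), 5)
    n = normalize(c)
    with pytest.raises(ValueError):
        normalize(n)
    with pytest.raises(ValueError):
        normalize(EFTCoefficients(harmonics=np.zeros((3, 4))))


def test_retained_vector_layout(rng):
    pts = smooth_outline(rng)
    nd = normalize(eft_forward(pts, 10))
    vec = retained_vector(nd, nd)
    assert vec.shape == (64,)
    assert np.array_equal(vec[:32], vec[32:])
    assert np.array_equal(vec[:4], nd.harmonics[1])  # A2 B2 C2 D2 first
    with pytest.raises(ValueError):
        retained_vector(eft_forward(pts, 10), nd)


def test_ellipse_retained_vector_near_zero():
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    n = normalize(eft_forward(np.column_stack([1.2 * np.cos(t), np.sin(t)]), 10))
    assert np.abs(retained_vector(n, n)).max() < 0.03


def test_roundtrip_error_below_one_percent(rng):
    pts = smooth_outline(rng, n_points=64)
    c = eft_forward(pts, 32)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    phases = 2 * np.pi * np.concatenate([[0.0], np.cumsum(seg)])[:-1] / seg.sum()
    rec = eft_inverse(c, None, t=phases)
    length = pts[:, 0].max() - pts[:, 0].min()
    assert np.abs(rec - pts).max() < 0.01 * length


def test_truncation_error_monotone(rng):
    pts = smooth_outline(rng, n_points=64, n_extra=6)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    phases = 2 * np.pi * np.concatenate([[0.0], np.cumsum(seg)])[:-1] / seg.sum()
    full = eft_forward(pts, 32)
    errs = []
    for h in (2, 4, 8, 16, 32):
        c = EFTCoefficients(harmonics=full.harmonics[:h], offset=full.offset)
        errs.append(np.abs(eft_inverse(c, None, t=phases) - pts).max())
    assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


def test_inverse_of_pure_ellipse_exact():
    c = EFTCoefficients(harmonics=np.array([[2.0, 0.0, 0.0, 1.0]]))
    pts = eft_inverse(c, 100)
    t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    assert np.allclose(pts, np.column_stack([2 * np.cos(t), np.sin(t)]), atol=1e-12)
    with pytest.raises(ValueError):
        eft_inverse(c, 2)


def test_parameter_validation(rng):
    pts = smooth_outline(rng, n_points=20)
    with pytest.raises(ValueError):
        eft_forward(pts, 11)  # > floor(points/2)
    bad = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0.5, 1.5], [0, 1]], float)
    ok = eft_forward(bad, 2)  # duplicate vertex removed automatically
    assert ok.n_harmonics == 2
    with pytest.raises(ValueError):
        eft_forward(np.array([[0, 0], [0, 0], [1e-9, 0]]), 1)


def test_mean_outline_idempotent_and_linear(rng):
    vec = rng.normal(0, 0.02, 64)
    d1, l1 = mean_outline([vec, vec, vec], n_points=64)
    d2, l2 = mean_outline([vec], n_points=64)
    assert np.allclose(d1, d2) and np.allclose(l1, l2)
    # linearity: mean of reconstructions == reconstruction of mean
    vecs = rng.normal(0, 0.02, (5, 64))
    dm, lm = mean_outline(vecs, n_points=64)
    singles = [mean_outline([v], n_points=64) for v in vecs]
    assert np.abs(np.mean([s[0] for s in singles], axis=0) - dm).max() < 1e-6
    assert np.abs(np.mean([s[1] for s in singles], axis=0) - lm).max() < 1e-6
    with pytest.raises(ValueError):
        mean_outline([], n_points=64)


def test_mean_outline_of_mirror_pair_symmetric(rng):
    v = rng.normal(0, 0.02, 64)
    mirror = v.copy()
    # reflection about the x axis: C and D rows of x stay, y-coefficients flip
    mirror.reshape(16, 4)[:, 2:] *= -1
    d, _ = mean_outline([v, mirror], n_points=256)
    ys = np.sort(np.round(d[:, 1], 9))
    assert abs(ys + ys[::-1]).max() < 1e-6  # bilaterally symmetric about y=0


def test_power_profile_matches_direct_sum(rng):
    h = rng.normal(size=(9, 4))
    c = EFTCoefficients(harmonics=h)
    p, frac = harmonic_power_profile(c)
    direct = 0.5 * (h**2).sum(axis=1)
    assert np.allclose(p, direct, rtol=1e-12)
    assert np.all(np.diff(frac) >= -1e-15) and frac[-1] == pytest.approx(1.0)
    # a pure ellipse concentrates all power in the first harmonic
    _, f_ell = harmonic_power_profile(EFTCoefficients(harmonics=np.array([[2.0, 0, 0, 1.0], [0, 0, 0, 0]])))
    assert f_ell[0] == pytest.approx(1.0)
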