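"""Elliptic Fourier analysis of closed outlines.

A closed outline sampled at points ``(x_p, y_p)`` is decomposed into
harmonically related ellipses following the chain formulation of Kuhl &
Giardina: the increments ``dx, dy`` along the polygon are expanded in a
Fourier series of the cumulative arclength ``t`` with period ``T`` (the
perimeter).  Each harmonic ``n`` contributes four coefficients ``A_n, B_n``
(for x) and ``C_n, D_n`` (for y).

The first harmonic is the best-fitting ellipse of the outline and carries
(almost) all size and orientation information; :func:`normalize` removes
size, orientation and starting-point phase using that ellipse, after which
the higher harmonics describe pure shape.  The shape feature vector used in
the downstream statistics concatenates harmonics 2..9 of the dorsal and
lateral views (64 numbers per seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EFTCoefficients",
    "eft_forward",
    "normalize",
    "retained_vector",
    "eft_inverse",
    "mean_outline",
    "harmonic_power_profile",
    "RETAINED_HARMONICS",
]

#: Harmonics kept for the shape feature vector (the first harmonic is
#: consumed by the normalization and excluded).
RETAINED_HARMONICS = range(2, 10)


class DegenerateOutlineError(ValueError):
    """Outline has too few points or zero-length edges after cleaning."""


@dataclass(frozen=True)
class EFTCoefficients:
    """Elliptic Fourier coefficient set for one outline.

    Parameters
    ----------
    harmonics : ndarray, shape (H, 4)
        Rows are ``(A_n, B_n, C_n, D_n)`` for ``n = 1..H``.
    offset : tuple of float
        Centroid terms ``(A0_x, A0_y)``; discarded by normalization.
    normalized : bool
        True once size/orientation/phase have been removed.
    view : str or None
        "dorsal" or "lateral" when known.
    """

    harmonics: np.ndarray
    offset: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False
    view: str | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (H, 4) array")
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def power(self) -> np.ndarray:
        """Per-harmonic power ``P_n = (A_n²+B_n²+C_n²+D_n²)/2``."""
        return 0.5 * np.sum(self.harmonics**2, axis=1)


def _closed_increments(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    # drop an explicit closing vertex and any zero-length edges
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    if not np.all(keep):
        pts = pts[keep]
        if len(pts) < 3:
            raise DegenerateOutlineError("outline degenerate after removing zero-length edges")
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        dt = np.hypot(d[:, 0], d[:, 1])
        if np.any(dt <= 0):
            raise DegenerateOutlineError("outline contains coincident points")
    return pts, d, dt


def eft_forward(outline, n_harmonics: int) -> EFTCoefficients:
    """Forward elliptic Fourier transform of a closed outline.

    ``outline`` may be an :class:`~seedmorph.outline_ops.Outline` or a bare
    ``(N, 2)`` point array.  Closure is implicit (last vertex connects back
    to the first).
    """
    points = getattr(outline, "points", outline)
    view = getattr(outline, "view", None)
    pts, d, dt = _closed_increments(points)
    n_pts = len(pts)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics > n_pts // 2:
        raise ValueError(
            f"n_harmonics={n_harmonics} exceeds floor(points/2)={n_pts // 2}"
        )
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T  # length n_pts + 1
    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (H, P)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    A = const * (dcos @ vx)
    B = const * (dsin @ vx)
    C = const * (dcos @ vy)
    D = const * (dsin @ vy)

    # DC (centroid) terms, Kuhl & Giardina A0/C0
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - vx * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - vy * t[:-1]
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    a0 = pts[0, 0] + (1.0 / T) * np.sum(0.5 * vx * dt2 + xi * dt)
    c0 = pts[0, 1] + (1.0 / T) * np.sum(0.5 * vy * dt2 + delta * dt)

    return EFTCoefficients(
        harmonics=np.column_stack([A, B, C, D]),
        offset=(float(a0), float(c0)),
        normalized=False,
        view=view,
    )


def _rotate_phase(h: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point: harmonic n right-multiplied by R(n*theta)."""
    out = np.empty_like(h)
    for i in range(h.shape[0]):
        n = i + 1
        c, s = np.cos(n * theta), np.sin(n * theta)
        m = h[i].reshape(2, 2) @ np.array([[c, -s], [s, c]])
        out[i] = m.ravel()
    return out


def _rotate_space(h: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the outline in the plane: left-multiply by R(-psi)."""
    c, s = np.cos(psi), np.sin(psi)
    rot = np.array([[c, s], [-s, c]])
    out = np.empty_like(h)
    for i in range(h.shape[0]):
        out[i] = (rot @ h[i].reshape(2, 2)).ravel()
    return out


def normalize(coeffs: EFTCoefficients) -> EFTCoefficients:
    """Remove size, orientation and starting-point phase via the first
    harmonic (the best-fitting ellipse).

    After normalization ``A1 = 1`` and ``B1 = C1 = 0``; ``D1`` holds the
    residual aspect ratio of the first ellipse.  The starting-point phase is
    only defined modulo 180 degrees by the first ellipse; the two solutions
    agree on odd harmonics and differ by a sign flip of all even harmonics
    (the compensating half-turn of the orientation cancels the flip on odd
    ones).  The ambiguity is resolved deterministically: the candidate whose
    first even-harmonic coefficient of appreciable magnitude (scanning
    A2, B2, C2, D2, A4, ...) is positive wins.  For egg-shaped seed outlines
    this anchors the pointier end consistently.
    """
    if coeffs.normalized:
        raise ValueError("coefficients are already normalized")
    A1, B1, C1, D1 = coeffs.harmonics[0]
    power1 = 0.5 * (A1**2 + B1**2 + C1**2 + D1**2)
    if power1 <= 0:
        raise ValueError("zero first-harmonic power; cannot normalize")

    theta = 0.5 * np.arctan2(2.0 * (A1 * B1 + C1 * D1), A1**2 + C1**2 - B1**2 - D1**2)

    def candidate(th: float) -> np.ndarray:
        h = _rotate_phase(coeffs.harmonics, th)
        psi = np.arctan2(h[0, 2], h[0, 0])  # atan2(C1', A1')
        h = _rotate_space(h, psi)
        scale = np.hypot(h[0, 0], h[0, 2])  # == semi-major axis magnitude
        return h / scale

    cand_a = candidate(theta)
    cand_b = candidate(theta + np.pi)
    chosen = cand_a
    if cand_a.shape[0] >= 2:
        scale_ref = float(np.max(np.abs(cand_a[1:])))
        tol = 1e-9 * max(scale_ref, 1.0)
        flat_a = cand_a[1::2].ravel()  # even harmonics n = 2, 4, ...
        idx = np.flatnonzero(np.abs(flat_a) > tol)
        if idx.size and flat_a[idx[0]] < 0:
            chosen = cand_b
    return EFTCoefficients(
        harmonics=chosen, offset=(0.0, 0.0), normalized=True, view=coeffs.view
    )


def retained_vector(
    coeffs_dorsal: EFTCoefficients, coeffs_lateral: EFTCoefficients
) -> np.ndarray:
    """Concatenate normalized harmonics 2..9 (A,B,C,D each), dorsal block
    first, into the 64-entry shape feature vector."""
    out = []
    for c in (coeffs_dorsal, coeffs_lateral):
        if not c.normalized:
            raise ValueError("retained_vector requires normalized coefficients")
        if c.n_harmonics < 9:
            raise ValueError("need at least 9 harmonics to retain H2..H9")
        out.append(c.harmonics[1:9].ravel())
    return np.concatenate(out)


def eft_inverse(coeffs: EFTCoefficients, n_points: int, t: np.ndarray | None = None):
    """Reconstruct an outline from a coefficient set.

    Returns an ``(n_points, 2)`` array of points at equally spaced values of
    the arclength parameter, or at the phases ``t`` (radians in [0, 2pi))
    when given — useful for comparing a reconstruction vertex-by-vertex with
    the original polygon, whose vertices are generally *not* equally spaced.
    """
    if t is None:
        if n_points < 3:
            raise ValueError("n_points must be >= 3")
        t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    else:
        t = np.asarray(t, dtype=float)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    A, B, C, D = coeffs.harmonics.T
    x = coeffs.offset[0] + A @ cos_nt + B @ sin_nt
    y = coeffs.offset[1] + C @ cos_nt + D @ sin_nt
    return np.column_stack([x, y])


def _vector_to_coeff_pair(
    vector: np.ndarray, d1: float
) -> tuple[EFTCoefficients, EFTCoefficients]:
    v = np.asarray(vector, dtype=float)
    if v.shape != (64,):
        raise ValueError("retained vector must have 64 entries")
    sets = []
    for block, view in ((v[:32], "dorsal"), (v[32:], "lateral")):
        h = np.vstack([[1.0, 0.0, 0.0, d1], block.reshape(8, 4)])
        sets.append(EFTCoefficients(harmonics=h, normalized=True, view=view))
    return sets[0], sets[1]


def mean_outline(vectors, n_points: int = 128, d1: float = 0.6):
    """Mean shape of a collection of 64-entry retained vectors.

    The coefficient-wise mean is re-expanded around the canonical unit first
    harmonic ``(1, 0, 0, d1)`` and inverse-transformed for both views.  The
    ``d1`` aspect surrogate only affects the visual reconstruction, never a
    statistic.  Returns ``(dorsal_points, lateral_points)``.
    """
    arr = np.asarray(list(vectors), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_outline requires a non-empty collection")
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 64:
        raise ValueError("retained vectors must have 64 entries")
    mean_vec = arr.mean(axis=0)
    cd, cl = _vector_to_coeff_pair(mean_vec, d1)
    return eft_inverse(cd, n_points), eft_inverse(cl, n_points)


def harmonic_power_profile(coeffs: EFTCoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power and its cumulative fraction of the total."""
    p = coeffs.power()
    total = p.sum()
    if total == 0:
        return p, np.ones_like(p)
    return p, np.cumsum(p) / total
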