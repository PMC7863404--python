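"""Nuclear-position morphometry along a three-point arc.

Each hair cell is summarized by three 3D landmarks: the apical surface
(cuticular plate) ``A``, the nucleus centroid ``N``, and the basal end
``B``.  A circular arc is fitted through the three points (their
circumcircle, in the plane they span) and the nucleus position is
reported as the arc length from the apical landmark to the nucleus,
optionally normalized by the total apical-to-basal arc length.

Collinear landmark triples fall back to straight-line segments, so the
statistic degrades gracefully for perfectly straight cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArcFit", "fit_arc", "nucleus_position"]

#: scale-free collinearity tolerance: triangle area < COLLINEAR_TOL * |AB|^2
COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class ArcFit:
    """Circular arc through apical (A), nucleus (N) and basal (B) landmarks.

    All coordinates and lengths are in micrometres.  When ``collinear``
    is true the "arc" is the pair of straight segments A→N and A→B and
    ``center``/``radius``/``normal`` are ``None``.
    """

    A: np.ndarray
    N: np.ndarray
    B: np.ndarray
    collinear: bool
    center: np.ndarray | None
    radius: float | None
    normal: np.ndarray | None
    length_an: float  # arc length A -> N (µm)
    length_ab: float  # arc length A -> B through N (µm)


def _as_point(p, name: str) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(-1)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


def fit_arc(A, N, B, voxel_size=(1.0, 1.0, 1.0)) -> ArcFit:
    """Fit the circumcircle arc through three landmarks.

    Parameters
    ----------
    A, N, B : array-like, shape (3,)
        Apical, nucleus and basal landmarks, in voxel coordinates
        (order x, y, z).  Pass ``voxel_size=(1, 1, 1)`` for landmarks
        already in µm.
    voxel_size : tuple of float
        Physical voxel spacing (dx, dy, dz) in µm; points are scaled to
        µm before fitting.

    Returns
    -------
    ArcFit
        Arc lengths are measured along the arc from A to B that passes
        through N (the three-point construction forces this choice).
    """
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError("voxel_size must be three strictly positive values")
    A = _as_point(A, "A") * vs
    N = _as_point(N, "N") * vs
    B = _as_point(B, "B") * vs

    if np.allclose(A, N) or np.allclose(A, B) or np.allclose(N, B):
        raise ValueError("landmarks must be three distinct points")

    u = N - A
    w = B - A
    n = np.cross(u, w)
    ab2 = float(w @ w)
    area = 0.5 * float(np.linalg.norm(n))

    if area < COLLINEAR_TOL * ab2:
        # straight cell: report chord lengths
        return ArcFit(
            A=A, N=N, B=B, collinear=True, center=None, radius=None,
            normal=None,
            length_an=float(np.linalg.norm(u)),
            length_ab=float(np.linalg.norm(w)),
        )

    # circumcenter of the triangle, in its own plane
    n2 = float(n @ n)
    center = A + np.cross((u @ u) * w - (w @ w) * u, n) / (2.0 * n2)
    radius = float(np.linalg.norm(A - center))

    # in-plane polar angles, measured from A around the circle
    nhat = n / np.sqrt(n2)
    e1 = (A - center) / radius
    e2 = np.cross(nhat, e1)

    def angle(p: np.ndarray) -> float:
        v = p - center
        a = float(np.arctan2(v @ e2, v @ e1))
        return a % (2.0 * np.pi)

    phi_n = angle(N)
    phi_b = angle(B)
    # choose the traversal direction in which N precedes B, i.e. the
    # arc from A to B that actually passes through N
    if phi_n <= phi_b:
        length_an = radius * phi_n
        length_ab = radius * phi_b
    else:
        length_an = radius * (2.0 * np.pi - phi_n)
        length_ab = radius * (2.0 * np.pi - phi_b)

    return ArcFit(
        A=A, N=N, B=B, collinear=False, center=center, radius=radius,
        normal=nhat, length_an=float(length_an), length_ab=float(length_ab),
    )


def nucleus_position(fit: ArcFit) -> dict:
    """Nucleus position statistics from a fitted arc.

    Returns ``distance_from_apical`` (µm of arc from the apical landmark
    to the nucleus) and ``normalized`` (that distance divided by the
    total apical-to-basal arc length, in [0, 1]).
    """
    if fit.length_ab <= 0:
        raise ValueError("total arc length A->B is zero; position undefined")
    return {
        "distance_from_apical": fit.length_an,
        "normalized": fit.length_an / fit.length_ab,
    }
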