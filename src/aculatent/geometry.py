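"""Geometry of latent trajectories: best-fit planes, inter-plane angles,
and elliptic attractor fits.

A condition's latent trajectory is summarised by (i) its best-fit plane — the
top two principal directions p1, p2 of the centred points ("acupuncture
modes") — and (ii) the ellipse the in-plane trajectory converges to, fitted
by the direct (Fitzgibbon / Halir-Flusser) least-squares conic method, which
is closed-form and guaranteed to return an ellipse when one exists.  Plane
orientation differences are unsigned dihedral angles in [0, 90] degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DegenerateFitError, DegenerateGeometryError
from .vae import LatentTrajectory


@dataclass
class PlaneModel:
    """Best-fit plane of a 3-D trajectory: centroid plus orthonormal in-plane
    basis (p1, p2) and unit normal; ``residual_frac`` is the fraction of
    variance off-plane."""

    centroid: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    normal: np.ndarray
    residual_frac: float


@dataclass
class EllipseAttractor:
    """Fitted ellipse in plane coordinates: ``a >= b > 0`` are the semi-axes,
    orientation (long-axis direction) lies in [0, pi)."""

    center: np.ndarray
    long_axis: float
    short_axis: float
    orientation: float
    fit_residual: float


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the first component of non-negligible magnitude is positive."""
    for x in v:
        if abs(x) > 1e-12:
            return v if x > 0 else -v
    return v


def _as_points(traj) -> np.ndarray:
    if isinstance(traj, LatentTrajectory):
        return traj.top(3)
    return np.asarray(traj, dtype=float)


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------

def fit_plane(traj) -> PlaneModel:
    """Total-least-squares plane through a (samples, 3) trajectory.

    p1, p2 are the top-2 principal directions of the centred points; raises
    :class:`DegenerateGeometryError` for collinear or coincident points.
    """
    pts = _as_points(traj)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12 or s[1] < 1e-9 * s[0]:
        raise DegenerateGeometryError("points are collinear or coincident")
    total = float(np.sum(s ** 2))
    return PlaneModel(
        centroid=centroid,
        p1=_fix_sign(vt[0]), p2=_fix_sign(vt[1]), normal=_fix_sign(vt[2]),
        residual_frac=float(s[2] ** 2 / total),
    )


def plane_angle(a: PlaneModel, b: PlaneModel) -> float:
    """Unsigned dihedral angle between two planes, degrees in [0, 90]."""
    c = abs(float(a.normal @ b.normal))
    s = float(np.linalg.norm(np.cross(a.normal, b.normal)))
    return float(np.degrees(np.arctan2(s, c)))  # stable near 0 and 90


def angle_frequency_regression(angles, freqs) -> tuple[float, float, float]:
    """OLS of plane angle on manipulation frequency -> (slope, intercept, R^2)."""
    angles = np.asarray(angles, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.unique(freqs).size < 3:
        raise ValueError("need at least 3 distinct frequencies")
    res = stats.linregress(freqs, angles)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def project_to_plane(traj, plane: PlaneModel) -> np.ndarray:
    """In-plane coordinates ((x - centroid) . p1, (x - centroid) . p2)."""
    pts = _as_points(traj)
    centered = pts - plane.centroid
    return np.column_stack([centered @ plane.p1, centered @ plane.p2])


# ---------------------------------------------------------------------------
# ellipse fitting (direct least-squares conic, ellipse-constrained)
# ---------------------------------------------------------------------------

def fit_ellipse(points: np.ndarray) -> EllipseAttractor:
    """Direct least-squares ellipse fit (Halir-Flusser formulation).

    Fits the conic a x^2 + b xy + c y^2 + d x + e y + f = 0 subject to
    4ac - b^2 = 1, which always yields an ellipse; semi-axes and orientation
    come from the conic's eigen-structure.  Raises
    :class:`DegenerateFitError` when the points do not determine an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise DegenerateFitError("need at least 6 points in 2-D")
    # centre and scale for conditioning
    mean = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale < 1e-12:
        raise DegenerateFitError("points are coincident")
    xy = (pts - mean) / scale
    x, y = xy[:, 0], xy[:, 1]

    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as err:
        raise DegenerateFitError("degenerate point configuration") from err
    m = s1 + s2 @ t
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if ok.size == 0:
        raise DegenerateFitError("no ellipse solution (points may be collinear)")
    a1 = np.real(eigvec[:, ok[0]])
    conic = np.concatenate([a1, t @ a1])  # [A, B, C, D, E, F] in scaled frame

    A, B, C, D, E, F = conic
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        center_s = np.linalg.solve(2.0 * q, [-D, -E])
    except np.linalg.LinAlgError as err:
        raise DegenerateFitError("degenerate conic") from err
    mu = (center_s @ q @ center_s + np.array([D, E]) @ center_s + F)
    lam, vec = np.linalg.eigh(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        ax = np.sqrt(-mu / lam)
    if not np.all(np.isfinite(ax)) or np.any(ax <= 0):
        raise DegenerateFitError("conic is not an ellipse")

    # long axis = larger semi-axis; its direction is the eigenvector of the
    # smaller quadratic-form eigenvalue
    i_long = int(np.argmax(ax))
    orientation = float(np.arctan2(vec[1, i_long], vec[0, i_long])) % np.pi
    vals = conic @ np.column_stack([d1, d2]).T
    residual = float(np.sqrt(np.mean(vals ** 2)) / np.linalg.norm(conic[:3]))
    return EllipseAttractor(
        center=center_s * scale + mean,
        long_axis=float(ax[i_long] * scale),
        short_axis=float(ax.min() * scale),
        orientation=orientation,
        fit_residual=residual * scale ** 2,
    )


# ---------------------------------------------------------------------------
# per-condition attractor statistics
# ---------------------------------------------------------------------------

def attractor_stats(fits_by_condition: dict[str, list[EllipseAttractor]]) -> pd.DataFrame:
    """Mean and variance of the long and short semi-axes per condition.

    Requires at least 2 trials per condition (variance is undefined
    otherwise).
    """
    rows = []
    for condition, fits in fits_by_condition.items():
        if len(fits) < 2:
            raise ValueError(f"condition {condition!r} has {len(fits)} trial(s); need >= 2")
        a = np.array([f.long_axis for f in fits])
        b = np.array([f.short_axis for f in fits])
        rows.append({
            "condition": condition, "n_trials": len(fits),
            "mean_a": a.mean(), "var_a": a.var(ddof=1),
            "mean_b": b.mean(), "var_b": b.var(ddof=1),
        })
    return pd.DataFrame(rows).set_index("condition")
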