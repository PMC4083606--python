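"""PCA reference frames and polynomial spline fits of helix shape.

Each helix trace gets a local coordinate system from principal component
analysis of its Cα cloud: the origin is the centroid and the axes are the
eigenvectors PC1, PC2, PC3 of the coordinate covariance, PC1 approximating
the helix axis. In that frame the helix shape is modelled as the parametric
curve

    c(z) = (z, f2(z), f3(z)),

where z is the PC1 coordinate and f2, f3 are single-segment polynomials
(degree m, no interior knots) fitted by ordinary least squares in the
PC1–PC2 and PC1–PC3 planes respectively — two independent one-dimensional
problems. The fitted curve is then discretised at M positions, uniformly in
z by default, and mapped back to global coordinates.

Sign conventions make frames deterministic: PC1 points from the first
toward the last residue, PC2 is oriented toward the first residue, and
PC3 = PC1 × PC2 (right-handed). The fitted global curve is invariant to
these choices; coefficient-level tests are not, hence the fixed convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import GeometryError, ValidationError
from .structure_io import HelixTrace

__all__ = [
    "ReferenceFrame",
    "SplineModel",
    "DiscretizedCurve",
    "compute_frame",
    "fit_spline",
    "evaluate_spline",
    "aic_score",
    "best_degree_by_aic",
]

#: polynomial degrees studied by default
DEFAULT_DEGREES = (2, 3, 4)


@dataclass(frozen=True)
class ReferenceFrame:
    """Local PCA coordinate system of one helix.

    ``axes`` rows are PC1, PC2, PC3 (orthonormal, right-handed);
    ``eigenvalues`` are the corresponding coordinate variances in Å²,
    descending.
    """

    origin: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map global (n, 3) points into frame coordinates (z, y2, y3)."""
        return (np.atleast_2d(points) - self.origin) @ self.axes.T

    def to_global(self, local: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_local`."""
        return np.atleast_2d(local) @ self.axes + self.origin


@dataclass(frozen=True)
class SplineModel:
    """Fitted curve c(z) = (z, f2(z), f3(z)) in its owning reference frame.

    Coefficients are in ascending powers (a_0 … a_m); ``rss`` is the summed
    squared residual of both component fits, in Å².
    """

    degree_m: int
    coeffs_f2: np.ndarray
    coeffs_f3: np.ndarray
    z_min: float
    z_max: float
    frame: ReferenceFrame
    rss: float
    n_points: int
    knots_K: int = 0

    def to_dict(self) -> dict:
        """JSON-serialisable provenance record."""
        return {
            "degree_m": self.degree_m,
            "knots_K": self.knots_K,
            "coeffs_f2": list(map(float, self.coeffs_f2)),
            "coeffs_f3": list(map(float, self.coeffs_f3)),
            "z_min": float(self.z_min),
            "z_max": float(self.z_max),
            "rss": float(self.rss),
            "n_points": self.n_points,
            "frame": {
                "origin": list(map(float, self.frame.origin)),
                "axes": [list(map(float, row)) for row in self.frame.axes],
                "eigenvalues": list(map(float, self.frame.eigenvalues)),
            },
        }


@dataclass(frozen=True)
class DiscretizedCurve:
    """The spline sampled at M parameter values u in [0, 1].

    ``points_global`` are the sampled positions in global coordinates;
    ``arc_lengths`` are cumulative chord lengths starting at 0.
    """

    u_values: np.ndarray
    points_global: np.ndarray
    arc_lengths: np.ndarray

    @property
    def M(self) -> int:
        return len(self.u_values)


def compute_frame(trace: HelixTrace) -> ReferenceFrame:
    """PCA reference frame of a helix trace.

    Origin is the centroid; axes are covariance eigenvectors in descending
    eigenvalue order with the deterministic sign convention described in the
    module docstring. Raises :class:`GeometryError` if all points coincide.
    """
    X = trace.coords
    origin = X.mean(axis=0)
    Xc = X - origin
    cov = (Xc.T @ Xc) / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 1e-24:
        raise GeometryError("all points coincident: no principal axis")

    pc1, pc2 = evecs[:, 0], evecs[:, 1]
    if np.dot(X[-1] - X[0], pc1) < 0:
        pc1 = -pc1
    if np.dot(X[0] - origin, pc2) < 0:
        pc2 = -pc2
    pc3 = np.cross(pc1, pc2)
    axes = np.vstack([pc1, pc2, pc3])
    return ReferenceFrame(origin=origin, axes=axes, eigenvalues=np.maximum(evals, 0.0))


def fit_spline(trace: HelixTrace, frame: ReferenceFrame, degree_m: int) -> SplineModel:
    """Least-squares polynomial fit of the trace in its reference frame.

    Solves two independent 1-D problems: f2 on (z, y2) and f3 on (z, y3),
    via an SVD-based least-squares factorisation (never explicit normal
    equations). Raises on too few points or rank deficiency.
    """
    if degree_m < 1:
        raise ValidationError(f"degree_m: must be >= 1, got {degree_m}")
    n = trace.n_residues
    if n < degree_m + 2:
        raise ValidationError(
            f"need at least degree_m + 2 = {degree_m + 2} points for degree "
            f"{degree_m}, got {n}"
        )
    local = frame.to_local(trace.coords)
    z, y2, y3 = local[:, 0], local[:, 1], local[:, 2]
    V = npoly.polyvander(z, degree_m)
    # scale columns for conditioning; rescale coefficients afterwards
    scale = np.sqrt((V * V).sum(axis=0))
    scale[scale == 0] = 1.0
    sol, _, rank, _ = np.linalg.lstsq(V / scale, np.column_stack([y2, y3]), rcond=None)
    if rank < degree_m + 1:
        raise GeometryError(
            f"rank-deficient fit (rank {rank} < {degree_m + 1}): too few "
            f"distinct z values for degree {degree_m}"
        )
    coeffs = sol / scale[:, None]
    resid = V @ coeffs - np.column_stack([y2, y3])
    rss = float((resid * resid).sum())
    return SplineModel(
        degree_m=degree_m,
        coeffs_f2=coeffs[:, 0],
        coeffs_f3=coeffs[:, 1],
        z_min=float(z.min()),
        z_max=float(z.max()),
        frame=frame,
        rss=rss,
        n_points=n,
    )


def _eval_local(model: SplineModel, z: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [z, npoly.polyval(z, model.coeffs_f2), npoly.polyval(z, model.coeffs_f3)]
    )


def evaluate_spline(
    model: SplineModel, M: int, spacing: str = "z"
) -> DiscretizedCurve:
    """Discretise the fitted curve at M positions in global coordinates.

    With ``spacing="z"`` (default) the samples are uniform in the curve
    parameter z over [z_min, z_max]; position i (1-based) sits at
    z_i = z_min + (i-1)/(M-1) · (z_max − z_min) and u_i = (i-1)/(M-1).
    ``spacing="arclength"`` resamples so points are uniform in arc length.
    """
    if M < 2:
        raise ValidationError(f"M: must be >= 2, got {M}")
    if spacing not in ("z", "arclength"):
        raise ValidationError(f"spacing: 'z' or 'arclength', got {spacing!r}")
    if spacing == "z":
        z = np.linspace(model.z_min, model.z_max, M)
    else:
        dense = np.linspace(model.z_min, model.z_max, max(8 * M, 4096))
        pts = _eval_local(model, dense)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        z = np.interp(np.linspace(0.0, s[-1], M), s, dense)
    points = model.frame.to_global(_eval_local(model, z))
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return DiscretizedCurve(
        u_values=np.linspace(0.0, 1.0, M),
        points_global=points,
        arc_lengths=np.concatenate([[0.0], np.cumsum(seg)]),
    )


def aic_score(model: SplineModel) -> float:
    """Akaike information criterion of a fitted spline model (lower is better).

    Package convention: AIC = n·ln(rss/n) + 2p with n = 2·n_points (the
    residuals of both f2 and f3 enter one Gaussian likelihood) and
    p = 2·(degree_m + 1) coefficients. A perfect fit (rss = 0) returns
    −inf with a warning.
    """
    if model.rss <= 0.0:
        warnings.warn("rss is zero: perfect fit, AIC = -inf", stacklevel=2)
        return -math.inf
    n = 2 * model.n_points
    p = 2 * (model.degree_m + 1)
    return n * math.log(model.rss / n) + 2 * p


def best_degree_by_aic(models: Sequence[SplineModel]) -> int:
    """Degree of the model with the lowest AIC (ties broken by lower degree)."""
    if not models:
        raise ValidationError("models: empty sequence")
    ordered = sorted(models, key=lambda m: (aic_score(m), m.degree_m))
    return ordered[0].degree_m
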