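"""Rulings, interhelical distance profiles and ruled-surface area.

Two discretised helix splines sharing a common parameter u are joined by M
"rulings" — straight segments between equal-u points. Because groove-flanking
helix pairs run antiparallel, the second curve's sampling order is reversed
whenever reversal yields the smaller total ruling length; correspondence is
always by index, never by closest-point reprojection.

The interhelical distance profile is d(u_i) = ||c2(u_i) − c1(u_i)||, and the
surface swept by the rulings is triangulated quad by quad with a fixed
diagonal, giving a deterministic total area A that measures the width/shape
of the inter-helix cleft.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .spline import DiscretizedCurve

__all__ = [
    "RulingSet",
    "SurfaceArea",
    "build_rulings",
    "interhelical_distances",
    "ruled_surface_area",
    "default_positions",
    "PAPER_POSITIONS",
    "rulings_to_csv",
]

#: the five canonical 1-based ruling positions at M = 1500:
#: the two flanking points and three central points of the splines
PAPER_POSITIONS = (1, 369, 737, 1105, 1471)

#: canonical number of rulings
DEFAULT_M = 1500


@dataclass(frozen=True)
class RulingSet:
    """M paired points on the two discretised splines with their distances (Å)."""

    u_values: np.ndarray
    endpoints_1: np.ndarray
    endpoints_2: np.ndarray
    distances: np.ndarray
    orientation_reversed: bool

    @property
    def M(self) -> int:
        return len(self.u_values)


@dataclass(frozen=True)
class SurfaceArea:
    """Triangulated ruled-surface area: per-quad areas and their total, in Å²."""

    total_area: float
    quad_areas: np.ndarray
    triangulation_diagonal: str


def build_rulings(curve1: DiscretizedCurve, curve2: DiscretizedCurve) -> RulingSet:
    """Pair the two curves point-by-point under the common parameter u.

    Curve 2's order is reversed iff reversal gives the smaller total ruling
    length (this resolves the antiparallel helix pairing without sequence
    metadata). Both curves must be discretised at the same M.
    """
    if curve1.M != curve2.M:
        raise ValidationError(
            f"curves discretised at different M ({curve1.M} vs {curve2.M}); "
            f"re-evaluate both splines at a common M"
        )
    p1 = curve1.points_global
    p2 = curve2.points_global
    len_direct = float(np.linalg.norm(p2 - p1, axis=1).sum())
    len_reversed = float(np.linalg.norm(p2[::-1] - p1, axis=1).sum())
    reversed_ = len_reversed < len_direct
    if reversed_:
        p2 = p2[::-1]
    return RulingSet(
        u_values=curve1.u_values.copy(),
        endpoints_1=p1.copy(),
        endpoints_2=p2.copy(),
        distances=np.linalg.norm(p2 - p1, axis=1),
        orientation_reversed=reversed_,
    )


def interhelical_distances(
    rulings: RulingSet, positions: Sequence[int]
) -> list[tuple[int, float]]:
    """Distances d at selected 1-based ruling positions.

    The canonical default at M = 1500 is :data:`PAPER_POSITIONS`
    (1, 369, 737, 1105, 1471): the spline ends plus three central points.
    """
    out = []
    for pos in positions:
        if not 1 <= pos <= rulings.M:
            raise ValidationError(
                f"position {pos} out of range [1, {rulings.M}]"
            )
        out.append((int(pos), float(rulings.distances[pos - 1])))
    return out


def default_positions(M: int) -> tuple[int, ...]:
    """The five canonical positions, rescaled proportionally when M != 1500."""
    if M == DEFAULT_M:
        return PAPER_POSITIONS
    if M < 2:
        raise ValidationError(f"M: must be >= 2, got {M}")
    return tuple(
        int(round((p - 1) / (DEFAULT_M - 1) * (M - 1))) + 1 for p in PAPER_POSITIONS
    )


def _tri_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def ruled_surface_area(rulings: RulingSet, diagonal: str = "12") -> SurfaceArea:
    """Total area of the triangulated ruled surface.

    Quad i has corners (p1_i, p2_i, p2_{i+1}, p1_{i+1}). With the default
    fixed diagonal ``"12"`` it is split along p1_i → p2_{i+1}; ``"21"``
    uses the other diagonal (provided to quantify triangulation
    sensitivity). Each triangle's area is half the cross-product magnitude
    of its edge vectors.
    """
    if rulings.M < 2:
        raise ValidationError(f"need at least 2 rulings, got {rulings.M}")
    if diagonal not in ("12", "21"):
        raise ValidationError(f"diagonal: '12' or '21', got {diagonal!r}")
    a1, b1 = rulings.endpoints_1[:-1], rulings.endpoints_1[1:]
    a2, b2 = rulings.endpoints_2[:-1], rulings.endpoints_2[1:]
    if diagonal == "12":
        quads = _tri_areas(a1, a2, b2) + _tri_areas(a1, b2, b1)
    else:
        quads = _tri_areas(a1, a2, b1) + _tri_areas(a2, b2, b1)
    return SurfaceArea(
        total_area=float(quads.sum()),
        quad_areas=quads,
        triangulation_diagonal=diagonal,
    )


def rulings_to_csv(rulings: RulingSet, path: str | Path) -> None:
    """Export rulings as CSV: u, x1, y1, z1, x2, y2, z2, d."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "x1", "y1", "z1", "x2", "y2", "z2", "d"])
        for u, p1, p2, d in zip(
            rulings.u_values, rulings.endpoints_1, rulings.endpoints_2, rulings.distances
        ):
            writer.writerow(
                [f"{u:.9g}"] + [f"{v:.9g}" for v in (*p1, *p2)] + [f"{d:.9g}"]
            )
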