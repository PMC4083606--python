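import numpy as np
import pytest

from helixgeom import (
    DiscretizedCurve,
    HelixSpec,
    HelixTrace,
    PairTrajectorySpec,
    ReferenceFrame,
)


def make_trace(coords, frame_index=0, chain_id="A"):
    coords = np.asarray(coords, dtype=float)
    return HelixTrace(
        frame_index=frame_index,
        chain_id=chain_id,
        residue_ids=np.arange(1, len(coords) + 1),
        coords=coords,
    )


def identity_frame():
    """Global frame: fits happen directly on raw (x, y, z)."""
    return ReferenceFrame(
        origin=np.zeros(3), axes=np.eye(3), eigenvalues=np.array([1.0, 1.0, 1.0])
    )


def line_curve(p0, p1, M):
    """Hand-built discretised straight curve from p0 to p1 (bypasses fitting)."""
    u = np.linspace(0.0, 1.0, M)
    pts = np.asarray(p0) + u[:, None] * (np.asarray(p1) - np.asarray(p0))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return DiscretizedCurve(
        u_values=u,
        points_global=pts,
        arc_lengths=np.concatenate([[0.0], np.cumsum(seg)]),
    )


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def straight_spec():
    """21 residues x 1.5 Å rise = 30 Å of exactly collinear points."""
    return HelixSpec(n_residues=21, helix_radius=0.0, noise_sigma=0.0, seed=0)


@pytest.fixture
def straight_pair_spec(straight_spec):
    return PairTrajectorySpec(
        helix1=straight_spec,
        helix2=HelixSpec(n_residues=21, helix_radius=0.0, noise_sigma=0.0, seed=1),
        separation=12.0,
        antiparallel=True,
        n_frames=1,
    )


@pytest.fixture
def curved_pair_spec():
    """Bent helical pair with realistic radius: smooth but genuinely curved."""
    bend = ((0.0, -0.08, 0.002), (0.0, 0.02, -0.0004))
    return PairTrajectorySpec(
        helix1=HelixSpec(n_residues=36, axis_bend_coeffs=bend, seed=10),
        helix2=HelixSpec(n_residues=36, axis_bend_coeffs=bend, seed=11),
        separation=14.0,
        antiparallel=True,
        n_frames=1,
    )
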