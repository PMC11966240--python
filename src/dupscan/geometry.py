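"""Elementary 3-D geometry: residue frames, rigid motions, superposition.

Points are plain ``numpy`` arrays of shape ``(3,)`` in Å (``Point3`` is an
alias).  A :class:`RigidMotion` is a proper rotation plus a translation —
the equivalence under which backbones are compared; reflections are
deliberately excluded so that mirror images remain distinguishable.

A :class:`ResidueFrame` is the right-handed orthonormal basis attached to a
residue from its three main-chain trace atoms (N, Cα, C):

* origin at Cα,
* ``e1`` along Cα→N,
* ``e3`` along the normal of the N–Cα–C plane,
* ``e2 = e3 × e1`` completing the right-handed triple.

The frame is continuous in the atom positions and equivariant under rigid
motion, which is what makes coordinates expressed in it rigid invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateFrame,
    ImproperRotation,
    LengthMismatch,
    TooFewPoints,
)

Point3 = np.ndarray  # shape (3,), float64, Å

#: tolerance on ||(N-Ca) x (C-Ca)|| below which a frame is degenerate (Å²)
COLLINEARITY_TOL = 1e-6

_ORTHO_TOL = 1e-10


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class RigidMotion:
    """Proper rigid motion p ↦ R·p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ImproperRotation("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ImproperRotation("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidMotion") -> "RigidMotion":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidMotion(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidMotion":
        return RigidMotion(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidMotion":
        return RigidMotion(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator, translation_scale: float = 50.0) -> "RigidMotion":
        """Uniformly random rotation plus a random translation (test harness)."""
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-translation_scale, translation_scale, size=3)
        return RigidMotion(R, t)


@dataclass(frozen=True)
class ResidueFrame:
    """Right-handed orthonormal frame attached to one residue."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix with e1, e2, e3 as rows."""
        return np.stack([self.e1, self.e2, self.e3])


def build_frame(n: Point3, ca: Point3, c: Point3, tol: float = COLLINEARITY_TOL) -> ResidueFrame:
    """Build the residue frame from its N, Cα and C atom positions.

    Raises :class:`DegenerateFrame` when the three points coincide or are
    collinear within ``tol`` (measured on the cross-product norm, Å²).
    Real backbones are far from this limit; the guard exists for synthetic
    edge cases.
    """
    n = _as_point(n)
    ca = _as_point(ca)
    c = _as_point(c)
    u = n - ca
    v = c - ca
    w = np.cross(u, v)
    wn = np.linalg.norm(w)
    if wn <= tol:
        raise DegenerateFrame(
            f"N, CA, C are coincident or collinear (|cross| = {wn:.3g} <= {tol:.3g})"
        )
    e1 = u / np.linalg.norm(u)
    e3 = w / wn
    e2 = np.cross(e3, e1)
    return ResidueFrame(origin=ca, e1=e1, e2=e2, e3=e3)


def express_in_frame(p: Point3, frame: ResidueFrame) -> np.ndarray:
    """Local coordinates of ``p`` in ``frame``: ((p−o)·e1, (p−o)·e2, (p−o)·e3)."""
    d = _as_point(p) - frame.origin
    return np.array([d @ frame.e1, d @ frame.e2, d @ frame.e3])


def place_from_frame(local: np.ndarray, frame: ResidueFrame) -> np.ndarray:
    """Inverse of :func:`express_in_frame`: origin + x·e1 + y·e2 + z·e3."""
    x, y, z = np.asarray(local, dtype=float)
    return frame.origin + x * frame.e1 + y * frame.e2 + z * frame.e3


def apply_rigid_motion(coords, motion: RigidMotion) -> np.ndarray:
    """Map a list/array of points through a rigid motion."""
    pts = np.asarray(coords, dtype=float)
    return motion.apply(pts)


def kabsch_superpose(a, b) -> tuple[RigidMotion, float]:
    """Optimal proper rigid motion of point set ``a`` onto ``b`` and its RMSD.

    Thin wrapper over the Kabsch solution (via
    :meth:`scipy.spatial.transform.Rotation.align_vectors`), restricted to
    proper rotations so a mirror image never superposes at zero RMSD.
    """
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise LengthMismatch(f"point sets differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("expected (n, 3) arrays")
    if A.shape[0] < 3:
        raise TooFewPoints("superposition needs at least 3 points")
    ca_ = A.mean(axis=0)
    cb_ = B.mean(axis=0)
    rot, rssd = Rotation.align_vectors(B - cb_, A - ca_)
    R = rot.as_matrix()
    t = cb_ - R @ ca_
    moved = (A @ R.T) + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return RigidMotion(R, t), rmsd
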