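"""Rigid-body superposition kernel.

Optimal least-squares superposition of ordered point sets (Kabsch, via
SVD with determinant correction so that only proper rotations are
returned), plus plain RMSD on corresponding points.  This is the
geometric engine under every seed superposition and every match
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "fit", "rmsd", "apply_transform"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1;
    ``translation`` is a 3-vector in Angstroms.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        return P @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) == self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


class DegenerateInputError(ValueError):
    """Fewer than three points were supplied to the fitting routine."""


def fit(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of P onto Q (points in correspondence).

    Returns the proper rigid transform minimising the RMSD of
    ``transform(P)`` against ``Q``, and that minimal RMSD.  Reflections
    are never returned even when one would score lower, because a
    mirror image of a nucleic-acid fragment is not the same molecule.

    Raises :class:`DegenerateInputError` for fewer than 3 points.
    Collinear inputs are still fitted (the minimiser exists but the
    rotation about the common axis is arbitrary).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)

    # residual via the trace identity would do, but the direct distance is
    # exact and immune to cancellation for near-zero RMSDs
    delta = transform.apply(P) - Q
    value = float(np.sqrt((delta * delta).sum() / n))
    return transform, value


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square deviation of corresponding points. No fitting."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"size mismatch: {P.shape} vs {Q.shape}")
    delta = np.atleast_2d(P - Q)
    return float(np.sqrt((delta * delta).sum() / delta.shape[0]))


def apply_transform(t: RigidTransform, P: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(P)
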