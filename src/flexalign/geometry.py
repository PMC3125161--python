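"""Rigid-body superposition utilities (SVD-based least squares)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation: x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def apply(t: RigidTransform, pts: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to a (k, 3) array (or a single 3-vector)."""
    pts = np.asarray(pts, dtype=float)
    return pts @ t.rotation.T + t.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform | None:
    """Least-squares proper rotation + translation mapping P onto Q.

    Returns ``None`` when fewer than three point pairs are given (the
    transform is considered undefined and callers must fall back).  For
    degenerate (e.g. collinear) sets the SVD solution is still returned,
    with the determinant corrected to +1; the minimiser may be non-unique.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        return None
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length point sets (Å)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have identical shapes")
    return float(np.sqrt(((P - Q) ** 2).sum(axis=-1).mean()))


def superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal superposition of P onto Q."""
    t = kabsch(P, Q)
    if t is None:
        raise ValueError("need at least three points")
    return rmsd(apply(t, P), Q)
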