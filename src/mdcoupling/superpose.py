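"""Least-squares rigid superposition (Kabsch) of trajectory frames.

Covariance and mutual-information estimates are only meaningful in a common
reference frame, so every frame is first superposed onto a reference using a
fit selection — here typically the Cα atoms of the TRP-like domain, which is
the most rigid part of the pocket-to-pore region.  The Kabsch rotation is
computed by SVD with the usual determinant correction so a reflection is
never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError
from .trajectory import AtomSelection, FrameSet

__all__ = ["RigidTransform", "kabsch", "align_frameset"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, x ↦ R·x + t, with the fit RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(reference: np.ndarray,
           mobile: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Optimal rigid transform mapping ``mobile`` onto ``reference``.

    Minimises the (weighted) RMSD over M ≥ 3 paired points; the SVD
    reflection branch is corrected so the returned rotation is proper even
    for mirror-image inputs (where the residual RMSD is then nonzero).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference and mobile must both be M×3")
    m = ref.shape[0]
    if m < 3:
        raise DegeneracyError(f"need at least 3 points, got {m}")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be M non-negative values, not all zero")
        w = w / w.sum()

    ref_centroid = w @ ref
    mob_centroid = w @ mob
    ref_c = ref - ref_centroid
    mob_c = mob - mob_centroid

    # Collinear point sets leave a rotation about the common axis undetermined.
    sv_ref = np.linalg.svd(ref_c * np.sqrt(w)[:, None], compute_uv=False)
    scale = max(sv_ref[0], 1e-30)
    if np.sum(sv_ref / scale > 1e-8) < 2:
        raise DegeneracyError("fit points are collinear or coincident")

    H = (mob_c * w[:, None]).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    translation = ref_centroid - R @ mob_centroid
    moved = mob_c @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - ref_c) ** 2)))
    return RigidTransform(R, translation, rmsd)


def align_frameset(frames: FrameSet,
                   fit_selection: AtomSelection,
                   reference: str | np.ndarray = "first") -> FrameSet:
    """Superpose every frame onto a reference via its fit-selection atoms.

    ``reference`` is either ``"first"`` (frame 0, the default) or an external
    N×3 or M×3 coordinate array (full topology or fit-selection size).  The
    whole frame — all N atoms — is moved by the transform fitted on the
    selection.
    """
    idx = fit_selection.atom_indices
    if isinstance(reference, str):
        if reference != "first":
            raise ValueError(f"unknown reference choice {reference!r}")
        ref_coords = frames.coordinates[0, idx]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape == (frames.n_atoms, 3):
            ref_coords = ref[idx]
        elif ref.shape == (idx.size, 3):
            ref_coords = ref
        else:
            raise ValueError(
                "external reference must be N×3 (topology) or M×3 (selection)"
            )

    out = np.empty_like(frames.coordinates)
    for t in range(frames.n_frames):
        try:
            transform = kabsch(ref_coords, frames.coordinates[t, idx])
        except DegeneracyError as exc:
            raise DegeneracyError(f"frame {t}: {exc}") from exc
        out[t] = transform.apply(frames.coordinates[t])
    return FrameSet(out, frames.times.copy(), frames.topology)
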