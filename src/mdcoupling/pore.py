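"""Simplified probe-sphere pore-radius profiling along a channel axis.

At each slice z along the (user-supplied or principal) channel axis, the
profile reports the radius of the largest sphere centred in that slice plane
that touches no van-der-Waals-inflated atom:

    radius(c) = min_i ( ‖pos_i − c‖ − vdw_i ),   c = origin + x·u + y·v + z·w

maximised over the in-plane offset (x, y) by a derivative-free Nelder–Mead
search seeded from the previous slice's centre, so the pore centre line is
followed continuously.  This is the HOLE/CHAP family of algorithms reduced
to a straight axis; absolute radii depend on the vdW table and are
comparable only qualitatively with curved-pathway tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import EmptyInputError, ShapeError
from .trajectory import AtomSelection, FrameSet, Topology

__all__ = [
    "VdwTable",
    "PoreProfile",
    "pore_radius_profile",
    "min_radius_series",
    "average_profile",
    "principal_axis",
]

#: Bondi-type van der Waals radii (Å); unknown elements use ``default``.
_BONDI = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class VdwTable:
    """Element → van der Waals radius (Å) with a documented fallback."""

    radii: dict[str, float] = field(default_factory=lambda: dict(_BONDI))
    default: float = 1.50

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.default <= 0:
            raise ValueError("vdW radii must be positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)

    def for_elements(self, elements: np.ndarray) -> np.ndarray:
        return np.array([self.radius(e) for e in elements])


@dataclass
class PoreProfile:
    """Maximal probe radius versus position along the channel axis."""

    z_values: np.ndarray
    radii: np.ndarray
    centre_path: np.ndarray        # (n_z, 2) in-plane offsets (Å)
    capped: np.ndarray             # True where the probe hit max_probe
    radii_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.z_values.shape != self.radii.shape:
            raise ShapeError("z grid and radii must align")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")

    @property
    def min_radius(self) -> float:
        return float(self.radii.min())

    @property
    def min_radius_z(self) -> float:
        return float(self.z_values[int(np.argmin(self.radii))])

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "z_A": self.z_values,
            "radius_A": self.radii,
            "cx_A": self.centre_path[:, 0],
            "cy_A": self.centre_path[:, 1],
        }
        if self.radii_std is not None:
            data["std_A"] = self.radii_std
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.4f")


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a point cloud (unit vector)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient towards +z for determinism
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    return axis / np.linalg.norm(axis)


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _slice_radius(xy: np.ndarray, plane_origin: np.ndarray,
                  u: np.ndarray, v: np.ndarray,
                  positions: np.ndarray, vdw: np.ndarray) -> float:
    c = plane_origin + xy[0] * u + xy[1] * v
    return float(np.min(np.linalg.norm(positions - c, axis=1) - vdw))


def pore_radius_profile(coordinates: np.ndarray,
                        pore_selection: AtomSelection,
                        topology: Topology,
                        axis: np.ndarray | None = None,
                        z_range: tuple[float, float] | None = None,
                        z_step: float = 0.5,
                        vdw: VdwTable | None = None,
                        max_probe: float = 10.0) -> PoreProfile:
    """Probe-sphere radius profile of one frame along the channel axis.

    ``axis`` defaults to the principal axis of the pore-lining selection and
    is anchored at the selection's centroid; ``z_range`` defaults to the
    selection's extent along the axis.  Negative maxima (slice fully
    occluded) are reported as 0; maxima above ``max_probe`` are capped and
    flagged.
    """
    if len(pore_selection) == 0:
        raise EmptyInputError("pore selection is empty")
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    vdw = vdw or VdwTable()
    positions = np.asarray(coordinates, dtype=float)[pore_selection.atom_indices]
    radii_atoms = vdw.for_elements(
        topology.element[pore_selection.atom_indices])

    w = (principal_axis(positions) if axis is None
         else np.asarray(axis, dtype=float) / np.linalg.norm(axis))
    u, v = _plane_basis(w)
    origin = positions.mean(axis=0)
    z_atoms = (positions - origin) @ w
    if z_range is None:
        z_range = (float(z_atoms.min()), float(z_atoms.max()))
    n_z = int(np.floor((z_range[1] - z_range[0]) / z_step)) + 1
    z_values = z_range[0] + z_step * np.arange(n_z)

    # coarse seeding grid: the in-plane slice objective is multimodal for
    # discrete atom rings, so a single-seed simplex can stall in a side lobe
    inplane = positions - origin - np.outer(z_atoms, w)
    p_uv = np.stack([inplane @ u, inplane @ v], axis=1)
    extent = min(float(np.linalg.norm(p_uv, axis=1).max()) + 0.5, 12.0)
    coarse = np.arange(-extent, extent + 0.25, 0.5)
    gx, gy = np.meshgrid(coarse, coarse)
    seed_grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    # a candidate is interior to the pore only if the pore lining surrounds
    # it azimuthally: the largest angular gap of atom directions is ≤ π
    deltas = p_uv[None, :, :] - seed_grid[:, None, :]
    angles = np.sort(np.arctan2(deltas[:, :, 1], deltas[:, :, 0]), axis=1)
    gaps = np.diff(angles, axis=1)
    wrap = 2.0 * np.pi - (angles[:, -1] - angles[:, 0])
    max_gap = np.maximum(gaps.max(axis=1, initial=0.0), wrap)
    interior = max_gap <= np.pi
    seed_grid = seed_grid[interior]
    if seed_grid.shape[0] == 0:
        seed_grid = np.zeros((1, 2))  # open geometry: fall back to the axis

    out_radii = np.empty(n_z)
    centres = np.empty((n_z, 2))
    capped = np.zeros(n_z, dtype=bool)
    guess = np.zeros(2)
    for k, z in enumerate(z_values):
        plane_origin = origin + z * w

        def objective(xy: np.ndarray) -> float:
            return -_slice_radius(xy, plane_origin, u, v, positions, radii_atoms)

        grid_centres = (plane_origin[None, :]
                        + seed_grid[:, :1] * u[None, :]
                        + seed_grid[:, 1:] * v[None, :])
        dists = np.linalg.norm(
            positions[None, :, :] - grid_centres[:, None, :], axis=2)
        grid_vals = (dists - radii_atoms[None, :]).min(axis=1)
        seeds = [guess, seed_grid[int(np.argmax(grid_vals))]]
        best = None
        for start in seeds:
            trial = minimize(objective, start, method="Nelder-Mead",
                             options={"xatol": 1e-3, "fatol": 1e-4,
                                      "maxiter": 400})
            if best is None or trial.fun < best.fun:
                best = trial
        radius = -best.fun
        centre = best.x
        if radius >= max_probe:
            capped[k] = True
            radius = max_probe
        out_radii[k] = max(radius, 0.0)
        centres[k] = centre
        # after a capped slice restart the next search from the axis
        guess = np.zeros(2) if capped[k] else centre
    return PoreProfile(z_values, out_radii, centres, capped)


def min_radius_series(frames: FrameSet,
                      pore_selection: AtomSelection,
                      **profiler_kwargs) -> pd.DataFrame:
    """Per-frame minimum probe radius: (time_ns, min_radius_A).

    The per-frame minimum over the profile is the quantity used to judge
    whether the pore is open or closed over time.
    """
    records = []
    for t in range(frames.n_frames):
        try:
            profile = pore_radius_profile(
                frames.coordinates[t], pore_selection, frames.topology,
                **profiler_kwargs)
        except Exception as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        records.append((frames.times[t], profile.min_radius))
    return pd.DataFrame(records, columns=["time_ns", "min_radius_A"])


def average_profile(profiles: Sequence[PoreProfile]) -> PoreProfile:
    """Per-slice mean and population standard deviation over frame profiles."""
    if not profiles:
        raise EmptyInputError("no profiles to average")
    z0 = profiles[0].z_values
    for p in profiles[1:]:
        if p.z_values.shape != z0.shape or not np.allclose(p.z_values, z0):
            raise ShapeError("profiles are not on a common z grid")
    stacked = np.stack([p.radii for p in profiles])
    centres = np.stack([p.centre_path for p in profiles]).mean(axis=0)
    capped = np.any(np.stack([p.capped for p in profiles]), axis=0)
    return PoreProfile(
        z0.copy(),
        stacked.mean(axis=0),
        centres,
        capped,
        radii_std=stacked.std(axis=0),
    )
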