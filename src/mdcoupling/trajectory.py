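"""Topologies, trajectory frames, and atom selections.

Conventions used throughout the package: coordinates are in Å, times in ns,
atom indices are 0-based internally, and residues are addressed externally by
author (PDB) numbering, e.g. K610 or V961.  PDB reading and writing is backed
by :mod:`biotite.structure.io.pdb`; alternate locations are resolved to the
highest-occupancy conformer (ties go to the first encountered, biotite's
``altloc="occupancy"`` policy), and insertion codes are rejected because
downstream residue keys are (chain, number) pairs.

A compact binary frame container is also provided for long trajectories:

    magic ``b"MDCOORD1"`` | uint32 N | uint32 T | T×N×3 little-endian float32
    coordinates (Å, C order) | T little-endian float64 times (ns)
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

from .errors import (
    EmptyInputError,
    FormatError,
    SelectionError,
    ShapeError,
)

__all__ = [
    "Topology",
    "FrameSet",
    "SegmentDef",
    "AtomSelection",
    "read_topology",
    "read_frames",
    "write_frames_pdb",
    "write_frames_binary",
    "select",
]

_BINARY_MAGIC = b"MDCOORD1"

# Elements counted as hydrogen for the heavy-atom flag.
_HYDROGEN = {"H", "D", "T"}


@dataclass(frozen=True)
class Topology:
    """Frame-independent atom annotations for one structure.

    Parallel arrays of length ``n_atoms``; atom indices are implicit and run
    contiguously from 0 in file order.
    """

    atom_name: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    is_hetero: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for arr in (self.residue_number, self.residue_name, self.chain_id,
                    self.element, self.is_hetero):
            if len(arr) != n:
                raise ShapeError("topology annotation arrays differ in length")
        keys = list(zip(self.chain_id, self.residue_number, self.atom_name))
        if len(set(keys)) != n:
            raise FormatError(
                "duplicate (chain, residue_number, atom_name) triples in topology"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def is_heavy(self) -> np.ndarray:
        return ~np.isin(np.char.upper(self.element.astype("U4")), list(_HYDROGEN))

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        mask = (
            (self.chain_id == chain_id)
            & (self.residue_number == residue_number)
            & (self.atom_name == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            from .errors import LookupFailure

            raise LookupFailure(
                f"atom {atom_name} of residue {residue_number} on chain "
                f"{chain_id} not found in topology"
            )
        return int(idx[0])

    def residue_key(self, atom_index: int) -> tuple[str, int]:
        return (str(self.chain_id[atom_index]), int(self.residue_number[atom_index]))


@dataclass
class FrameSet:
    """T frames × N atoms × 3 coordinates (Å) with per-frame times (ns)."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ShapeError("coordinates must have shape (T, N, 3)")
        if self.coordinates.shape[0] < 1:
            raise ShapeError("a FrameSet needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology ({self.topology.n_atoms})"
            )
        if self.times.shape != (self.coordinates.shape[0],):
            raise ShapeError("times must have one entry per frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ShapeError("coordinates contain non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ShapeError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def copy(self) -> "FrameSet":
        return FrameSet(self.coordinates.copy(), self.times.copy(), self.topology)


@dataclass(frozen=True)
class SegmentDef:
    """A named residue range on one chain, e.g. the pocket lid L663–Q676."""

    name: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"segment {self.name}: first_residue ({self.first_residue}) "
                f"exceeds last_residue ({self.last_residue})"
            )

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return (
            chain_id == self.chain_id
            and self.first_residue <= residue_number <= self.last_residue
        )

    def on_chain(self, chain_id: str) -> "SegmentDef":
        """The same residue range addressed on a different monomer chain."""
        return SegmentDef(self.name, chain_id, self.first_residue, self.last_residue)


@dataclass(frozen=True)
class AtomSelection:
    """An ordered subset of topology atoms with per-atom residue keys."""

    atom_indices: np.ndarray
    residue_keys: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=np.intp)
        object.__setattr__(self, "atom_indices", idx)
        if len(np.unique(idx)) != idx.size:
            raise SelectionError("duplicate atom indices in selection")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise SelectionError("selection must follow topology order")
        if len(self.residue_keys) != idx.size:
            raise SelectionError("residue_keys must align with atom_indices")

    @property
    def n_atoms(self) -> int:
        return self.atom_indices.size

    def __len__(self) -> int:
        return self.n_atoms


# ---------------------------------------------------------------------------
# PDB reading


def _validate_pdb_lines(path: Path) -> int:
    """Pre-validate coordinate records, returning the ATOM/HETATM count.

    Supplies the line numbers for the format-error contract; biotite's own
    exceptions do not carry them.
    """
    n_records = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"{path}, line {lineno}: truncated {rec} record")
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {lineno}: unparsable {rec} record ({exc})"
                ) from None
            if line[26] not in (" ", ""):
                raise FormatError(
                    f"{path}, line {lineno}: insertion code {line[26]!r} is "
                    "not supported (residue keys are (chain, number) pairs)"
                )
    return n_records


def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    element = arr.element.astype("U4")
    missing = element == ""
    if np.any(missing):
        element[missing] = struc.infer_elements(arr.atom_name[missing])
    return Topology(
        atom_name=arr.atom_name.astype("U6"),
        residue_number=arr.res_id.astype(np.int64),
        residue_name=arr.res_name.astype("U5"),
        chain_id=arr.chain_id.astype("U4"),
        element=element,
        is_hetero=arr.hetero.astype(bool),
    )


def read_topology(path: str | Path) -> Topology:
    """Build a :class:`Topology` from the first MODEL of a PDB file.

    Alternate locations are collapsed to the highest-occupancy conformer;
    element symbols fall back to the atom-name convention when the element
    column is blank.
    """
    path = Path(path)
    n_records = _validate_pdb_lines(path)
    if n_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    pdb_file = _pdb.PDBFile.read(path)
    try:
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several types
        raise FormatError(f"{path}: {exc}") from exc
    return _topology_from_atom_array(arr)


def _read_times_remarks(path: Path) -> list[float] | None:
    times: list[float] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("REMARK 100 TIME_NS"):
                times.append(float(line.split()[-1]))
            elif line.startswith(("ATOM", "HETATM", "MODEL")):
                break
    return times or None


def _model_atom_counts(path: Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as handle:
        for line in handle:
            if line.startswith("MODEL"):
                in_model = True
                current = 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line[:6].strip() in ("ATOM", "HETATM"):
                current += 1
    if in_model:
        counts.append(current)
    if not counts and current:
        counts.append(current)  # single-model file without MODEL records
    return counts


def _frames_from_pdb(path: Path, topology: Topology) -> tuple[np.ndarray, list[float] | None]:
    _validate_pdb_lines(path)
    for t, count in enumerate(_model_atom_counts(path)):
        if count != topology.n_atoms:
            raise ShapeError(
                f"frame {t} in {path} has {count} atoms, "
                f"topology has {topology.n_atoms}"
            )
    pdb_file = _pdb.PDBFile.read(path)
    try:
        stack = pdb_file.get_structure(altloc="occupancy")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    return coords, _read_times_remarks(path)


def _frames_from_binary(path: Path) -> tuple[np.ndarray, list[float]]:
    raw = path.read_bytes()
    if len(raw) < len(_BINARY_MAGIC) + 8:
        raise FormatError(f"{path}: truncated binary frame container")
    n_atoms, n_frames = struct.unpack_from("<II", raw, len(_BINARY_MAGIC))
    offset = len(_BINARY_MAGIC) + 8
    n_coord = n_frames * n_atoms * 3
    expected = offset + 4 * n_coord + 8 * n_frames
    if len(raw) != expected:
        raise FormatError(
            f"{path}: size {len(raw)} does not match header "
            f"(N={n_atoms}, T={n_frames}, expected {expected})"
        )
    coords = np.frombuffer(raw, dtype="<f4", count=n_coord, offset=offset)
    coords = coords.reshape(n_frames, n_atoms, 3).astype(np.float64)
    times = np.frombuffer(raw, dtype="<f8", count=n_frames,
                          offset=offset + 4 * n_coord)
    return coords, list(times)


def _is_binary_container(path: Path) -> bool:
    with open(path, "rb") as handle:
        return handle.read(len(_BINARY_MAGIC)) == _BINARY_MAGIC


def read_frames(paths: str | Path | Sequence[str | Path],
                topology: Topology) -> FrameSet:
    """Read trajectory frames from one or more files, concatenated in order.

    Accepts multi-model PDB files and the package's binary frame container
    (auto-detected by magic bytes).  Times come from file metadata when
    present; otherwise frames are assigned 0, 1, 2, … ns continuing across
    file boundaries.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_coords: list[np.ndarray] = []
    all_times: list[np.ndarray] = []
    frame_offset = 0
    next_default_time = 0.0
    for path in paths:
        path = Path(path)
        if _is_binary_container(path):
            coords, times = _frames_from_binary(path)
        else:
            coords, times = _frames_from_pdb(path, topology)
        if coords.shape[1] != topology.n_atoms:
            raise ShapeError(
                f"frame {frame_offset} in {path} has {coords.shape[1]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        if times is None:
            times_arr = next_default_time + np.arange(coords.shape[0], dtype=float)
        else:
            times_arr = np.asarray(times, dtype=float)
        all_coords.append(coords)
        all_times.append(times_arr)
        frame_offset += coords.shape[0]
        next_default_time = times_arr[-1] + 1.0 if len(times_arr) else next_default_time
    if not all_coords:
        raise EmptyInputError("no trajectory files given")
    return FrameSet(
        np.concatenate(all_coords, axis=0),
        np.concatenate(all_times),
        topology,
    )


# ---------------------------------------------------------------------------
# Writers


def _atom_array_from(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = topology.atom_name
    arr.res_id = topology.residue_number
    arr.res_name = topology.residue_name
    arr.chain_id = topology.chain_id
    arr.element = topology.element
    arr.hetero = topology.is_hetero
    return arr


def write_frames_pdb(frames: FrameSet, path: str | Path) -> None:
    """Write a FrameSet as a multi-model PDB with times in REMARK 100."""
    path = Path(path)
    stack = struc.stack(
        [_atom_array_from(frames.topology, frames.coordinates[t])
         for t in range(frames.n_frames)]
    )
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    remarks = [
        f"REMARK 100 TIME_NS {t:.6f}" for t in frames.times
    ]
    path.write_text("\n".join(remarks) + "\n" + "\n".join(pdb_file.lines) + "\n")


def write_frames_binary(frames: FrameSet, path: str | Path) -> None:
    """Write a FrameSet in the compact binary frame container."""
    path = Path(path)
    with open(path, "wb") as handle:
        handle.write(_BINARY_MAGIC)
        handle.write(struct.pack("<II", frames.n_atoms, frames.n_frames))
        handle.write(
            np.ascontiguousarray(frames.coordinates, dtype="<f4").tobytes()
        )
        handle.write(np.ascontiguousarray(frames.times, dtype="<f8").tobytes())


# ---------------------------------------------------------------------------
# Selections


def select(topology: Topology,
           segment: SegmentDef,
           heavy_only: bool = False,
           calpha_only: bool = False,
           include_hetero: bool = False) -> AtomSelection:
    """Resolve a residue-range segment to an ordered atom selection.

    Ligand (HETATM) atoms are excluded unless ``include_hetero`` is set, so
    protein-only analyses are the default.  An empty selection is allowed but
    raises a warning.
    """
    if segment.chain_id not in topology.chains():
        raise SelectionError(
            f"segment {segment.name}: chain {segment.chain_id!r} not present "
            f"in topology (chains: {', '.join(topology.chains())})"
        )
    mask = (
        (topology.chain_id == segment.chain_id)
        & (topology.residue_number >= segment.first_residue)
        & (topology.residue_number <= segment.last_residue)
    )
    if not include_hetero:
        mask &= ~topology.is_hetero
    if heavy_only:
        mask &= topology.is_heavy
    if calpha_only:
        mask &= topology.atom_name == "CA"
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        warnings.warn(
            f"segment {segment.name} ({segment.chain_id} "
            f"{segment.first_residue}-{segment.last_residue}) selects no atoms",
            stacklevel=2,
        )
    keys = tuple(topology.residue_key(int(i)) for i in indices)
    return AtomSelection(indices, keys)
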