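"""Gaussian (quasi-harmonic) mutual information between residue motions.

The coupling between two groups of atoms A and B is quantified under the
multivariate-Gaussian approximation of their coordinate fluctuations.  For a
coordinate set **X** with trajectory covariance C(**X**) — entries
⟨X_ij X_kl⟩ − ⟨X_ij⟩⟨X_kl⟩, plain averages over frames — the configurational
entropy is

    H(X) = ½ ln |2πe C(X)|        (nats)

and the mutual information of a residue pair is

    MI(A, B) = H(X_A) + H(X_B) − H(X_{A,B})

which for Gaussians equals ½ ln(|C_A||C_B| / |C_AB|) and is non-negative by
Fischer's inequality.  Log-determinants are computed from eigenvalue spectra
(never a raw determinant), with a configurable eigenvalue floor because the
entropy diverges at zero eigenvalues whenever the sample covariance is
singular (T < d, duplicated atoms).

Aggregation over replicate units follows the two-stage scheme used for
multi-monomer channel trajectories: the entrywise maximum over all
(run, monomer) units per residue pair, then, per segment pair, the mean over
each residue's best partner value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    InsufficientFramesError,
    InvalidCovarianceError,
    SelectionError,
)
from .trajectory import AtomSelection, FrameSet, SegmentDef, Topology, select

__all__ = [
    "CoordinateSetCovariance",
    "EntropyValue",
    "MIMatrix",
    "SegmentPairSummary",
    "covariance",
    "config_entropy",
    "pairwise_mi",
    "mi_matrix",
    "aggregate_max",
    "segment_pair_mean",
    "top_pairs",
    "DEFAULT_EIGENVALUE_FLOOR",
]

#: Default eigenvalue floor (Å²) guarding the log-determinant.
DEFAULT_EIGENVALUE_FLOOR = 1e-8

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))

ResidueKey = tuple[str, int]
PairKey = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class CoordinateSetCovariance:
    """Sample covariance of a flattened coordinate set (d = 3 × n_atoms)."""

    atom_indices: np.ndarray
    mean: np.ndarray
    matrix: np.ndarray
    n_frames: int

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EntropyValue:
    """A configurational entropy in nats with floor bookkeeping."""

    value: float
    dimension: int
    floor_applied: bool


@dataclass(frozen=True)
class SegmentPairSummary:
    segment_a: str
    segment_b: str
    per_residue_max: dict[ResidueKey, float]
    mean_of_maxima: float


def _canonical_pair(a: ResidueKey, b: ResidueKey) -> PairKey:
    return (a, b) if (a, b) <= (b, a) else (b, a)


class MIMatrix:
    """Residue-pair mutual information values (nats) with provenance.

    Symmetric in the pair, diagonal excluded; ``provenance`` records which
    (run, monomer) unit supplied each value after max-aggregation.
    """

    def __init__(self) -> None:
        self._values: dict[PairKey, float] = {}
        self._provenance: dict[PairKey, str] = {}
        self._resnames: dict[ResidueKey, str] = {}
        self._segments: dict[ResidueKey, str] = {}

    def set(self, a: ResidueKey, b: ResidueKey, value: float,
            provenance: str = "", *,
            resname_a: str = "", resname_b: str = "",
            segment_a: str = "", segment_b: str = "") -> None:
        if a == b:
            raise SelectionError("diagonal entries are excluded from an MIMatrix")
        if value < 0:
            raise ValueError("mutual information values must be non-negative")
        key = _canonical_pair(a, b)
        self._values[key] = float(value)
        self._provenance[key] = provenance
        if resname_a:
            self._resnames[a] = resname_a
        if resname_b:
            self._resnames[b] = resname_b
        if segment_a:
            self._segments[a] = segment_a
        if segment_b:
            self._segments[b] = segment_b

    def get(self, a: ResidueKey, b: ResidueKey) -> float:
        return self._values[_canonical_pair(a, b)]

    def provenance(self, a: ResidueKey, b: ResidueKey) -> str:
        return self._provenance[_canonical_pair(a, b)]

    def pairs(self) -> list[PairKey]:
        return list(self._values)

    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a, b in self._values:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def segment_of(self, residue: ResidueKey) -> str:
        return self._segments.get(residue, "")

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, pair: PairKey) -> bool:
        return _canonical_pair(*pair) in self._values

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (a, b), v in sorted(self._values.items()):
            rows.append({
                "chain_a": a[0], "resnum_a": a[1],
                "resname_a": self._resnames.get(a, ""),
                "chain_b": b[0], "resnum_b": b[1],
                "resname_b": self._resnames.get(b, ""),
                "mi_nats": v,
                "source": self._provenance.get((a, b), ""),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


# ---------------------------------------------------------------------------
# Estimators


def covariance(frames: FrameSet, selection: AtomSelection,
               ddof: int = 0) -> CoordinateSetCovariance:
    """Trajectory covariance of the selection's flattened coordinates.

    Plain trajectory averages are used, i.e. the population denominator T
    (``ddof=0``, the default); ``ddof=1`` switches to the unbiased T−1 form.
    Frames must already be superposed onto a common reference.
    """
    if frames.n_frames < 2:
        raise InsufficientFramesError(
            f"covariance needs at least 2 frames, got {frames.n_frames}"
        )
    X = frames.coordinates[:, selection.atom_indices, :].reshape(frames.n_frames, -1)
    mean = X.mean(axis=0)
    centered = X - mean
    matrix = centered.T @ centered / (frames.n_frames - ddof)
    matrix = 0.5 * (matrix + matrix.T)
    return CoordinateSetCovariance(
        atom_indices=selection.atom_indices.copy(),
        mean=mean,
        matrix=matrix,
        n_frames=frames.n_frames,
    )


def _entropy_from_matrix(matrix: np.ndarray,
                         eigenvalue_floor: float) -> EntropyValue:
    eigvals = np.linalg.eigvalsh(matrix)
    scale = max(float(eigvals[-1]), 1.0)
    if eigvals[0] < -1e-10 * scale:
        raise InvalidCovarianceError(
            f"covariance has negative eigenvalue {eigvals[0]:.3e}"
        )
    floor_applied = bool(np.any(eigvals < eigenvalue_floor))
    floored = np.maximum(eigvals, eigenvalue_floor)
    value = 0.5 * float(np.sum(np.log(floored) + _LN_2PIE))
    return EntropyValue(value=value, dimension=matrix.shape[0],
                        floor_applied=floor_applied)


def config_entropy(cov: CoordinateSetCovariance | np.ndarray,
                   eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR
                   ) -> EntropyValue:
    """Quasi-harmonic configurational entropy ½ ln|2πe C| in nats.

    Computed as ½ Σ_k ln(2πe λ_k) over the eigenvalue spectrum, each λ_k
    floored at ``eigenvalue_floor`` (Å²); ``floor_applied`` reports whether
    any eigenvalue was clamped.
    """
    matrix = cov.matrix if isinstance(cov, CoordinateSetCovariance) else np.asarray(cov, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InvalidCovarianceError("covariance must be a square matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-8 * max(1.0, float(np.abs(matrix).max()))):
        raise InvalidCovarianceError("covariance must be symmetric")
    return _entropy_from_matrix(matrix, eigenvalue_floor)


def pairwise_mi(frames: FrameSet,
                selection_a: AtomSelection,
                selection_b: AtomSelection,
                eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
                clip_negative: bool = True) -> float:
    """Mutual information H(A) + H(B) − H(A,B) between two atom groups, in nats.

    All three entropies use the same frames and the same eigenvalue floor.
    Sample MI is non-negative up to floor effects; tiny negative round-off is
    clipped to zero unless ``clip_negative`` is disabled.
    """
    if np.intersect1d(selection_a.atom_indices, selection_b.atom_indices).size:
        raise SelectionError("selections A and B overlap")
    # the joint covariance is kept in topology order (canonical for both
    # argument orders) so that MI(A,B) and MI(B,A) are bit-identical
    merged_indices = np.sort(np.concatenate([selection_a.atom_indices,
                                             selection_b.atom_indices]))
    merged = AtomSelection(
        merged_indices,
        tuple([("", 0)] * (len(selection_a) + len(selection_b))),
    )
    joint = covariance(frames, merged).matrix
    pos = {int(a): i for i, a in enumerate(merged_indices)}
    dims_a = np.concatenate(
        [np.arange(3) + 3 * pos[int(a)] for a in selection_a.atom_indices])
    dims_b = np.concatenate(
        [np.arange(3) + 3 * pos[int(b)] for b in selection_b.atom_indices])
    h_a = _entropy_from_matrix(joint[np.ix_(dims_a, dims_a)], eigenvalue_floor)
    h_b = _entropy_from_matrix(joint[np.ix_(dims_b, dims_b)], eigenvalue_floor)
    h_ab = _entropy_from_matrix(joint, eigenvalue_floor)
    mi = h_a.value + h_b.value - h_ab.value
    if clip_negative and mi < 0:
        mi = 0.0
    return mi


def _residue_selections(topology: Topology, segment: SegmentDef,
                        heavy_only: bool) -> dict[ResidueKey, AtomSelection]:
    """Per-residue atom selections (all heavy atoms by default) for a segment."""
    seg_sel = select(topology, segment, heavy_only=heavy_only)
    out: dict[ResidueKey, list[int]] = {}
    for idx, key in zip(seg_sel.atom_indices, seg_sel.residue_keys):
        out.setdefault(key, []).append(int(idx))
    return {
        key: AtomSelection(np.asarray(indices, dtype=np.intp),
                           tuple([key] * len(indices)))
        for key, indices in out.items()
    }


def mi_matrix(frames: FrameSet,
              segments: Sequence[SegmentDef],
              heavy_only: bool = True,
              eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
              include_intra: bool = False,
              stride: int | None = None,
              provenance: str = "") -> MIMatrix:
    """Residue-pair MI for every inter-segment pair across the given segments.

    One covariance over the union of all segment atoms is estimated once and
    sliced per pair, which makes the per-pair cost a small eigendecomposition.
    ``stride`` optionally subsamples frames for speed (default: none).
    """
    topo = frames.topology
    if stride is not None and stride > 1:
        frames = FrameSet(frames.coordinates[::stride],
                          frames.times[::stride], topo)
    residues: dict[ResidueKey, AtomSelection] = {}
    residue_segment: dict[ResidueKey, str] = {}
    for segment in segments:
        per_res = _residue_selections(topo, segment, heavy_only)
        if not per_res:
            raise SelectionError(f"segment {segment.name} selects no residues")
        for key, sel in per_res.items():
            if key in residues:
                raise SelectionError(
                    f"residue {key} appears in segments "
                    f"{residue_segment[key]} and {segment.name}"
                )
            residues[key] = sel
            residue_segment[key] = segment.name

    all_indices = np.sort(np.concatenate(
        [sel.atom_indices for sel in residues.values()]))
    union = AtomSelection(all_indices, tuple([("", 0)] * all_indices.size))
    big_cov = covariance(frames, union).matrix

    pos_of_atom = {int(a): i for i, a in enumerate(all_indices)}
    res_dims: dict[ResidueKey, np.ndarray] = {}
    for key, sel in residues.items():
        cols = np.concatenate(
            [np.arange(3) + 3 * pos_of_atom[int(a)] for a in sel.atom_indices])
        res_dims[key] = cols

    resname: dict[ResidueKey, str] = {}
    for key, sel in residues.items():
        resname[key] = str(topo.residue_name[sel.atom_indices[0]])

    # cache marginal entropies per residue
    h_single = {
        key: _entropy_from_matrix(big_cov[np.ix_(dims, dims)], eigenvalue_floor)
        for key, dims in res_dims.items()
    }

    result = MIMatrix()
    keys = list(residues)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            same_segment = residue_segment[a] == residue_segment[b]
            if same_segment and not include_intra:
                continue
            dims = np.concatenate([res_dims[a], res_dims[b]])
            h_ab = _entropy_from_matrix(big_cov[np.ix_(dims, dims)],
                                        eigenvalue_floor)
            mi = h_single[a].value + h_single[b].value - h_ab.value
            mi = max(mi, 0.0)
            result.set(a, b, mi, provenance,
                       resname_a=resname[a], resname_b=resname[b],
                       segment_a=residue_segment[a],
                       segment_b=residue_segment[b])
    return result


# ---------------------------------------------------------------------------
# Aggregation


def relabel_chains(matrix: MIMatrix, chain_id: str) -> MIMatrix:
    """Map every residue key onto one canonical chain label.

    Monomers of a homotetramer carry the same residue numbering on different
    chains; relabelling makes their matrices max-aggregable per residue pair.
    """
    out = MIMatrix()
    for a, b in matrix.pairs():
        a2, b2 = (chain_id, a[1]), (chain_id, b[1])
        out.set(a2, b2, matrix.get(a, b), matrix.provenance(a, b),
                resname_a=matrix._resnames.get(a, ""),
                resname_b=matrix._resnames.get(b, ""),
                segment_a=matrix.segment_of(a),
                segment_b=matrix.segment_of(b))
    return out


def aggregate_max(matrices: Mapping[str, MIMatrix]) -> MIMatrix:
    """Entrywise maximum over (run, monomer) units, recording the arg-max.

    All inputs must share the same residue-pair index up to per-monomer chain
    relabelling handled upstream; provenance records which unit supplied each
    surviving value.
    """
    if not matrices:
        raise AggregationError("no matrices to aggregate")
    labels = list(matrices)
    reference_pairs = set(matrices[labels[0]].pairs())
    for label in labels[1:]:
        if set(matrices[label].pairs()) != reference_pairs:
            raise AggregationError(
                f"matrix {label!r} has a different residue-pair index"
            )
    out = MIMatrix()
    first = matrices[labels[0]]
    for a, b in sorted(reference_pairs):
        best_label = max(labels, key=lambda lab: matrices[lab].get(a, b))
        # max() keeps the first label on ties: deterministic in input order
        out.set(a, b, matrices[best_label].get(a, b), best_label,
                resname_a=first._resnames.get(a, ""),
                resname_b=first._resnames.get(b, ""),
                segment_a=first.segment_of(a),
                segment_b=first.segment_of(b))
    return out


def segment_pair_mean(max_matrix: MIMatrix,
                      segment_a: SegmentDef | str,
                      segment_b: SegmentDef | str) -> SegmentPairSummary:
    """Mean of per-residue best-partner MI values for a segment pair.

    For each residue of either segment, its maximum MI to any residue of the
    partner segment is taken; ``mean_of_maxima`` is the arithmetic mean of
    those per-residue maxima over both segments' residues.
    """
    name_a = segment_a.name if isinstance(segment_a, SegmentDef) else segment_a
    name_b = segment_b.name if isinstance(segment_b, SegmentDef) else segment_b
    res_a = [r for r in max_matrix.residues() if max_matrix.segment_of(r) == name_a]
    res_b = [r for r in max_matrix.residues() if max_matrix.segment_of(r) == name_b]
    if not res_a or not res_b:
        raise AggregationError(
            f"segments {name_a!r}/{name_b!r} not present in matrix index"
        )
    per_residue: dict[ResidueKey, float] = {}
    for r in res_a:
        vals = [max_matrix.get(r, p) for p in res_b if (r, p) in max_matrix]
        if vals:
            per_residue[r] = max(vals)
    for r in res_b:
        vals = [max_matrix.get(r, p) for p in res_a if (r, p) in max_matrix]
        if vals:
            per_residue[r] = max(vals)
    if not per_residue:
        raise AggregationError(
            f"no residue pairs between segments {name_a!r} and {name_b!r}"
        )
    mean = float(np.mean(list(per_residue.values())))
    return SegmentPairSummary(name_a, name_b, per_residue, mean)


def top_pairs(max_matrix: MIMatrix, k: int,
              min_value: float = 0.0) -> list[tuple[PairKey, float]]:
    """The k strongest residue pairs, descending, with a documented tie-break.

    Ties on the MI value are broken by the residue number of the first, then
    the second, member of the pair (ascending).  Pairs below ``min_value``
    are dropped, so fewer than k entries may be returned.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    entries = [
        ((a, b), max_matrix.get(a, b))
        for a, b in max_matrix.pairs()
        if max_matrix.get(a, b) >= min_value
    ]
    entries.sort(key=lambda item: (-item[1], item[0][0][1], item[0][1][1],
                                   item[0][0][0], item[0][1][0]))
    return entries[:k]
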