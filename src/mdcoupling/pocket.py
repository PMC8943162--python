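"""Binding-pocket openness: width series, state classification, occupancy.

The electrophile-binding pocket of TRPA1 is enclosed by two mobile lids; its
openness is quantified as the Cα–Cα distance between K610 (lower lid) and
L667 (upper lid).  Deposited structures put this width at 15.5 Å when the
pocket is open and 9.4 Å when closed, and a frame is classified *closed*
when the width is strictly below an 11 Å cutoff.  Occupancies are pooled,
time-weighted fractions over replicate (run × monomer) units, reported in
percent with the standard deviation across units as the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, LookupFailure
from .trajectory import AtomSelection, FrameSet, Topology

__all__ = [
    "PocketSeries",
    "OccupancySummary",
    "DEFAULT_CUTOFF",
    "DEFAULT_RESIDUE_PAIR",
    "pocket_width_series",
    "structure_pocket_width",
    "moving_average",
    "classify_states",
    "occupancy",
    "out_of_pocket_occupancy",
]

#: Pocket open/closed classification cutoff on the lid Cα–Cα distance (Å).
DEFAULT_CUTOFF = 11.0

#: Lower-lid / upper-lid residue numbers defining the pocket width.
DEFAULT_RESIDUE_PAIR = (610, 667)


@dataclass
class PocketSeries:
    """Per-frame pocket width (Å) for one monomer."""

    monomer_id: str
    times: np.ndarray
    widths: np.ndarray
    residue_pair: tuple[tuple[str, int], tuple[str, int]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.times.shape != self.widths.shape:
            raise ValueError("times and widths must align")
        if not np.all(np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise ValueError("pocket widths must be positive and finite")

    def to_dataframe(self, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times,
            "width_A": self.widths,
            "state": np.where(self.widths < cutoff, "closed", "open"),
        })


@dataclass(frozen=True)
class OccupancySummary:
    """Pooled closed-state population (percent) with dispersion across units."""

    scenario: str
    fraction_closed: float
    dispersion: float
    n_units: int
    total_time_us: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_closed <= 100.0:
            raise ValueError("fraction_closed must lie in [0, 100]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def _calpha_index(topology: Topology, chain: str, resnum: int) -> int:
    try:
        return topology.atom_index(chain, resnum, "CA")
    except LookupFailure:
        raise LookupFailure(
            f"Cα atom of residue {resnum} on chain {chain} is missing"
        ) from None


def pocket_width_series(frames: FrameSet, monomer: str,
                        residue_pair: tuple[int, int] = DEFAULT_RESIDUE_PAIR
                        ) -> PocketSeries:
    """Per-frame lid Cα–Cα distance for one monomer chain.

    Distances are invariant under rigid motion, so no prior alignment is
    needed.
    """
    lo, hi = residue_pair
    i = _calpha_index(frames.topology, monomer, lo)
    j = _calpha_index(frames.topology, monomer, hi)
    deltas = frames.coordinates[:, i, :] - frames.coordinates[:, j, :]
    widths = np.linalg.norm(deltas, axis=1)
    return PocketSeries(
        monomer_id=monomer,
        times=frames.times.copy(),
        widths=widths,
        residue_pair=((monomer, lo), (monomer, hi)),
    )


def structure_pocket_width(topology: Topology, coordinates: np.ndarray,
                           monomer: str,
                           residue_pair: tuple[int, int] = DEFAULT_RESIDUE_PAIR
                           ) -> float:
    """Lid Cα–Cα distance (Å) for a single structure, e.g. a deposited model."""
    lo, hi = residue_pair
    i = _calpha_index(topology, monomer, lo)
    j = _calpha_index(topology, monomer, hi)
    return float(np.linalg.norm(coordinates[i] - coordinates[j]))


def moving_average(series: PocketSeries, window_ns: float) -> PocketSeries:
    """Centered moving average over a ±window/2 time window, for plotting.

    Edge frames use the truncated window; times are unchanged.  A window
    smaller than the frame spacing returns the series unchanged.
    """
    if window_ns <= 0:
        raise ValueError("window must be positive")
    t = series.times
    half = window_ns / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(series.widths)])
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return PocketSeries(series.monomer_id, t.copy(), smoothed,
                        series.residue_pair)


def classify_states(series: PocketSeries,
                    cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean closed-state flags: closed iff width < cutoff (strict).

    A width exactly at the cutoff is open.  Applied to the raw series by
    default; smoothing is for plotting only.
    """
    return series.widths < cutoff


def _frame_weights(times: np.ndarray) -> np.ndarray:
    """Per-frame time weights: the spacing to the next frame, last = previous."""
    if times.size == 1:
        return np.ones(1)
    dt = np.diff(times)
    return np.concatenate([dt, dt[-1:]])


def occupancy(state_series_set: Sequence[tuple[np.ndarray, np.ndarray]],
              scenario: str = "",
              dispersion_over: str = "units",
              run_labels: Sequence[str] | None = None) -> OccupancySummary:
    """Pooled closed-state occupancy over replicate (run × monomer) units.

    Each element is a ``(times_ns, closed_flags)`` pair.  ``fraction_closed``
    is the time-weighted pooled fraction in percent.  ``dispersion`` is the
    sample standard deviation of the per-unit fractions; with
    ``dispersion_over="runs"`` and per-unit ``run_labels``, monomer units are
    pooled per run first and the deviation is taken across runs instead.
    ``total_time_us`` sums the unit durations.
    """
    if len(state_series_set) == 0:
        raise EmptyInputError("occupancy needs at least one state series")
    if dispersion_over not in ("units", "runs"):
        raise ValueError("dispersion_over must be 'units' or 'runs'")
    if dispersion_over == "runs" and (
            run_labels is None or len(run_labels) != len(state_series_set)):
        raise ValueError("dispersion_over='runs' needs one run label per unit")
    closed_time = 0.0
    total_time = 0.0
    unit_closed_times = []
    unit_totals = []
    for times, states in state_series_set:
        times = np.asarray(times, dtype=float)
        states = np.asarray(states, dtype=bool)
        w = _frame_weights(times)
        unit_total = float(w.sum())
        unit_closed = float(w[states].sum())
        closed_time += unit_closed
        total_time += unit_total
        unit_closed_times.append(unit_closed)
        unit_totals.append(unit_total)
    fraction = 100.0 * closed_time / total_time
    if dispersion_over == "runs":
        groups: dict[str, list[int]] = {}
        for i, label in enumerate(run_labels):  # type: ignore[arg-type]
            groups.setdefault(str(label), []).append(i)
        group_fractions = [
            100.0 * sum(unit_closed_times[i] for i in idx)
            / sum(unit_totals[i] for i in idx)
            for idx in groups.values()
        ]
    else:
        group_fractions = [
            100.0 * c / t for c, t in zip(unit_closed_times, unit_totals)
        ]
    if len(group_fractions) > 1:
        dispersion = float(np.std(group_fractions, ddof=1))
    else:
        dispersion = 0.0
    return OccupancySummary(
        scenario=scenario,
        fraction_closed=fraction,
        dispersion=dispersion,
        n_units=len(state_series_set),
        total_time_us=total_time / 1000.0,
    )


def out_of_pocket_occupancy(frames: FrameSet,
                            ligand_selection: AtomSelection,
                            pocket_selection: AtomSelection,
                            contact_cutoff: float = 3.5) -> float:
    """Percent of frames with the ligand rotated out of the pocket.

    A frame counts as out-of-pocket when the minimum heavy-atom distance
    between the ligand and the pocket-defining atoms exceeds
    ``contact_cutoff`` (Å).
    """
    if len(ligand_selection) == 0 or len(pocket_selection) == 0:
        raise EmptyInputError("ligand and pocket selections must be non-empty")
    lig = frames.coordinates[:, ligand_selection.atom_indices, :]
    pocket = frames.coordinates[:, pocket_selection.atom_indices, :]
    out_frames = 0
    for t in range(frames.n_frames):
        min_dist = cdist(lig[t], pocket[t]).min()
        if min_dist > contact_cutoff:
            out_frames += 1
    return 100.0 * out_frames / frames.n_frames
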