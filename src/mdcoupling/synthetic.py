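"""Synthetic trajectories with known ground truth.

MD studies rarely deposit their trajectories, so every analysis stage in
this package is validated against generated data whose answer is known in
closed form:

* stationary multivariate-Gaussian heavy-atom fluctuations around a
  reference structure with a user-specified covariance — the Gaussian MI of
  any coordinate block pair is then analytic;
* two-state (open/closed) Markov-switching pocket widths with Gaussian
  observation noise — the stationary closed fraction is
  k_oc / (k_oc + k_co);
* toy pore geometries (stacked atom rings) whose maximal probe radius at a
  ring's z is exactly ring_radius − vdW;
* rigid-motion trajectories for superposition tests.

Every generator is a pure function of its spec plus a seed: reruns are
bit-identical, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .pocket import PocketSeries
from .pore import VdwTable
from .trajectory import FrameSet, Topology

__all__ = [
    "GaussianTrajectorySpec",
    "MarkovPocketSpec",
    "MarkovPocketResult",
    "gen_gaussian_trajectory",
    "gen_coupled_pair",
    "gen_markov_pocket",
    "pocket_frameset_from_widths",
    "gen_toy_pore",
    "gen_rigid_motion",
    "make_chain_topology",
    "trpa1_like_fixture",
]

# Heavy-atom names of an alanine residue (N, CA, C, O, CB): 5 atoms.
_ALA_HEAVY = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))


def make_chain_topology(chain_id: str,
                        residue_ranges: Sequence[tuple[int, int]],
                        res_name: str = "ALA") -> Topology:
    """A poly-alanine-like chain covering the given residue-number ranges.

    Each residue carries the 5 heavy atoms of alanine; used to build desk-
    scale stand-ins whose residue numbering matches the channel's.
    """
    names, resnums, resnames, chains, elements = [], [], [], [], []
    for first, last in residue_ranges:
        for resnum in range(first, last + 1):
            for atom_name, element in _ALA_HEAVY:
                names.append(atom_name)
                resnums.append(resnum)
                resnames.append(res_name)
                chains.append(chain_id)
                elements.append(element)
    n = len(names)
    return Topology(
        atom_name=np.array(names, dtype="U6"),
        residue_number=np.array(resnums, dtype=np.int64),
        residue_name=np.array(resnames, dtype="U5"),
        chain_id=np.array(chains, dtype="U4"),
        element=np.array(elements, dtype="U4"),
        is_hetero=np.zeros(n, dtype=bool),
    )


def merge_topologies(topologies: Sequence[Topology]) -> Topology:
    return Topology(
        atom_name=np.concatenate([t.atom_name for t in topologies]),
        residue_number=np.concatenate([t.residue_number for t in topologies]),
        residue_name=np.concatenate([t.residue_name for t in topologies]),
        chain_id=np.concatenate([t.chain_id for t in topologies]),
        element=np.concatenate([t.element for t in topologies]),
        is_hetero=np.concatenate([t.is_hetero for t in topologies]),
    )


@dataclass(frozen=True)
class GaussianTrajectorySpec:
    """Stationary Gaussian fluctuations around a reference structure."""

    topology: Topology
    reference_coords: np.ndarray     # N×3 Å
    covariance: np.ndarray           # 3N×3N Å²
    n_frames: int
    seed: int
    dt_ns: float = 0.1

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        ref = np.asarray(self.reference_coords, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if ref.shape != (n, 3):
            raise SpecError("reference_coords must be N×3")
        if cov.shape != (3 * n, 3 * n):
            raise SpecError("covariance must be 3N×3N")
        if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
            raise SpecError("covariance must be symmetric")
        if self.n_frames < 1:
            raise SpecError("n_frames must be ≥ 1")


def _covariance_sqrt(cov: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(cov)
    scale = max(float(eigvals[-1]), 1.0)
    if eigvals[0] < -1e-10 * scale:
        raise SpecError(
            f"covariance is not PSD (eigenvalue {eigvals[0]:.3e})"
        )
    return eigvecs * np.sqrt(np.maximum(eigvals, 0.0))


def gen_gaussian_trajectory(spec: GaussianTrajectorySpec) -> FrameSet:
    """Frames = reference + seeded Gaussian draws with the spec covariance."""
    rng = np.random.default_rng(spec.seed)
    n = spec.topology.n_atoms
    sqrt_cov = _covariance_sqrt(np.asarray(spec.covariance, dtype=float))
    draws = rng.standard_normal((spec.n_frames, 3 * n)) @ sqrt_cov.T
    coords = (np.asarray(spec.reference_coords, dtype=float)[None]
              + draws.reshape(spec.n_frames, n, 3))
    times = spec.dt_ns * np.arange(spec.n_frames, dtype=float)
    return FrameSet(coords, times, spec.topology)


def gen_coupled_pair(rho: float, d_per_block: int, n_frames: int,
                     seed: int) -> tuple[FrameSet, float]:
    """Two pseudo-residues with matched coordinates correlated at ρ.

    Residues 1 and 2 on chain A each carry ``d_per_block`` atoms; the x
    coordinate of atom m of residue 1 is correlated at ρ with the x
    coordinate of atom m of residue 2, all other coordinates are independent
    unit-variance noise.  The Gaussian MI between the residues is then
    analytic: −(d_per_block/2)·ln(1−ρ²) nats.
    """
    if not abs(rho) < 1:
        raise SpecError("|rho| must be < 1")
    if d_per_block < 1:
        raise SpecError("d_per_block must be ≥ 1")
    rng = np.random.default_rng(seed)
    n_atoms = 2 * d_per_block
    coords = rng.standard_normal((n_frames, n_atoms, 3))
    shared = rng.standard_normal((n_frames, d_per_block))
    fresh_a = coords[:, :d_per_block, 0]
    fresh_b = coords[:, d_per_block:, 0]
    mix = np.sqrt(abs(rho))
    keep = np.sqrt(1.0 - abs(rho))
    sign = np.sign(rho) if rho != 0 else 1.0
    coords[:, :d_per_block, 0] = keep * fresh_a + mix * shared
    coords[:, d_per_block:, 0] = keep * fresh_b + sign * mix * shared

    names = [f"X{m+1}" for m in range(d_per_block)]
    topo = Topology(
        atom_name=np.array(names * 2, dtype="U6"),
        residue_number=np.array([1] * d_per_block + [2] * d_per_block,
                                dtype=np.int64),
        residue_name=np.array(["GSA"] * n_atoms, dtype="U5"),
        chain_id=np.array(["A"] * n_atoms, dtype="U4"),
        element=np.array(["C"] * n_atoms, dtype="U4"),
        is_hetero=np.zeros(n_atoms, dtype=bool),
    )
    frames = FrameSet(coords, np.arange(n_frames, dtype=float), topo)
    analytic_mi = -(d_per_block / 2.0) * np.log(1.0 - rho * rho)
    return frames, float(analytic_mi)


@dataclass(frozen=True)
class MarkovPocketSpec:
    """Two-state Markov-switching pocket width with observation noise.

    Mean widths default to the deposited pocket-open (15.5 Å) and
    pocket-closed (9.4 Å) structure values; ``noise_sd`` models within-state
    thermal fluctuation of the lid Cα–Cα distance.
    """

    rate_open_to_closed: float       # per ns
    rate_closed_to_open: float       # per ns
    mean_open: float = 15.5
    mean_closed: float = 9.4
    noise_sd: float = 0.7
    duration_ns: float = 1000.0
    dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_open_to_closed < 0 or self.rate_closed_to_open < 0:
            raise SpecError("rates must be non-negative")
        if self.mean_open <= 0 or self.mean_closed <= 0:
            raise SpecError("state means must be positive")
        if self.dt_ns <= 0 or self.duration_ns <= 0:
            raise SpecError("duration and dt must be positive")
        fastest = max(self.rate_open_to_closed, self.rate_closed_to_open)
        if fastest > 0 and self.dt_ns > 0.1 / fastest:
            raise SpecError(
                "dt must be ≪ 1/max(rate) (dt·rate ≤ 0.1) for the "
                "discretised chain to match the continuous-time rates"
            )


@dataclass(frozen=True)
class MarkovPocketResult:
    series: PocketSeries
    true_states: np.ndarray          # True where closed
    true_closed_fraction: float


def gen_markov_pocket(spec: MarkovPocketSpec,
                      monomer_id: str = "A") -> MarkovPocketResult:
    """Sampled two-state chain with stationary closed fraction k_oc/(k_oc+k_co).

    The per-step switching probabilities are rate·dt, which leaves the
    stationary distribution of the discretised chain exactly at the
    continuous-time value; the initial state is drawn from it.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_ns / spec.dt_ns))
    p_oc = spec.rate_open_to_closed * spec.dt_ns
    p_co = spec.rate_closed_to_open * spec.dt_ns
    total = spec.rate_open_to_closed + spec.rate_closed_to_open
    pi_closed = (spec.rate_open_to_closed / total) if total > 0 else 0.0

    closed = np.empty(n_steps, dtype=bool)
    state = bool(rng.random() < pi_closed)
    uniforms = rng.random(n_steps)
    for i in range(n_steps):
        closed[i] = state
        if state:
            if uniforms[i] < p_co:
                state = False
        else:
            if uniforms[i] < p_oc:
                state = True
    widths = np.where(closed, spec.mean_closed, spec.mean_open)
    widths = widths + spec.noise_sd * rng.standard_normal(n_steps)
    times = spec.dt_ns * np.arange(n_steps, dtype=float)
    series = PocketSeries(
        monomer_id=monomer_id,
        times=times,
        widths=np.maximum(widths, 1e-3),
        residue_pair=((monomer_id, 610), (monomer_id, 667)),
    )
    return MarkovPocketResult(series, closed, float(pi_closed))


def pocket_frameset_from_widths(series: PocketSeries) -> FrameSet:
    """A minimal 2-residue FrameSet realising a pocket-width series.

    The lower-lid Cα sits at the origin and the upper-lid Cα at
    (width, 0, 0), so ``pocket_width_series`` recovers the input exactly;
    used to drive the frame-based pipeline from a width series.
    """
    chain = series.monomer_id
    (_, lo), (_, hi) = series.residue_pair
    topo = Topology(
        atom_name=np.array(["CA", "CA"], dtype="U6"),
        residue_number=np.array([lo, hi], dtype=np.int64),
        residue_name=np.array(["LYS", "LEU"], dtype="U5"),
        chain_id=np.array([chain, chain], dtype="U4"),
        element=np.array(["C", "C"], dtype="U4"),
        is_hetero=np.zeros(2, dtype=bool),
    )
    n = series.widths.size
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = series.widths
    return FrameSet(coords, series.times.copy(), topo)


def gen_toy_pore(ring_radii: Sequence[tuple[float, float]],
                 atoms_per_ring: int = 12,
                 vdw_element: str = "C",
                 vdw: VdwTable | None = None,
                 seed: int = 0) -> tuple[Topology, FrameSet, dict[float, float]]:
    """Stacked atom rings centred on the z axis with a known radius profile.

    Returns the topology, a single-frame FrameSet, and the true profile
    {ring z → ring_radius − vdW radius}.
    """
    if len(ring_radii) == 0:
        raise SpecError("need at least one ring")
    vdw = vdw or VdwTable()
    r_vdw = vdw.radius(vdw_element)
    for z, r in ring_radii:
        if r <= r_vdw:
            raise SpecError(
                f"ring at z={z} has radius {r} ≤ vdW radius {r_vdw}: "
                "the pore is degenerate"
            )
    names, resnums, coords = [], [], []
    angles = 2.0 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
    for ring_index, (z, r) in enumerate(ring_radii):
        for a_index, theta in enumerate(angles):
            names.append(f"A{a_index}")
            resnums.append(ring_index + 1)
            coords.append((r * np.cos(theta), r * np.sin(theta), z))
    n = len(names)
    topo = Topology(
        atom_name=np.array(names, dtype="U6"),
        residue_number=np.array(resnums, dtype=np.int64),
        residue_name=np.array(["RNG"] * n, dtype="U5"),
        chain_id=np.array(["P"] * n, dtype="U4"),
        element=np.array([vdw_element] * n, dtype="U4"),
        is_hetero=np.zeros(n, dtype=bool),
    )
    frames = FrameSet(np.asarray(coords, dtype=float)[None],
                      np.zeros(1), topo)
    true_profile = {float(z): float(r - r_vdw) for z, r in ring_radii}
    return topo, frames, true_profile


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_rigid_motion(reference: np.ndarray, n_frames: int, seed: int,
                     topology: Topology | None = None,
                     translation_scale: float = 5.0) -> FrameSet:
    """Frames that are seeded random rigid motions of a reference structure."""
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise SpecError("reference must be N×3 with N ≥ 3")
    rng = np.random.default_rng(seed)
    if topology is None:
        # one CA per residue: the default fixture doubles as a Cα trace
        n = ref.shape[0]
        topology = Topology(
            atom_name=np.array(["CA"] * n, dtype="U6"),
            residue_number=np.arange(1, n + 1, dtype=np.int64),
            residue_name=np.array(["PNT"] * n, dtype="U5"),
            chain_id=np.array(["A"] * n, dtype="U4"),
            element=np.array(["C"] * n, dtype="U4"),
            is_hetero=np.zeros(n, dtype=bool),
        )
    coords = np.empty((n_frames, ref.shape[0], 3))
    for t in range(n_frames):
        R = _random_rotation(rng)
        trans = translation_scale * rng.standard_normal(3)
        coords[t] = ref @ R.T + trans
    return FrameSet(coords, np.arange(n_frames, dtype=float), topology)


# ---------------------------------------------------------------------------
# The desk-scale channel-like fixture

#: Segment residue ranges mirroring the analysed channel regions: pocket lid,
#: S1 helix, S4–S5 span, and the TRP-like domain + S6 span.
CHANNEL_SEGMENTS = {
    "lid": (663, 676),
    "S1": (706, 730),
    "S4": (842, 865),
    "TRPL_S6": (961, 1005),
}

#: Default planted coupling: a lid residue to a loop residue above the pocket,
#: mirroring the kind of lid-to-pore-flank pair the analysis should surface.
DEFAULT_PLANTED_PAIR = (671, 988)


def trpa1_like_fixture(n_frames: int = 800,
                       seed: int = 0,
                       n_monomers: int = 4,
                       planted_pair: tuple[int, int] = DEFAULT_PLANTED_PAIR,
                       planted_rho: float = 0.95,
                       planted_coords: int = 3,
                       fluctuation_sd: float = 0.5) -> tuple[FrameSet, float]:
    """A 4-pseudo-monomer channel-like trajectory with one planted coupling.

    Each monomer chain (A, B, …) carries the four analysed segments with the
    channel's residue numbering, 5 heavy atoms per residue, independent
    Gaussian fluctuations of ``fluctuation_sd`` Å around a spread-out
    reference — except the planted residue pair, whose first
    ``planted_coords`` coordinates share a latent mode at correlation
    ``planted_rho`` (same construction as :func:`gen_coupled_pair`).
    Returns the FrameSet and the planted pair's analytic MI,
    −(planted_coords/2)·ln(1−ρ²).
    """
    rng = np.random.default_rng(seed)
    chains = [chr(ord("A") + i) for i in range(n_monomers)]
    topos = [make_chain_topology(c, list(CHANNEL_SEGMENTS.values()))
             for c in chains]
    topo = merge_topologies(topos)
    n_atoms = topo.n_atoms

    # compact helix-like reference per chain (~protein-domain dimensions);
    # large lever arms would let fit noise induce common-mode correlations
    reference = np.zeros((n_atoms, 3))
    atoms_per_res = len(_ALA_HEAVY)
    for i in range(n_atoms):
        chain_index = ord(str(topo.chain_id[i])) - ord("A")
        res_index = (i % (topo.n_atoms // n_monomers)) // atoms_per_res
        atom_index = i % atoms_per_res
        theta = 0.6 * res_index
        reference[i] = (
            40.0 * chain_index + 9.0 * np.cos(theta) + 0.7 * atom_index,
            9.0 * np.sin(theta),
            0.45 * res_index,
        )

    coords = reference[None] + fluctuation_sd * rng.standard_normal(
        (n_frames, n_atoms, 3))

    lo, hi = planted_pair
    mix = np.sqrt(planted_rho)
    keep = np.sqrt(1.0 - planted_rho)
    for chain in chains:
        idx_lo = np.flatnonzero((topo.chain_id == chain)
                                & (topo.residue_number == lo))
        idx_hi = np.flatnonzero((topo.chain_id == chain)
                                & (topo.residue_number == hi))
        shared = rng.standard_normal((n_frames, planted_coords))
        for m in range(planted_coords):
            atom_a, dim_a = divmod(m, 3)
            atom_b, dim_b = divmod(m, 3)
            fresh_a = coords[:, idx_lo[atom_a], dim_a] - reference[idx_lo[atom_a], dim_a]
            fresh_b = coords[:, idx_hi[atom_b], dim_b] - reference[idx_hi[atom_b], dim_b]
            coords[:, idx_lo[atom_a], dim_a] = (
                reference[idx_lo[atom_a], dim_a]
                + keep * fresh_a + mix * fluctuation_sd * shared[:, m])
            coords[:, idx_hi[atom_b], dim_b] = (
                reference[idx_hi[atom_b], dim_b]
                + keep * fresh_b + mix * fluctuation_sd * shared[:, m])

    frames = FrameSet(coords, 0.1 * np.arange(n_frames, dtype=float), topo)
    analytic_mi = -(planted_coords / 2.0) * np.log(1.0 - planted_rho ** 2)
    return frames, float(analytic_mi)
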