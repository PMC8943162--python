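import numpy as np
import pytest

import mdcoupling as mc
from mdcoupling.errors import (
    AggregationError,
    InsufficientFramesError,
    InvalidCovarianceError,
    SelectionError,
)
from mdcoupling.mutualinfo import (
    MIMatrix,
    aggregate_max,
    config_entropy,
    covariance,
    mi_matrix,
    pairwise_mi,
    relabel_chains,
    segment_pair_mean,
    top_pairs,
)
from mdcoupling.synthetic import (
    GaussianTrajectorySpec,
    gen_coupled_pair,
    gen_gaussian_trajectory,
    make_chain_topology,
)
from mdcoupling.trajectory import AtomSelection, FrameSet, SegmentDef, Topology, select

H_1D_UNIT = 0.5 * np.log(2 * np.pi * np.e)   # ≈ 1.41894 nats


def single_atom_frames(x_values):
    """One atom moving along x only."""
    topo = make_chain_topology("A", [(1, 1)])
    coords = np.zeros((len(x_values), topo.n_atoms, 3))
    coords[:, 0, 0] = x_values
    return FrameSet(coords, np.arange(len(x_values), dtype=float), topo)


def residue_selection(frames, resnum, chain="A"):
    return select(frames.topology,
                  SegmentDef(f"r{resnum}", chain, resnum, resnum))


class TestCovariance:
    def test_static_coordinates_give_zero(self):
        frames = single_atom_frames([1.5, 1.5, 1.5])
        sel = residue_selection(frames, 1)
        cov = covariance(frames, sel)
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-14)

    def test_two_frame_variance_population_form(self):
        # x ∈ {0, 2}: population var = 1 Å², all other entries 0
        frames = single_atom_frames([0.0, 2.0])
        sel = AtomSelection(np.array([0]), (("A", 1),))
        cov = covariance(frames, sel)
        expected = np.zeros((3, 3))
        expected[0, 0] = 1.0
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-14)

    def test_ddof_switch_matches_numpy(self):
        rng = np.random.default_rng(0)
        frames = single_atom_frames(rng.standard_normal(50))
        sel = AtomSelection(np.array([0]), (("A", 1),))
        pop = covariance(frames, sel).matrix[0, 0]
        unbiased = covariance(frames, sel, ddof=1).matrix[0, 0]
        x = frames.coordinates[:, 0, 0]
        assert pop == pytest.approx(np.var(x))
        assert unbiased == pytest.approx(np.var(x, ddof=1))

    def test_sampled_covariance_recovers_spec(self):
        """20,000 Gaussian frames recover a known 6×6 covariance within 5%."""
        topo = make_chain_topology("A", [(1, 1)])
        # use first 2 atoms → d=6; build a full-rank PSD matrix
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 6))
        target = A @ A.T + 0.5 * np.eye(6)
        n = topo.n_atoms
        cov_full = 0.01 * np.eye(3 * n)
        cov_full[:6, :6] = target
        frames = gen_gaussian_trajectory(GaussianTrajectorySpec(
            topology=topo,
            reference_coords=np.zeros((n, 3)),
            covariance=cov_full,
            n_frames=20000,
            seed=17,
        ))
        sel = AtomSelection(np.array([0, 1]), (("A", 1), ("A", 1)))
        sample = covariance(frames, sel).matrix
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        np.testing.assert_allclose(sample / scale, target / scale, atol=0.05)

    def test_single_frame_rejected(self):
        frames = single_atom_frames([1.0])
        sel = AtomSelection(np.array([0]), (("A", 1),))
        with pytest.raises(InsufficientFramesError):
            covariance(frames, sel)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(3)
        frames = single_atom_frames(rng.standard_normal(100))
        frames.coordinates[:, :, 1] = rng.standard_normal((100, frames.n_atoms))
        sel = AtomSelection(np.arange(frames.n_atoms),
                            tuple(frames.topology.residue_key(i)
                                  for i in range(frames.n_atoms)))
        m = covariance(frames, sel).matrix
        np.testing.assert_allclose(m, m.T, atol=1e-14)
        assert np.linalg.eigvalsh(m).min() >= -1e-10


class TestConfigEntropy:
    def test_unit_variance_1d(self):
        h = config_entropy(np.array([[1.0]]))
        assert h.value == pytest.approx(H_1D_UNIT, abs=1e-12)
        assert not h.floor_applied

    @pytest.mark.parametrize("d", [2, 3, 10])
    def test_identity_covariance_scales_with_dimension(self, d):
        h = config_entropy(np.eye(d))
        assert h.value == pytest.approx(d * H_1D_UNIT, abs=1e-9)
        assert h.dimension == d

    def test_variance_4_adds_ln2(self):
        h = config_entropy(np.array([[4.0]]))
        assert h.value == pytest.approx(H_1D_UNIT + np.log(2.0), abs=1e-12)

    def test_floor_applied_on_singular(self):
        cov = np.diag([1.0, 0.0])
        h = config_entropy(cov, eigenvalue_floor=1e-8)
        assert h.floor_applied
        assert h.value == pytest.approx(
            H_1D_UNIT + 0.5 * (np.log(1e-8) + np.log(2 * np.pi * np.e)),
            abs=1e-9)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(InvalidCovarianceError):
            config_entropy(np.diag([1.0, -0.5]))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InvalidCovarianceError):
            config_entropy(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestPairwiseMI:
    def test_closed_form_correlated_pair(self):
        """ρ=0.9 matched coordinates: population MI = −½ln(1−0.81)."""
        frames, analytic = gen_coupled_pair(0.9, 1, 50000, seed=7)
        assert analytic == pytest.approx(0.8304, abs=1e-4)
        sa = residue_selection(frames, 1)
        sb = residue_selection(frames, 2)
        mi = pairwise_mi(frames, sa, sb)
        assert mi == pytest.approx(analytic, abs=0.02)

    def test_independent_blocks_near_zero(self):
        frames, analytic = gen_coupled_pair(0.0, 1, 50000, seed=11)
        assert analytic == 0.0
        mi = pairwise_mi(frames, residue_selection(frames, 1),
                         residue_selection(frames, 2))
        assert 0.0 <= mi <= 0.05

    def test_symmetry_exact(self):
        frames, _ = gen_coupled_pair(0.5, 2, 2000, seed=3)
        sa = residue_selection(frames, 1)
        sb = residue_selection(frames, 2)
        assert pairwise_mi(frames, sa, sb) == pairwise_mi(frames, sb, sa)

    def test_overlapping_selections_rejected(self):
        frames, _ = gen_coupled_pair(0.5, 1, 100, seed=1)
        sa = residue_selection(frames, 1)
        with pytest.raises(SelectionError):
            pairwise_mi(frames, sa, sa)

    def test_duplicated_coordinates_floor_dependent(self):
        """B = A + 1 Å: singular joint covariance, large finite MI."""
        frames, _ = gen_coupled_pair(0.0, 1, 500, seed=9)
        coords = frames.coordinates.copy()
        coords[:, 1, :] = coords[:, 0, :] + 1.0
        dup = FrameSet(coords, frames.times, frames.topology)
        sa = residue_selection(dup, 1)
        sb = residue_selection(dup, 2)
        mi_loose = pairwise_mi(dup, sa, sb, eigenvalue_floor=1e-6)
        mi_tight = pairwise_mi(dup, sa, sb, eigenvalue_floor=1e-10)
        assert np.isfinite(mi_loose) and np.isfinite(mi_tight)
        assert mi_tight > mi_loose > 5.0

    def test_uniform_scaling_leaves_mi_unchanged(self):
        frames, _ = gen_coupled_pair(0.7, 2, 3000, seed=5)
        sa = residue_selection(frames, 1)
        sb = residue_selection(frames, 2)
        mi = pairwise_mi(frames, sa, sb, eigenvalue_floor=0.0)
        scaled = FrameSet(frames.coordinates * 3.7, frames.times,
                          frames.topology)
        mi_scaled = pairwise_mi(scaled, sa, sb, eigenvalue_floor=0.0)
        assert mi_scaled == pytest.approx(mi, abs=1e-8)

    def test_block_linear_maps_leave_mi_unchanged(self):
        frames, _ = gen_coupled_pair(0.6, 1, 3000, seed=6)
        sa = residue_selection(frames, 1)
        sb = residue_selection(frames, 2)
        mi = pairwise_mi(frames, sa, sb, eigenvalue_floor=0.0)
        rng = np.random.default_rng(0)
        La = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        Lb = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        coords = frames.coordinates.copy()
        coords[:, 0, :] = coords[:, 0, :] @ La.T
        coords[:, 1, :] = coords[:, 1, :] @ Lb.T
        mapped = FrameSet(coords, frames.times, frames.topology)
        mi_mapped = pairwise_mi(mapped, sa, sb, eigenvalue_floor=0.0)
        assert mi_mapped == pytest.approx(mi, abs=1e-6)


class TestMIMatrix:
    def test_two_by_two_combinatorics(self):
        frames, _ = gen_coupled_pair(0.4, 1, 500, seed=4)
        # two segments of one residue each → 1 inter-segment pair; widen:
        topo = make_chain_topology("A", [(1, 2), (11, 12)])
        rng = np.random.default_rng(8)
        coords = rng.standard_normal((400, topo.n_atoms, 3))
        fr = FrameSet(coords, np.arange(400, dtype=float), topo)
        segs = [SegmentDef("s1", "A", 1, 2), SegmentDef("s2", "A", 11, 12)]
        matrix = mi_matrix(fr, segs)
        assert len(matrix) == 4  # 2 × 2 inter-segment residue pairs
        a, b = ("A", 1), ("A", 11)
        assert matrix.get(a, b) == matrix.get(b, a)

    def test_planted_coupled_pair_attains_maximum(self):
        topo = make_chain_topology("A", [(1, 3), (11, 13)])
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((2000, topo.n_atoms, 3))
        # plant a shared mode between residue 2 and residue 12 (x of atom 0)
        i2 = np.flatnonzero(topo.residue_number == 2)[0]
        i12 = np.flatnonzero(topo.residue_number == 12)[0]
        shared = rng.standard_normal(2000)
        coords[:, i2, 0] = np.sqrt(0.1) * coords[:, i2, 0] + np.sqrt(0.9) * shared
        coords[:, i12, 0] = np.sqrt(0.1) * coords[:, i12, 0] + np.sqrt(0.9) * shared
        fr = FrameSet(coords, np.arange(2000, dtype=float), topo)
        matrix = mi_matrix(fr, [SegmentDef("s1", "A", 1, 3),
                                SegmentDef("s2", "A", 11, 13)])
        (top_a, top_b), _ = top_pairs(matrix, 1)[0]
        assert {top_a[1], top_b[1]} == {2, 12}

    def test_independent_residues_below_shuffled_null(self):
        """All-independent data: max MI below the 99th pct of a frame-shuffle null."""
        topo = make_chain_topology("A", [(1, 2), (11, 12)])
        rng = np.random.default_rng(23)
        coords = rng.standard_normal((3000, topo.n_atoms, 3))
        fr = FrameSet(coords, np.arange(3000, dtype=float), topo)
        segs = [SegmentDef("s1", "A", 1, 2), SegmentDef("s2", "A", 11, 12)]
        matrix = mi_matrix(fr, segs)
        observed_max = max(matrix.get(a, b) for a, b in matrix.pairs())
        null_max = []
        for p in range(100):
            perm = rng.permutation(3000)
            shuffled = coords.copy()
            # shuffle the second segment's frames relative to the first
            seg2 = np.isin(topo.residue_number, [11, 12])
            shuffled[:, seg2, :] = shuffled[perm][:, seg2, :]
            fr_s = FrameSet(shuffled, fr.times, topo)
            m_s = mi_matrix(fr_s, segs)
            null_max.append(max(m_s.get(a, b) for a, b in m_s.pairs()))
        assert observed_max <= np.quantile(null_max, 0.99)


class TestAggregation:
    @staticmethod
    def _matrix(value_ab, value_cd, provenance=""):
        m = MIMatrix()
        m.set(("A", 1), ("A", 11), value_ab, provenance,
              segment_a="s1", segment_b="s2")
        m.set(("A", 2), ("A", 12), value_cd, provenance,
              segment_a="s1", segment_b="s2")
        return m

    def test_entrywise_max_with_provenance(self):
        matrices = {
            "run1/A": self._matrix(3.0, 1.0, "run1/A"),
            "run2/A": self._matrix(5.0, 0.5, "run2/A"),
            "run3/A": self._matrix(4.0, 2.0, "run3/A"),
        }
        agg = aggregate_max(matrices)
        assert agg.get(("A", 1), ("A", 11)) == 5.0
        assert agg.provenance(("A", 1), ("A", 11)) == "run2/A"
        assert agg.get(("A", 2), ("A", 12)) == 2.0
        assert agg.provenance(("A", 2), ("A", 12)) == "run3/A"

    def test_single_matrix_is_identity(self):
        m = self._matrix(1.0, 2.0, "only")
        agg = aggregate_max({"only": m})
        for pair in m.pairs():
            assert agg.get(*pair) == m.get(*pair)

    def test_order_invariance(self):
        m1 = self._matrix(3.0, 1.0)
        m2 = self._matrix(5.0, 0.5)
        a = aggregate_max({"x": m1, "y": m2})
        b = aggregate_max({"y": m2, "x": m1})
        for pair in a.pairs():
            assert a.get(*pair) == b.get(*pair)

    def test_aggregated_dominates_inputs(self):
        matrices = {"u": self._matrix(3.0, 1.0), "v": self._matrix(2.0, 4.0)}
        agg = aggregate_max(matrices)
        for label, m in matrices.items():
            for pair in m.pairs():
                assert agg.get(*pair) >= m.get(*pair)

    def test_index_mismatch_rejected(self):
        m1 = self._matrix(1.0, 2.0)
        m2 = MIMatrix()
        m2.set(("A", 1), ("A", 99), 1.0)
        with pytest.raises(AggregationError):
            aggregate_max({"a": m1, "b": m2})

    def test_relabel_chains_canonicalises_monomers(self):
        m = MIMatrix()
        m.set(("B", 1), ("B", 11), 2.5, "run1/B",
              segment_a="s1", segment_b="s2")
        r = relabel_chains(m, "*")
        assert r.get(("*", 1), ("*", 11)) == 2.5
        assert r.segment_of(("*", 1)) == "s1"


class TestSegmentPairMean:
    @staticmethod
    def _worked_example():
        """2 residues per segment with pair values [[1,2],[3,4]]."""
        m = MIMatrix()
        values = {(1, 11): 1.0, (1, 12): 2.0, (2, 11): 3.0, (2, 12): 4.0}
        for (ra, rb), v in values.items():
            m.set(("A", ra), ("A", rb), v,
                  segment_a="segA", segment_b="segB")
        return m

    def test_worked_example_mean(self):
        summary = segment_pair_mean(self._worked_example(), "segA", "segB")
        # per-residue maxima: res1→2, res2→4, res11→3, res12→4; mean 3.25
        assert summary.mean_of_maxima == pytest.approx(3.25, abs=1e-12)
        assert summary.per_residue_max[("A", 1)] == 2.0
        assert summary.per_residue_max[("A", 11)] == 3.0

    def test_constant_matrix_gives_constant(self):
        m = MIMatrix()
        for ra in (1, 2):
            for rb in (11, 12):
                m.set(("A", ra), ("A", rb), 1.7,
                      segment_a="segA", segment_b="segB")
        summary = segment_pair_mean(m, "segA", "segB")
        assert summary.mean_of_maxima == pytest.approx(1.7)

    def test_dominated_pair_does_not_change_summary(self):
        base = segment_pair_mean(self._worked_example(), "segA", "segB")
        m = self._worked_example()
        m.set(("A", 1), ("A", 11), 0.5,  # strictly dominated update
              segment_a="segA", segment_b="segB")
        again = segment_pair_mean(m, "segA", "segB")
        assert again.mean_of_maxima == base.mean_of_maxima

    def test_mean_within_min_max_of_maxima(self):
        summary = segment_pair_mean(self._worked_example(), "segA", "segB")
        maxima = list(summary.per_residue_max.values())
        assert min(maxima) <= summary.mean_of_maxima <= max(maxima)

    def test_missing_segment_rejected(self):
        with pytest.raises(AggregationError):
            segment_pair_mean(self._worked_example(), "segA", "nope")


class TestTopPairs:
    @staticmethod
    def _matrix():
        m = MIMatrix()
        m.set(("A", 5), ("A", 20), 2.0)   # AB
        m.set(("A", 3), ("A", 30), 5.0)   # CD
        m.set(("A", 4), ("A", 10), 5.0)   # EF (tie with CD)
        return m

    def test_tie_break_on_residue_number(self):
        ranked = top_pairs(self._matrix(), 2)
        assert ranked[0][0] == (("A", 3), ("A", 30))
        assert ranked[1][0] == (("A", 4), ("A", 10))

    def test_min_value_filters_all(self):
        assert top_pairs(self._matrix(), 3, min_value=10.0) == []

    def test_k_exceeding_pairs_returns_all(self):
        assert len(top_pairs(self._matrix(), 99)) == 3

    def test_values_descending(self):
        ranked = top_pairs(self._matrix(), 3)
        values = [v for _, v in ranked]
        assert values == sorted(values, reverse=True)
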