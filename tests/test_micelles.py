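import numpy as np
import pytest

import helpers
from setsolv.engine import Trajectory, TrajectoryFrame
from setsolv.fixtures import MicelleFixtureSpec, generate_micelle_trajectory, model_amphiphile
from setsolv.micelles import (
    AggregateDistribution,
    aggregation_distribution,
    average_cmc,
    cluster_frame,
    cmc_from_trajectory,
    find_ncut,
)
from setsolv.units import molar_concentration


def two_molecule_traj(separation: float, box: float = 10.0) -> Trajectory:
    """Two single-tail-bead molecules a given tail distance apart."""
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + separation, 1.0, 1.0]])
    frame = TrajectoryFrame(step=1000, positions=pos, box=box)
    return Trajectory(
        frames=[frame],
        bead_names=["TL", "TL"],
        mol_ids=np.array([0, 1]),
        mol_names=["m", "m"],
        n_steps=2000,
        tail_beads=frozenset({"TL"}),
    )


def partition_set(aggregates):
    return {frozenset(int(m) for m in agg) for agg in aggregates}


class TestClusterFrame:
    def test_contact_pair_merges(self):
        traj = two_molecule_traj(0.9)
        aggs = cluster_frame(traj.frames[0], traj, cutoff=1.0)
        assert partition_set(aggs) == {frozenset({0, 1})}

    def test_distant_pair_stays_separate(self):
        traj = two_molecule_traj(1.5)
        aggs = cluster_frame(traj.frames[0], traj, cutoff=1.0)
        assert partition_set(aggs) == {frozenset({0}), frozenset({1})}

    def test_contact_across_periodic_boundary(self):
        pos = np.array([[0.2, 5.0, 5.0], [9.9, 5.0, 5.0]])
        frame = TrajectoryFrame(step=1000, positions=pos, box=10.0)
        traj = two_molecule_traj(1.5)
        traj.frames = [frame]
        aggs = cluster_frame(frame, traj, cutoff=1.0)
        assert partition_set(aggs) == {frozenset({0, 1})}

    def test_no_surfactants_rejected(self):
        frame = TrajectoryFrame(step=0, positions=np.zeros((2, 3)), box=5.0)
        traj = Trajectory(
            frames=[frame],
            bead_names=["W", "W"],
            mol_ids=np.array([0, 1]),
            mol_names=["W", "W"],
            n_steps=100,
        )
        with pytest.raises(ValueError, match="no surfactant"):
            cluster_frame(frame, traj)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_union_find_oracle(self, seed):
        """Random 50-molecule frames agree with a brute-force clustering."""
        rng = np.random.default_rng(seed)
        _, top = model_amphiphile()
        box = 12.0
        n_mol = 50
        pos = []
        mol_ids = []
        names = []
        for m in range(n_mol):
            anchor = rng.random(3) * box
            for k, bead in enumerate(top.beads):
                pos.append((anchor + 0.3 * rng.normal(size=3)) % box)
                mol_ids.append(m)
                names.append(bead)
        pos = np.array(pos)
        frame = TrajectoryFrame(step=1000, positions=pos, box=box)
        traj = Trajectory(
            frames=[frame],
            bead_names=names,
            mol_ids=np.array(mol_ids),
            mol_names=[top.name] * n_mol,
            n_steps=2000,
            tail_beads=frozenset({"TL"}),
        )
        aggs = cluster_frame(frame, traj, cutoff=1.0)
        is_tail = np.array([n == "TL" for n in names])
        expected = helpers.brute_cluster(
            pos, box, np.array(mol_ids), is_tail, np.arange(n_mol), 1.0
        )
        assert partition_set(aggs) == set(expected)

    def test_permutation_invariance(self):
        spec = MicelleFixtureSpec(box=20.0, n_micelles=2, size_range=(8, 12),
                                  n_monomers=6, seed=3)
        traj, _ = generate_micelle_trajectory(spec, n_frames=1)
        frame = traj.frames[0]
        base = partition_set(cluster_frame(frame, traj))
        # permute bead storage order consistently
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(traj.bead_names))
        traj2 = Trajectory(
            frames=[TrajectoryFrame(frame.step, frame.positions[perm], frame.box)],
            bead_names=[traj.bead_names[i] for i in perm],
            mol_ids=traj.mol_ids[perm],
            mol_names=traj.mol_names,
            n_steps=traj.n_steps,
            tail_beads=traj.tail_beads,
        )
        assert partition_set(cluster_frame(traj2.frames[0], traj2)) == base

    def test_rigid_translation_invariance(self):
        spec = MicelleFixtureSpec(box=20.0, n_micelles=2, size_range=(8, 12),
                                  n_monomers=6, seed=4)
        traj, _ = generate_micelle_trajectory(spec, n_frames=1)
        frame = traj.frames[0]
        base = partition_set(cluster_frame(frame, traj))
        shifted = TrajectoryFrame(
            frame.step, (frame.positions + np.array([3.7, -1.2, 9.9])) % frame.box,
            frame.box,
        )
        assert partition_set(cluster_frame(shifted, traj)) == base


class TestDistribution:
    def test_planted_micelle_and_monomers_mass(self):
        spec = MicelleFixtureSpec(
            box=20.0, n_micelles=1, micelle_sizes=(20,), n_monomers=5, seed=1
        )
        traj, _ = generate_micelle_trajectory(spec, n_frames=4)
        dist = aggregation_distribution(traj, smoothing_window=1)
        nonzero = dict(zip(dist.sizes[dist.counts > 0], dist.counts[dist.counts > 0]))
        assert set(nonzero) == {1, 20}
        # molecule weighting: 5 monomers and 20 micellized molecules per frame
        assert nonzero[1] == 5 * dist.n_frames
        assert nonzero[20] == 20 * dist.n_frames

    def test_aggregate_weighting(self):
        spec = MicelleFixtureSpec(
            box=20.0, n_micelles=1, micelle_sizes=(20,), n_monomers=5, seed=1
        )
        traj, _ = generate_micelle_trajectory(spec, n_frames=4)
        dist = aggregation_distribution(traj, weighting="aggregate")
        nonzero = dict(zip(dist.sizes[dist.counts > 0], dist.counts[dist.counts > 0]))
        assert nonzero[20] == 1 * dist.n_frames

    def test_full_discard_rejected(self):
        spec = MicelleFixtureSpec(box=20.0, n_micelles=1, n_monomers=3, seed=2)
        traj, _ = generate_micelle_trajectory(spec, n_frames=3)
        with pytest.raises(ValueError, match="no frames"):
            aggregation_distribution(traj, discard_steps=traj.n_steps)

    def test_few_frames_warning_attached(self):
        spec = MicelleFixtureSpec(box=20.0, n_micelles=1, n_monomers=3, seed=2)
        traj, _ = generate_micelle_trajectory(spec, n_frames=3)
        dist = aggregation_distribution(traj)
        assert any("frames" in w for w in dist.warnings_)

    def test_per_frame_mass_balance(self):
        spec = MicelleFixtureSpec(box=24.0, n_micelles=3, size_range=(10, 20),
                                  n_monomers=7, seed=5)
        traj, _ = generate_micelle_trajectory(spec, n_frames=6)
        dist = aggregation_distribution(traj, smoothing_window=1)
        n_mol = (np.bincount(traj.mol_ids) > 1).sum()
        assert (dist.sizes * 0 + dist.counts).sum() == n_mol * dist.n_frames


class TestFindNcut:
    def test_constructed_minimum_between_modes(self):
        dist = AggregateDistribution.from_counts(
            {1: 100, 2: 30, 3: 5, 10: 0.5, 25: 40, 30: 35}
        )
        assert find_ncut(dist) == 10

    def test_strictly_decreasing_falls_back(self):
        dist = AggregateDistribution.from_counts({1: 10, 2: 6, 3: 3, 4: 1})
        with pytest.warns(UserWarning, match="fall"):
            assert find_ncut(dist) == 10

    def test_tie_breaks_toward_smaller_n(self):
        dist = AggregateDistribution.from_counts({1: 50, 4: 2, 6: 2, 9: 40})
        assert find_ncut(dist) == 4

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_gap_recovered(self, seed):
        """Fixtures with no aggregates in [8, 15] put N_cut inside the gap."""
        rng = np.random.default_rng(seed)
        small = (2, 3, 4, 5, 6, 7)  # submicellar sizes fill the low range
        big = tuple(int(s) for s in rng.integers(16, 26, size=3))
        spec = MicelleFixtureSpec(
            box=30.0, n_micelles=9, micelle_sizes=small + big,
            n_monomers=10, seed=seed,
        )
        traj, _ = generate_micelle_trajectory(spec, n_frames=4)
        dist = aggregation_distribution(traj)
        ncut = find_ncut(dist)
        assert 8 <= ncut <= 15


class TestCmc:
    def make_traj(self, n_free, seed=0):
        spec = MicelleFixtureSpec(
            box=26.0, n_micelles=2, micelle_sizes=(25, 30),
            n_monomers=n_free, seed=seed,
        )
        traj, _ = generate_micelle_trajectory(spec, n_frames=4)
        return traj

    def test_planted_free_count_conversion(self):
        traj = self.make_traj(12)
        est = cmc_from_trajectory(traj, n_cut=10)
        assert est.free_count_mean == 12
        assert est.cmc_molar == pytest.approx(molar_concentration(12, 26.0))
        assert est.flags == []

    def test_zero_free_flagged(self):
        traj = self.make_traj(0)
        est = cmc_from_trajectory(traj, n_cut=10)
        assert est.cmc_molar == 0.0
        assert any("no free" in f for f in est.flags)

    def test_ncut_above_all_aggregates_flagged(self):
        traj = self.make_traj(5)
        est = cmc_from_trajectory(traj, n_cut=50)
        assert any("exceeds" in f for f in est.flags)
        total = len(np.flatnonzero(np.bincount(traj.mol_ids) > 1))
        assert est.free_count_mean == total

    def test_multi_run_average(self):
        runs = [cmc_from_trajectory(self.make_traj(n, seed=n), 10)
                for n in (10, 12, 14)]
        for run, n in zip(runs, (10, 12, 14)):
            assert run.cmc_molar == pytest.approx(molar_concentration(n, 26.0))
        assert average_cmc(runs) == pytest.approx(molar_concentration(12, 26.0))

    def test_invalid_ncut_rejected(self):
        with pytest.raises(ValueError):
            cmc_from_trajectory(self.make_traj(3), n_cut=1)
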