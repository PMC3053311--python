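"""Trajectory observables: RMSd series, RMSF, clustering, DCCM, entropy, H-bonds."""

import numpy as np
import pytest
from scipy import constants

from ensdyn import (
    CoreDefinition, GeneratorSpec, Trajectory, cluster_average_linkage,
    compare_rmsf, dccm, entropy_from_eigenvalues, gen_gaussian_traj,
    gen_hbond_traj, gen_two_state_traj, hbond_occupancy, make_toy_chain,
    quasiharmonic_entropy, rmsd, rmsd_series, rmsf,
)
from ensdyn.synthetic_data import random_rotation, rigid_body_basis
from ensdyn.traj_metrics import CA_MASS, pairwise_rmsd_matrix

from conftest import SEED, naive_average_linkage, partition_from_labels


def internal_modes(xyz, n_modes, seed=7):
    """Random internal (rigid-free) orthonormal modes at a geometry."""
    B = rigid_body_basis(xyz)
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(xyz.size, n_modes))
    A -= B @ (B.T @ A)
    Q, _ = np.linalg.qr(A)
    return Q


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        chain = make_toy_chain(12)
        traj = Trajectory(topology=chain,
                          frames=np.tile(chain.coords, (5, 1, 1)))
        series = rmsd_series(traj, chain)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-9)

    def test_rigidly_rotated_frames_are_zero(self):
        chain = make_toy_chain(12)
        rng = np.random.default_rng(SEED)
        frames = np.stack([chain.coords @ random_rotation(rng).T
                           + rng.normal(scale=8.0, size=3) for _ in range(6)])
        series = rmsd_series(traj := Trajectory(topology=chain, frames=frames),
                             chain)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-9)

    def test_matches_per_frame_rmsd_calls(self):
        spec = GeneratorSpec(seed=SEED, n_residues=20, n_frames=15)
        traj, _ = gen_two_state_traj(spec, separation=5.0, jitter=0.4)
        ref = traj.topology
        series = rmsd_series(traj, ref)
        ids, frames = traj.ca_view()
        expect = [rmsd(frames[k], ref.ca_coords(ids), fit=True)
                  for k in range(traj.n_frames)]
        np.testing.assert_allclose(series["rmsd"], expect, atol=1e-9)


class TestRmsf:
    def test_rigid_trajectory_is_zero(self):
        chain = make_toy_chain(10)
        traj = Trajectory(topology=chain,
                          frames=np.tile(chain.coords, (8, 1, 1)))
        table = rmsf(traj)
        np.testing.assert_allclose(table["rmsf"], 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self):
        """Per-coordinate σ -> RMSF = √3 σ; rigid motion must not leak in."""
        sigma = 0.5
        spec = GeneratorSpec(seed=SEED, n_residues=100, n_frames=10_000)
        traj, _ = gen_gaussian_traj(spec, sigma ** 2 * np.eye(300),
                                    apply_rigid=True)
        table = rmsf(traj)
        assert table["rmsf"].mean() == pytest.approx(np.sqrt(3) * sigma,
                                                     rel=0.02)

    def test_planted_soft_residue(self):
        """A residue with doubled σ shows ~2x the RMSF of its neighbors."""
        n = 40
        sigma = np.full(n, 0.3)
        sigma[20] = 0.6
        cov = np.diag(np.repeat(sigma ** 2, 3))
        spec = GeneratorSpec(seed=SEED, n_residues=n, n_frames=8000)
        traj, _ = gen_gaussian_traj(spec, cov)
        table = rmsf(traj)
        soft = table.loc[table.residue_id == 21, "rmsf"].item()
        neighbors = table.loc[table.residue_id.isin((20, 22)), "rmsf"].mean()
        assert soft / neighbors == pytest.approx(2.0, rel=0.10)

    def test_empty_window_rejected(self):
        chain = make_toy_chain(5)
        traj = Trajectory(topology=chain,
                          frames=np.tile(chain.coords, (4, 1, 1)))
        with pytest.raises(ValueError):
            rmsf(traj, window=(3, 3))


class TestCompareRmsf:
    @staticmethod
    def make_group(seeds, stabilized=False, n_frames=300):
        out = []
        for s in seeds:
            sigma = np.full(50, 0.5)
            if stabilized:
                sigma[25:33] = 0.25    # residues 85-92 of a 60-109 chain
            cov = np.diag(np.repeat(sigma ** 2, 3))
            spec = GeneratorSpec(seed=s, n_residues=50, res_start=60,
                                 n_frames=n_frames)
            traj, _ = gen_gaussian_traj(spec, cov)
            out.append(traj)
        return out

    def test_identical_groups_flag_at_most_alpha_rate(self):
        group = self.make_group(range(6))
        other = self.make_group(range(100, 106))
        table = compare_rmsf(group, other, alpha=0.05)
        assert table["significant"].mean() <= 0.15

    def test_planted_stabilization_recovered(self):
        """σ halved on residues 85-92 in group B: >=90% of planted residues
        flagged over 20 seeded repeats, 6 vs 6 replicates."""
        hits = total = 0
        for rep in range(20):
            a = self.make_group(range(1000 + 10 * rep, 1006 + 10 * rep))
            b = self.make_group(range(5000 + 10 * rep, 5006 + 10 * rep),
                                stabilized=True)
            table = compare_rmsf(a, b)
            planted = table[table.residue_id.between(85, 92)]
            hits += int(planted["significant"].sum())
            total += len(planted)
        assert hits / total >= 0.90

    def test_single_replicate_rejected(self):
        group = self.make_group([1])
        with pytest.raises(ValueError, match="replicates"):
            compare_rmsf(group, group * 2)


class TestClustering:
    def test_identical_frames_single_cluster(self):
        chain = make_toy_chain(10)
        traj = Trajectory(topology=chain,
                          frames=np.tile(chain.coords, (7, 1, 1)))
        result = cluster_average_linkage(traj, n_clusters=1,
                                         references={"self": chain})
        assert result.sizes == {1: 7}
        assert result.rmsd_table["rmsd_self"].item() == pytest.approx(
            0.0, abs=1e-9)

    def test_two_state_label_recovery(self):
        spec = GeneratorSpec(seed=SEED, n_residues=50, n_frames=60)
        traj, truth = gen_two_state_traj(spec, separation=8.0, jitter=0.5)
        result = cluster_average_linkage(traj, n_clusters=2)
        labels = result.labels - 1
        agreement = max(np.mean(labels == truth["schedule"]),
                        np.mean(labels != truth["schedule"]))
        assert agreement == 1.0

    def test_nearest_two_of_three_states_merge(self):
        """States at pairwise distances (8, 8, 3): cutting at 2 clusters
        merges the close pair, exactly as the exhaustive linkage does."""
        spec = GeneratorSpec(seed=SEED, n_residues=30, n_frames=24)
        traj, truth = gen_two_state_traj(spec, separation=8.0, jitter=0.1)
        # third state: small deformation of state B (≈3 Å away)
        spec_c = GeneratorSpec(seed=SEED + 1, n_residues=30, n_frames=24)
        _, truth_c = gen_two_state_traj(spec_c, separation=3.0, jitter=0.0)
        delta = truth_c["state_b"] - truth_c["state_a"]
        frames = traj.frames.copy()
        # schedule: frames 0-11 state A, 12-23 state B; turn 16-23 into the
        # third state (B + ~3 Å deformation)
        third = np.arange(16, 24)
        frames[third] = truth["state_b"] + delta + 0.1 * np.random.default_rng(
            SEED).normal(size=(len(third),) + frames.shape[1:])
        traj3 = Trajectory(topology=traj.topology, frames=frames)
        result = cluster_average_linkage(traj3, n_clusters=2)
        labels = result.labels
        assert len(set(labels[12:24].tolist())) == 1
        assert set(labels[:12].tolist()).isdisjoint(set(labels[12:].tolist()))

    @pytest.mark.parametrize("n_frames,n_clusters",
                             [(5, 2), (12, 3), (20, 4), (30, 5), (30, 2)])
    def test_agrees_with_exhaustive_linkage_oracle(self, n_frames, n_clusters):
        spec = GeneratorSpec(seed=SEED + n_frames + n_clusters,
                             n_residues=15, n_frames=n_frames)
        traj, _ = gen_gaussian_traj(spec, 1.5 ** 2 * np.eye(45))
        _, frames = traj.ca_view()
        D = pairwise_rmsd_matrix(frames)
        result = cluster_average_linkage(traj, n_clusters=n_clusters)
        oracle = {frozenset(c) for c in naive_average_linkage(D, n_clusters)}
        assert partition_from_labels(result.labels) == oracle

    def test_rmsd_table_layout(self):
        spec = GeneratorSpec(seed=SEED, n_residues=20, n_frames=20)
        traj, truth = gen_two_state_traj(spec, separation=6.0, jitter=0.3)
        refs = {"t": traj.topology}
        result = cluster_average_linkage(traj, n_clusters=2, references=refs)
        assert list(result.rmsd_table.columns) == ["cluster", "size", "rmsd_t"]
        assert result.rmsd_table["size"].sum() == traj.n_frames


class TestDccm:
    def test_diagonal_is_one(self):
        spec = GeneratorSpec(seed=SEED, n_residues=15, n_frames=400)
        traj, _ = gen_gaussian_traj(spec, 0.2 ** 2 * np.eye(45))
        cmap = dccm(traj)
        np.testing.assert_allclose(np.diag(cmap.matrix), 1.0, atol=1e-12)
        np.testing.assert_allclose(cmap.matrix, cmap.matrix.T, atol=1e-12)

    def test_perfectly_coupled_pairs(self):
        """Residues driven by one shared 1-D coordinate: c = +1; anti-phase
        pairs give −1 (fit held fixed by a static core)."""
        n = 20
        v = np.zeros(3 * n); v[3 * 2 + 1] = v[3 * 10 + 1] = 1.0
        w = np.zeros(3 * n); w[3 * 5 + 1] = 1.0; w[3 * 15 + 1] = -1.0
        cov = 0.25 * (np.outer(v, v) + np.outer(w, w))
        spec = GeneratorSpec(seed=SEED, n_residues=n, n_frames=1500)
        traj, _ = gen_gaussian_traj(spec, cov)
        static = np.setdiff1d(np.arange(1, n + 1), [3, 6, 11, 16])
        cmap = dccm(traj, core=CoreDefinition(residue_ids=static))
        assert cmap.matrix[2, 10] == pytest.approx(1.0, abs=1e-9)
        assert cmap.matrix[5, 15] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_residues_mostly_uncorrelated(self):
        spec = GeneratorSpec(seed=SEED, n_residues=40, n_frames=10_000)
        traj, _ = gen_gaussian_traj(spec, 0.3 ** 2 * np.eye(120))
        cmap = dccm(traj)
        off = cmap.matrix[np.triu_indices(40, k=1)]
        assert np.mean(np.abs(off) < 0.1) >= 0.99

    def test_window_consistency_filter(self):
        """A planted coupling must be consistent across all three windows;
        independent low-noise residues must not be (fit on a quiet core, so
        the big coupled motion cannot bleed into other residues)."""
        n = 12
        v = np.zeros(3 * n); v[3 * 1 + 2] = v[3 * 8 + 2] = 1.0
        cov = 0.25 * np.outer(v, v) + 0.0025 * np.eye(3 * n)
        spec = GeneratorSpec(seed=SEED, n_residues=n, n_frames=900)
        traj, _ = gen_gaussian_traj(spec, cov)
        quiet = np.setdiff1d(np.arange(1, n + 1), [2, 9])
        cmap = dccm(traj, windows=[(0, 300), (300, 600), (600, 900)],
                    consistency_threshold=0.5,
                    core=CoreDefinition(residue_ids=quiet))
        assert (2, 9) in cmap.consistent_pairs
        # coupled pair dominates; spurious consistency is rare
        assert len(cmap.consistent_pairs) <= 3


class TestEntropy:
    def test_stiff_limit_vanishes(self):
        s, k = entropy_from_eigenvalues(np.full(9, 1e-12))
        assert s == 0.0

    def test_single_mode_closed_form(self):
        """One prescribed eigenvalue at 300 K against an independent
        evaluation of the oscillator entropy formula."""
        lam = 0.7            # Å²·amu
        s, k = entropy_from_eigenvalues(np.array([lam]), temperature=300.0,
                                        drop_modes=0)
        kT = constants.k * 300.0
        omega = np.sqrt(kT / (lam * 1e-20 * constants.atomic_mass))
        a = constants.hbar * omega / kT
        expect = constants.R * (a / (np.exp(a) - 1) - np.log(1 - np.exp(-a)))
        assert k == 1
        assert s == pytest.approx(expect, rel=1e-10)

    def test_three_atom_gaussian_matches_analytic_covariance(self):
        """10⁵ samples from a prescribed 3-atom Gaussian: entropy within 2%
        of the value computed from the true covariance."""
        n = 3
        base = make_toy_chain(n)
        Q = internal_modes(base.ca_coords(), 3)
        lam_true = np.array([0.006, 0.004, 0.002])
        cov = (Q * lam_true) @ Q.T
        spec = GeneratorSpec(seed=SEED, n_residues=n, n_frames=100_000)
        traj, _ = gen_gaussian_traj(spec, cov)
        curve = quasiharmonic_entropy(traj, checkpoints=[100_000])
        s_true, _ = entropy_from_eigenvalues(
            np.concatenate([lam_true * CA_MASS, np.zeros(6)]))
        assert curve.entropies[0] == pytest.approx(s_true, rel=0.02)

    def test_curve_reproducible_bit_identical(self):
        spec = GeneratorSpec(seed=SEED, n_residues=10, n_frames=400)
        traj, _ = gen_gaussian_traj(spec, 0.01 * np.eye(30))
        c1 = quasiharmonic_entropy(traj, checkpoints=[100, 200, 400])
        c2 = quasiharmonic_entropy(traj, checkpoints=[100, 200, 400])
        assert np.array_equal(c1.entropies, c2.entropies)

    def test_checkpoints_must_increase(self):
        spec = GeneratorSpec(seed=SEED, n_residues=5, n_frames=50)
        traj, _ = gen_gaussian_traj(spec, 0.01 * np.eye(15))
        with pytest.raises(ValueError):
            quasiharmonic_entropy(traj, checkpoints=[30, 30])

    def test_rmsf_equals_dccm_covariance_diagonal(self):
        """RMSF² per residue equals the trace of the displacement covariance
        used by the correlation map (same fitting convention)."""
        spec = GeneratorSpec(seed=SEED, n_residues=20, n_frames=500)
        traj, _ = gen_gaussian_traj(spec, 0.3 ** 2 * np.eye(60))
        table = rmsf(traj)
        ids, frames = traj.ca_view()
        from ensdyn.superpose import fit_frames
        fitted = fit_frames(frames, frames.mean(axis=0))
        for _ in range(3):
            fitted = fit_frames(fitted, fitted.mean(axis=0))
        dev = fitted - fitted.mean(axis=0)
        per_res = np.mean(np.sum(dev ** 2, axis=2), axis=0)
        np.testing.assert_allclose(table["rmsf"] ** 2, per_res, atol=1e-9)


class TestHbonds:
    def test_ideal_geometry_full_occupancy(self):
        spec = GeneratorSpec(seed=SEED, n_frames=50)
        traj, truth = gen_hbond_traj(spec, 1.0)
        table = hbond_occupancy(traj, donors=np.array([truth["donor"]]),
                                acceptors=np.array([truth["acceptor"]]))
        assert table.table["occupancy"].item() == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.5, 0.25, 0.9])
    def test_planted_occupancy_exact(self, target):
        spec = GeneratorSpec(seed=SEED, n_frames=1000)
        traj, truth = gen_hbond_traj(spec, target)
        table = hbond_occupancy(traj, donors=np.array([0]),
                                acceptors=np.array([2]))
        assert table.table["occupancy"].item() == target

    def test_zero_occupancy_empty_table(self):
        spec = GeneratorSpec(seed=SEED, n_frames=100)
        traj, _ = gen_hbond_traj(spec, 0.0)
        table = hbond_occupancy(traj, donors=np.array([0]),
                                acceptors=np.array([2]))
        assert len(table) == 0

    def test_angle_criterion_rejects_bent_geometry(self):
        spec = GeneratorSpec(seed=SEED, n_frames=10)
        traj, _ = gen_hbond_traj(spec, 1.0)
        # move acceptor to 100° at the hydrogen but keep distance small
        traj.frames[:, 2, :] = np.array([1.3, 1.8, 0.0])
        table = hbond_occupancy(traj, donors=np.array([0]),
                                acceptors=np.array([2]))
        assert len(table) == 0

    def test_empty_selection_rejected(self):
        spec = GeneratorSpec(seed=SEED, n_frames=10)
        traj, _ = gen_hbond_traj(spec, 1.0)
        with pytest.raises(ValueError):
            hbond_occupancy(traj, donors=np.array([]), acceptors=np.array([2]))
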