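import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from corestab.structure_io import AtomRecord, Structure, Ensemble
from corestab.conformation_analysis import (superpose, rmsd_series, rmsf,
                                            hbond_series, salt_bridges, pca,
                                            _fit_frames_to_mean)
from corestab.synthetic_data import make_helix, make_extended, make_ensemble


def quaternion_search_rmsd(ref, mob, seed=0):
    """Brute-force oracle: annealed random search over rotations (quaternion
    perturbations with shrinking step), independent of the Kabsch solution."""
    rng = np.random.default_rng(seed)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def rmsd_of(rot):
        d = rot.apply(mob_c) - ref_c
        return np.sqrt((d ** 2).sum() / len(ref))

    best_rot = Rotation.identity()
    best = rmsd_of(best_rot)
    for r in Rotation.random(2000, random_state=rng):
        v = rmsd_of(r)
        if v < best:
            best, best_rot = v, r
    for scale in (0.5, 0.2, 0.08, 0.03, 0.01, 0.003, 0.001):
        for _ in range(800):
            r = Rotation.from_rotvec(rng.normal(scale=scale, size=3)) * best_rot
            v = rmsd_of(r)
            if v < best:
                best, best_rot = v, r
    return best


class TestSuperpose:
    def test_identity_on_equal_sets(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        sp = superpose(x, x)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0)

    def test_recovers_a_known_rotation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        rot = Rotation.from_euler("xyz", [15, -70, 33], degrees=True)
        y = rot.apply(x) + np.array([2.0, -1.0, 4.0])
        sp = superpose(y, x)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sp.apply(x), y, atol=1e-9)

    def test_matches_quaternion_search_oracle_under_noise(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 3)) * 3.0
        y = Rotation.from_euler("zyx", [40, 10, -25], degrees=True).apply(x)
        y = y + rng.normal(scale=0.3, size=(10, 3))
        ours = superpose(y, x).rmsd
        oracle = quaternion_search_rmsd(y, x)
        assert ours <= oracle + 1e-9          # Kabsch is the true minimum
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            superpose(line, line)

    def test_rmsd_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert superpose(x, y).rmsd == pytest.approx(superpose(y, x).rmsd, abs=1e-9)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self, helix12):
        s, _ = helix12
        ens = Ensemble(s, np.repeat(s.coords()[None], 4, axis=0))
        assert np.allclose(rmsd_series(ens), 0.0, atol=1e-12)

    def test_designed_displacement_recovered(self, helix12):
        s, _ = helix12
        xyz = s.coords()
        frames = np.repeat(xyz[None], 3, axis=0)
        ca = np.array([a.name == "CA" for a in s.atoms])
        # frame 2: move every CA along a non-rigid alternating pattern
        delta = np.zeros_like(xyz)
        delta[ca, 2] = np.where(np.arange(ca.sum()) % 2 == 0, 0.5, -0.5)
        frames[2] += delta
        series = rmsd_series(ens := Ensemble(s, frames), reference_frame=0,
                             selection="CA")
        assert series[0] == series[1] == pytest.approx(0.0, abs=1e-12)
        # the alternating pattern is orthogonal to rigid modes on a helix only
        # approximately; Kabsch can only reduce the apparent displacement
        assert 0.3 < series[2] <= 0.5 + 1e-9

    def test_empty_selection_rejected(self, helix12):
        s, _ = helix12
        ens = Ensemble(s, s.coords()[None])
        with pytest.raises(ValueError):
            rmsd_series(ens, selection=np.zeros(len(s.atoms), dtype=bool))


class TestRmsf:
    def test_identical_frames_are_rigid(self, helix12):
        s, _ = helix12
        ens = Ensemble(s, np.repeat(s.coords()[None], 3, axis=0))
        assert np.allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_single_frame_is_an_error(self, helix12):
        s, _ = helix12
        with pytest.raises(ValueError):
            rmsf(Ensemble(s, s.coords()[None]))

    def test_recovers_generator_amplitudes(self):
        base = make_extended(60)
        amp = np.concatenate([np.full(20, 0.5), np.full(20, 1.0), np.full(20, 2.0)])
        ens, gt = make_ensemble(base, amplitude_profile=amp, n_frames=500, seed=7)
        got = rmsf(ens, selection="CA",
                   fit_selection=np.ones(len(base.atoms), dtype=bool))
        assert np.max(np.abs(got - gt.designed_rmsf) / gt.designed_rmsf) < 0.05

    def test_invariant_under_global_rigid_motion(self):
        base = make_extended(20)
        amp = np.full(20, 0.8)
        ens, gt = make_ensemble(base, amplitude_profile=amp, n_frames=60, seed=5)
        ref = rmsf(ens, selection="CA")
        rng = np.random.default_rng(9)
        moved = np.stack([
            Rotation.random(random_state=rng).apply(f) + rng.normal(size=3) * 10
            for f in ens.frames])
        got = rmsf(Ensemble(base, moved), selection="CA")
        assert np.allclose(got, ref, atol=1e-6)

    def test_hinge_mode_peaks_at_designed_loop(self):
        base = make_extended(60)
        n_atoms = len(base.atoms)
        res_idx = np.repeat(np.arange(60), 5)
        mode = np.zeros((n_atoms, 3))
        mode[(res_idx >= 25) & (res_idx < 35), 2] = 1.0
        ens, _ = make_ensemble(base, mode_spec=[(mode, 4.0)], n_frames=300, seed=3)
        prof = rmsf(ens, selection="CA")
        assert 25 <= int(np.argmax(prof)) < 35
        assert prof[:15].max() < 0.3 * prof.max()


class TestHbondSeries:
    def test_rigid_helix_is_constant_n_minus_4(self, helix12):
        s, _ = helix12
        ens = Ensemble(s, np.repeat(s.coords()[None], 3, axis=0))
        assert list(hbond_series(ens)) == [8, 8, 8]

    def test_breaking_designed_bonds_drops_the_count(self, helix12):
        s, _ = helix12
        xyz = s.coords()
        frames = np.repeat(xyz[None], 3, axis=0)
        moved = np.array([a.residue_seq >= 8 for a in s.atoms])
        frames[2, moved] += np.array([80.0, 0.0, 0.0])
        series = hbond_series(Ensemble(s, frames))
        # bonds crossing the residue-7/8 boundary: donors 8..11, acceptors 4..7
        broken = len([(d, a) for d, a in
                      [(i + 4, i) for i in range(1, 9)] if d >= 8 and a < 8])
        assert series[0] == 8
        assert series[2] == 8 - broken

    def test_geometric_mode_counts_on_rigid_frames(self, helix12):
        s, _ = helix12
        ens = Ensemble(s, np.repeat(s.coords()[None], 2, axis=0))
        series = hbond_series(ens, mode="all")
        assert series[0] == series[1] > 0


class TestSaltBridges:
    def _pair(self, d):
        atoms = [
            AtomRecord(1, "N", "N", "GLU", 1, "", "A", (0, 5, 0)),
            AtomRecord(2, "CA", "C", "GLU", 1, "", "A", (1.5, 5, 0)),
            AtomRecord(3, "OE1", "O", "GLU", 1, "", "A", (0.0, 0.0, 0.0)),
            AtomRecord(4, "OE2", "O", "GLU", 1, "", "A", (0.0, 2.2, 0.0)),
            AtomRecord(5, "N", "N", "LYS", 9, "", "A", (d + 3, 5, 0)),
            AtomRecord(6, "CA", "C", "LYS", 9, "", "A", (d + 2, 5, 0)),
            AtomRecord(7, "NZ", "N", "LYS", 9, "", "A", (d, 0.0, 0.0)),
        ]
        return Structure(atoms, "pair")

    def test_pair_within_cutoff_reported_with_distance(self):
        recs = salt_bridges(self._pair(3.0))
        assert len(recs) == 1
        r = recs[0]
        assert r.distance == pytest.approx(3.0)
        assert r.min_atom_pair == ("OE1", "NZ")
        assert r.occupancy == 1.0

    def test_pair_beyond_cutoff_not_reported(self):
        assert salt_bridges(self._pair(4.5)) == []

    def test_ensemble_occupancy_counts_frames(self):
        s = self._pair(3.0)
        far = self._pair(8.0)
        ens = Ensemble(s, np.stack([s.coords(), far.coords()]))
        recs = salt_bridges(ens)
        assert len(recs) == 1
        assert recs[0].occupancy == pytest.approx(0.5)

    def test_single_frame_equals_ensemble_of_that_frame(self, helix12):
        s = self._pair(3.5)
        direct = salt_bridges(s)
        via_ens = salt_bridges(Ensemble(s, s.coords()[None]))
        assert [(r.acidic_residue, r.basic_residue, r.occupancy) for r in direct] == \
               [(r.acidic_residue, r.basic_residue, r.occupancy) for r in via_ens]


class TestPca:
    def test_single_linear_mode_is_100_percent(self, helix12):
        s, _ = helix12
        mode = np.zeros((len(s.atoms), 3))
        mode[:, 2] = np.where(np.arange(len(s.atoms)) % 2 == 0, 1.0, -1.0)
        ens, _ = make_ensemble(s, mode_spec=[(mode, 1.0)], n_frames=100, seed=2)
        res = pca(ens, selection=None)
        assert res.contribution_pct[0] == pytest.approx(100.0, abs=1e-6)

    def test_two_mode_variance_ratio_recovered(self):
        base = make_extended(40)
        n_atoms = len(base.atoms)
        xyz = base.coords()
        m1 = np.zeros((n_atoms, 3))
        m1[xyz[:, 0] > np.median(xyz[:, 0]), 0] = 1.0
        m1[xyz[:, 0] <= np.median(xyz[:, 0]), 0] = -1.0
        m2 = np.zeros((n_atoms, 3))
        m2[:, 2] = np.where(np.arange(n_atoms) % 2 == 0, 1.0, -1.0)
        ens, _ = make_ensemble(base, mode_spec=[(m1, 3.0), (m2, 1.0)],
                               n_frames=1000, seed=11)
        res = pca(ens, selection=None)
        assert res.contribution_pct[0] == pytest.approx(75.0, abs=3.0)
        assert res.contribution_pct[1] == pytest.approx(25.0, abs=3.0)

    def test_eigenvalue_sum_equals_total_variance(self):
        base = make_extended(15)
        ens, _ = make_ensemble(base, amplitude_profile=np.full(15, 0.5),
                               n_frames=50, seed=8)
        res = pca(ens, selection="CA")
        mask = np.array([a.name == "CA" for a in base.atoms])
        fitted = _fit_frames_to_mean(ens.frames[:, mask, :])
        total = np.mean(np.sum((fitted - fitted.mean(axis=0)) ** 2, axis=(1, 2)))
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-8)
        assert res.contribution_pct.sum() == pytest.approx(100.0, rel=1e-8)

    def test_descending_nonnegative_eigenvalues(self):
        base = make_extended(10)
        ens, _ = make_ensemble(base, amplitude_profile=np.full(10, 0.3),
                               n_frames=30, seed=1)
        res = pca(ens)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= -1e-12)

    def test_single_frame_rejected(self, helix12):
        s, _ = helix12
        with pytest.raises(ValueError):
            pca(Ensemble(s, s.coords()[None]))
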