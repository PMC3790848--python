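import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from corestab.structure_io import AtomRecord, Structure, classify_nonpolar_carbons
from corestab.hbond_wrapping import (place_amide_hydrogen, kabsch_sander_energy,
                                     extract_bhb, wrapping_count, wrapping_profile,
                                     threshold_from_counts, calibrate_threshold,
                                     KS_CONSTANT)
from corestab.synthetic_data import (make_helix, make_extended,
                                     decorate_hydrophobics, brute_force_wrapping)


class TestAmideHydrogen:
    def test_chain_initial_residue_cannot_donate(self, helix12):
        s, _ = helix12
        residues = s.residues()
        assert place_amide_hydrogen(residues[0], None) is None

    def test_proline_has_no_amide_hydrogen(self):
        s = make_extended(3, residue_name="PRO")
        residues = s.residues()
        assert place_amide_hydrogen(residues[1], residues[0]) is None

    def test_geometry_of_placed_hydrogen(self, helix12):
        s, _ = helix12
        residues = s.residues()
        h = place_amide_hydrogen(residues[5], residues[4])
        n = residues[5].coord("N")
        assert h is not None
        assert np.linalg.norm(h - n) == pytest.approx(1.0, abs=1e-9)
        # N->H anti-parallel to the previous O->C direction
        co = residues[4].coord("C") - residues[4].coord("O")
        cos = np.dot(h - n, co) / np.linalg.norm(co)
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestKabschSanderEnergy:
    def test_symmetric_placement_cancels(self):
        # O and C on the N/H mirror plane: r_ON = r_OH, r_CN = r_CH -> E = 0
        donor = Structure([
            AtomRecord(1, "N", "N", "ALA", 3, "", "A", (0.0, 1.0, 0.0)),
            AtomRecord(2, "H", "H", "ALA", 3, "", "A", (0.0, -1.0, 0.0)),
        ], "d").residues()[0]
        acceptor = Structure([
            AtomRecord(1, "C", "C", "ALA", 1, "", "A", (6.0, 0.0, 0.0)),
            AtomRecord(2, "O", "O", "ALA", 1, "", "A", (4.0, 0.0, 0.0)),
        ], "a").residues()[0]
        assert kabsch_sander_energy(donor, acceptor) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_linear_bond(self):
        # collinear N-H...O=C with r_ON = 2.9
        n, h = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        o, c = np.array([2.9, 0, 0]), np.array([4.131, 0, 0])
        donor = Structure([AtomRecord(1, "N", "N", "ALA", 3, "", "A", n),
                           AtomRecord(2, "H", "H", "ALA", 3, "", "A", h)], "d").residues()[0]
        acceptor = Structure([AtomRecord(1, "C", "C", "ALA", 1, "", "A", c),
                              AtomRecord(2, "O", "O", "ALA", 1, "", "A", o)], "a").residues()[0]
        expected = KS_CONSTANT * (1 / 2.9 + 1 / 3.131 - 1 / 1.9 - 1 / 4.131)
        assert kabsch_sander_energy(donor, acceptor) == pytest.approx(expected, rel=1e-12)
        assert expected < -0.5   # a canonical bond passes the cutoff

    def test_floor_applied_and_close_contact_raises(self):
        from corestab.hbond_wrapping import GeometryError
        n, h = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        donor = Structure([AtomRecord(1, "N", "N", "ALA", 3, "", "A", n),
                           AtomRecord(2, "H", "H", "ALA", 3, "", "A", h)], "d").residues()[0]
        close = Structure([AtomRecord(1, "C", "C", "ALA", 1, "", "A", (3.0, 0, 0)),
                           AtomRecord(2, "O", "O", "ALA", 1, "", "A", (1.6, 0, 0))],
                          "a").residues()[0]
        assert kabsch_sander_energy(donor, close) == -9.9
        overlapping = Structure([AtomRecord(1, "C", "C", "ALA", 1, "", "A", (2.0, 0, 0)),
                                 AtomRecord(2, "O", "O", "ALA", 1, "", "A", (1.2, 0, 0))],
                                "a").residues()[0]
        with pytest.raises(GeometryError):
            kabsch_sander_energy(donor, overlapping)

    def test_ideal_helix_i_to_i4_energies_below_cutoff(self, helix12):
        s, _ = helix12
        bonds = extract_bhb(s)
        assert all(b.energy < -0.5 for b in bonds)


class TestExtractBhb:
    def test_single_residue_yields_nothing(self):
        s = make_extended(1)
        assert extract_bhb(s) == []

    @pytest.mark.parametrize("n", range(4, 31))
    def test_ideal_helix_closed_form(self, n):
        s, gt = make_helix(n)
        bonds = extract_bhb(s)
        assert len(bonds) == max(0, n - 4)
        assert {(b.donor.seq, b.acceptor.seq) for b in bonds} == set(gt.designed_hbonds)

    def test_hairpin_ladder_matches_designed_register(self, hairpin6):
        s, gt = hairpin6
        turn = gt.params["turn_len"]
        found = {(b.donor.seq, b.acceptor.seq) for b in extract_bhb(s)
                 if min(b.donor.seq, b.acceptor.seq) <= 6
                 and max(b.donor.seq, b.acceptor.seq) > 6 + turn}
        assert found == set(gt.designed_hbonds)

    def test_lower_cutoff_never_adds_bonds(self, hairpin6):
        s, _ = hairpin6
        loose = {(b.donor.seq, b.acceptor.seq) for b in extract_bhb(s, -0.5)}
        strict = {(b.donor.seq, b.acceptor.seq) for b in extract_bhb(s, -1.5)}
        assert strict <= loose


class TestWrapping:
    def test_boundary_crossing_changes_count_by_one(self, helix12):
        s, _ = helix12
        bonds = extract_bhb(s)
        bond = bonds[0]
        d_ca, a_ca = bond.donor.coord("CA"), bond.acceptor.coord("CA")
        # a point equidistant from both CAs, on the perpendicular bisector
        mid = 0.5 * (d_ca + a_ca)
        half = 0.5 * np.linalg.norm(a_ca - d_ca)
        axis = (a_ca - d_ca) / (2 * half)
        base_perp = np.cross(axis, [0.0, 0.0, 1.0])
        base_perp /= np.linalg.norm(base_perp)

        def at_distance(r, perp):
            return mid + math.sqrt(r * r - half * half) * perp - bond.donor.coord("CA")

        # probe equidistant directions until the pseudo-atom clears all atoms
        inside = outside = None
        for angle in np.linspace(0, 2 * math.pi, 24, endpoint=False):
            perp = Rotation.from_rotvec(angle * axis).apply(base_perp)
            try:
                inside, _ = decorate_hydrophobics(
                    s, [(bond.donor.seq, "C", at_distance(6.4, perp))])
                outside, _ = decorate_hydrophobics(
                    s, [(bond.donor.seq, "C", at_distance(6.6, perp))])
                break
            except RuntimeError:
                continue
        assert inside is not None, "no clash-free probe direction found"
        classify_nonpolar_carbons(inside)
        classify_nonpolar_carbons(outside)

        def count(st):
            b = [x for x in extract_bhb(st)
                 if (x.donor.seq, x.acceptor.seq) == (bond.donor.seq, bond.acceptor.seq)][0]
            return wrapping_count(st, b)

        assert count(inside) - count(outside) == 1

    def test_matches_brute_force_oracle_on_decorated_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            s, _ = make_helix(int(rng.integers(6, 12)))
            decs = []
            for _k in range(int(rng.integers(1, 6))):
                seq = int(rng.integers(1, len(s.residues()) + 1))
                offset = rng.uniform(-8, 8, size=3)
                if np.linalg.norm(offset) < 3.0:
                    offset *= 3.0 / np.linalg.norm(offset)
                decs.append((seq, "C", offset))
            try:
                dec, _ = decorate_hydrophobics(s, decs)
            except RuntimeError:
                continue  # clashing decoration; the generator refuses it
            classify_nonpolar_carbons(dec)
            for b in extract_bhb(dec):
                assert wrapping_count(dec, b) == brute_force_wrapping(
                    dec, b.donor.coord("CA"), b.acceptor.coord("CA"))

    def test_enlarging_radius_is_monotone(self, helix12):
        s, _ = helix12
        classify_nonpolar_carbons(s)
        for b in extract_bhb(s):
            assert wrapping_count(s, b, radius=7.5) >= wrapping_count(s, b, radius=6.5)


class TestWrappingProfile:
    def test_rho_is_mean_and_vulnerability_is_inclusive(self, helix12):
        s, _ = helix12
        prof = wrapping_profile(s)
        counts = [b.wrapping for b in prof.bonds]
        assert prof.rho == pytest.approx(np.mean(counts))
        assert prof.n_vulnerable == sum(c <= prof.threshold for c in counts)
        # bare poly-alanine helix is sparsely wrapped: every bond vulnerable at 16
        assert all(c <= 16 for c in counts)
        assert prof.n_vulnerable == len(prof.bonds)

    def test_zero_bond_structure_reports_nan_rho(self):
        s = make_extended(3)
        prof = wrapping_profile(s)
        assert math.isnan(prof.rho)
        assert prof.n_vulnerable == 0

    def test_rho_invariant_under_rigid_motion(self, hairpin6):
        s, _ = hairpin6
        ref = wrapping_profile(s)
        rot = Rotation.from_euler("zyx", [11, -37, 119], degrees=True)
        moved = s.with_coords(rot.apply(s.coords()) + np.array([5.0, -3.0, 12.0]))
        got = wrapping_profile(moved)
        assert got.rho == pytest.approx(ref.rho, abs=1e-9)
        assert got.n_vulnerable == ref.n_vulnerable


class TestThresholdCalibration:
    def test_synthetic_background_tail_rule(self):
        counts = [20] * 10 + [30] * 90
        assert threshold_from_counts(counts, 0.10) == 20

    def test_zero_tail_puts_threshold_below_minimum(self):
        counts = [20] * 10 + [30] * 90
        assert threshold_from_counts(counts, 0.0) == 19

    def test_pooling_is_duplication_invariant(self, helix12):
        s, _ = helix12
        one = calibrate_threshold([s], 0.25)
        two = calibrate_threshold([s, s], 0.25)
        assert one.derived_threshold == two.derived_threshold

    def test_empty_background_is_an_error(self):
        with pytest.raises(ValueError):
            calibrate_threshold([], 0.1)
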