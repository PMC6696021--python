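"""Interaction terms: boundary values, continuity, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dockscreen as ds
from dockscreen.pdbqt_io import HYDROPHOBIC_TYPES, HYDROGEN_TYPES
from dockscreen.scoring import ScoringError

# ---------------------------------------------------------------------------
# Independent brute-force oracle: formulas transcribed separately from the
# implementation, pure-python double loop, its own class derivation.
# ---------------------------------------------------------------------------

ORACLE_RADII = {"C": 1.9, "A": 1.9, "N": 1.8, "NA": 1.8, "O": 1.7, "OA": 1.7,
                "S": 2.0, "SA": 2.0, "P": 2.1, "F": 1.5, "Cl": 1.8,
                "Br": 2.0, "I": 2.2}


def oracle_flags(atoms):
    """Independent re-derivation of the interaction classes."""
    out = []
    hds = [a for a in atoms if a.element_type == "HD"]
    for a in atoms:
        hydro = a.element_type in {"C", "A", "F", "Cl", "Br", "I"}
        acc = a.element_type in {"NA", "OA"}
        donor = a.element_type in {"N", "NA", "O", "OA"} and any(
            math.dist(a.coords, h.coords) <= 1.1 for h in hds)
        out.append((a, hydro, acc, donor))
    return [t for t in out if t[0].element_type not in {"H", "HD"}]


def oracle_terms(pose, receptor_atoms, cutoff=8.0):
    lig = oracle_flags(pose)
    rec = oracle_flags(receptor_atoms)
    g1 = g2 = rep = hyd = hb = 0.0
    for a, ah, aa, ad in lig:
        for b, bh, ba, bd in rec:
            r = math.dist(a.coords, b.coords)
            if r > cutoff:
                continue
            d = r - ORACLE_RADII[a.element_type] - ORACLE_RADII[b.element_type]
            g1 += math.exp(-((d / 0.5) ** 2))
            g2 += math.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0:
                rep += d * d
            if ah and bh:
                hyd += min(1.0, max(0.0, (1.5 - d) / 1.0))
            if (ad and ba) or (aa and bd):
                hb += min(1.0, max(0.0, -d / 0.7))
    return g1, g2, rep, hyd, hb


def _atom(t, xyz, serial=1, **flags):
    a = ds.TypedAtom(serial=serial, name=t, element_type=t,
                     x=xyz[0], y=xyz[1], z=xyz[2])
    return ds.assign_interaction_classes([a])[0] if not flags else \
        ds.TypedAtom(serial=serial, name=t, element_type=t,
                     x=xyz[0], y=xyz[1], z=xyz[2], **flags)


class TestSurfaceDistance:
    @pytest.mark.parametrize("r,ri,rj,expected", [
        (3.6, 1.8, 1.8, 0.0),
        (0.0, 1.9, 1.9, -3.8),
        (8.0, 1.7, 1.9, 4.4),
    ])
    def test_arithmetic(self, r, ri, rj, expected):
        assert ds.surface_distance(r, ri, rj) == pytest.approx(expected)


class TestPairTerms:
    C = _atom("C", (0, 0, 0))
    OA_DONOR = _atom("OA", (0, 0, 0), is_acceptor=True, is_donor_heavy=True)
    NA = _atom("NA", (0, 0, 0), is_acceptor=True)
    N_DONOR = _atom("N", (0, 0, 0), is_donor_heavy=True)

    def test_contact_boundary_values(self):
        g1, g2, rep, hyd, hb = ds.pair_terms(0.0, self.N_DONOR, self.NA)
        assert g1 == pytest.approx(1.0)
        assert rep == 0.0
        assert hb == 0.0  # ramp hits zero exactly at d = 0

    def test_gauss2_peaks_at_three_angstrom(self):
        assert ds.pair_terms(3.0, self.C, self.C)[1] == pytest.approx(1.0)

    def test_gauss1_at_half_angstrom(self):
        assert ds.pair_terms(0.5, self.C, self.C)[0] == pytest.approx(
            math.exp(-1), abs=1e-9)

    def test_hydrophobic_midpoint(self):
        assert ds.pair_terms(1.0, self.C, self.C)[3] == pytest.approx(0.5)

    def test_hydrophobic_needs_both_atoms_hydrophobic(self):
        assert ds.pair_terms(1.0, self.C, self.NA)[3] == 0.0

    def test_hbond_midpoint(self):
        assert ds.pair_terms(-0.35, self.N_DONOR, self.NA)[4] == pytest.approx(0.5)

    def test_hbond_needs_donor_acceptor_pair(self):
        assert ds.pair_terms(-0.35, self.C, self.C)[4] == 0.0
        # symmetric in direction
        assert ds.pair_terms(-0.35, self.NA, self.N_DONOR)[4] == pytest.approx(0.5)

    @pytest.mark.parametrize("brk", [0.5, 1.5, -0.7, 0.0])
    def test_continuity_at_ramp_breakpoints(self, brk):
        eps = 1e-9
        lo = ds.pair_terms(brk - eps, self.OA_DONOR, self.NA)
        hi = ds.pair_terms(brk + eps, self.OA_DONOR, self.NA)
        for a, b in zip(lo, hi):
            assert a == pytest.approx(b, abs=1e-6)

    @given(st.floats(min_value=-3.8, max_value=7.9, allow_nan=False))
    @settings(deadline=None)
    def test_term_ranges(self, d):
        g1, g2, rep, hyd, hb = ds.pair_terms(d, self.OA_DONOR, self.NA)
        assert 0 < g1 <= 1 and 0 < g2 <= 1
        assert 0 <= hb <= 1
        if d >= 0:
            assert rep == 0
        elif d < -1e-150:  # below this, d*d underflows to zero
            assert rep > 0


class TestIntermolecularTerms:
    def test_beyond_cutoff_everything_zero(self):
        rec = ds.Receptor("r", (_atom("C", (0, 0, 0)),))
        pose = [_atom("C", (20.0, 0, 0))]
        tv = ds.intermolecular_terms(pose, rec, n_rotatable=0)
        assert tv.as_array() == pytest.approx(np.zeros(6))

    def test_single_carbon_pair_at_contact(self):
        rec = ds.Receptor("r", (_atom("C", (0, 0, 0)),))
        pose = [_atom("C", (3.8, 0, 0))]  # d = 0 for two 1.9 Å radii
        tv = ds.intermolecular_terms(pose, rec)
        assert tv.gauss1 == pytest.approx(1.0)
        assert tv.gauss2 == pytest.approx(math.exp(-9 / 4))
        assert tv.repulsion == 0.0
        assert tv.hydrophobic == pytest.approx(1.0)
        assert tv.hbond == 0.0

    def test_oracle_equivalence_random_complexes(self):
        """Vectorised path equals the brute-force double loop, 100 complexes."""
        worst = 0.0
        for seed in range(100):
            receptor, pose_set = ds.make_toy_complex(
                ds.ToyComplexSpec(seed=seed, n_receptor_atoms=30,
                                  n_ligand_atoms=8, n_poses=1))
            tv = ds.intermolecular_terms(pose_set.poses[0], receptor)
            expected = oracle_terms(pose_set.poses[0], receptor.atoms)
            dev = np.abs(tv.as_array()[:5] - np.array(expected)).max()
            worst = max(worst, dev)
        assert worst <= 1e-9

    def test_rigid_transform_invariance(self):
        receptor, pose_set = ds.make_toy_complex(ds.ToyComplexSpec(seed=11))
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(scale=10, size=3)

        def move(atoms):
            out = []
            for a in atoms:
                x, y, z = q @ np.array(a.coords) + shift
                out.append(ds.TypedAtom(a.serial, a.name, a.element_type,
                                        float(x), float(y), float(z),
                                        a.partial_charge, a.is_hydrophobic,
                                        a.is_acceptor, a.is_donor_heavy))
            return out

        before = ds.intermolecular_terms(pose_set.poses[0], receptor)
        moved_rec = ds.Receptor(receptor.structure_id,
                                tuple(move(receptor.atoms)))
        after = ds.intermolecular_terms(move(pose_set.poses[0]), moved_rec)
        assert after.as_array() == pytest.approx(before.as_array(), abs=1e-8)

    def test_empty_pose_errors(self):
        rec = ds.Receptor("r", (_atom("C", (0, 0, 0)),))
        with pytest.raises(ScoringError):
            ds.intermolecular_terms([], rec)

    def test_missing_radius_errors(self):
        rec = ds.Receptor("r", (_atom("C", (0, 0, 0)),))
        pose = [_atom("C", (1.0, 0, 0))]
        with pytest.raises(ScoringError, match="radius"):
            ds.intermolecular_terms(pose, rec, radii={"N": 1.8})


class TestVinaScore:
    def test_zero_terms_zero_score(self):
        assert ds.vina_score([0, 0, 0, 0, 0], 7) == 0.0

    def test_no_rotatable_bonds_is_plain_weighted_sum(self):
        terms = [2.0, 30.0, 0.5, 4.0, 1.0]
        w = ds.DEFAULT_WEIGHTS
        expected = (w.w_gauss1 * 2 + w.w_gauss2 * 30 + w.w_repulsion * 0.5
                    + w.w_hydrophobic * 4 + w.w_hbond * 1)
        assert ds.vina_score(terms, 0) == pytest.approx(expected)

    def test_entropic_denominator(self):
        terms = [2.0, 30.0, 0.5, 4.0, 1.0]
        s0 = ds.vina_score(terms, 0)
        assert ds.vina_score(terms, 5) == pytest.approx(
            s0 / (1 + 5 * ds.DEFAULT_WEIGHTS.w_rot))

    def test_negative_rotatable_rejected(self):
        with pytest.raises(ScoringError):
            ds.vina_score([0, 0, 0, 0, 0], -1)


class TestPoseGeometry:
    def test_identical_poses_zero_rmsd(self, toy_complex):
        _, ps = toy_complex
        assert ds.pose_rmsd(ps.poses[0], ps.poses[0]) == 0.0

    def test_uniform_translation_rmsd(self):
        pose = [_atom("C", (float(i), 0, 0), serial=i) for i in range(1, 6)]
        moved = [ds.TypedAtom(a.serial, a.name, a.element_type,
                              a.x + 3, a.y + 4, a.z, a.partial_charge)
                 for a in pose]
        assert ds.pose_rmsd(pose, moved) == pytest.approx(5.0)

    def test_rmsd_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = [_atom("C", tuple(rng.normal(size=3)), serial=i) for i in range(10)]
        b = [_atom("C", tuple(rng.normal(size=3)), serial=i) for i in range(10)]
        expected = math.sqrt(sum(math.dist(x.coords, y.coords) ** 2
                                 for x, y in zip(a, b)) / 10)
        assert ds.pose_rmsd(a, b) == pytest.approx(expected)

    def test_rmsd_count_mismatch(self):
        a = [_atom("C", (0, 0, 0))]
        with pytest.raises(ScoringError):
            ds.pose_rmsd(a, a * 2)

    def test_centroid_at_reference(self):
        dist, in_site = ds.centroid_reference_distance(
            [_atom("C", (1, 2, 3))], (1, 2, 3))
        assert dist == 0.0 and in_site

    def test_centroid_of_two_atoms(self):
        pose = [_atom("C", (0, 0, 0)), _atom("C", (2, 0, 0), serial=2)]
        dist, in_site = ds.centroid_reference_distance(pose, (1, 0, 0))
        assert dist == 0.0 and in_site

    def test_far_pose_flagged_outside_site(self):
        dist, in_site = ds.centroid_reference_distance(
            [_atom("C", (55.0, 0, 0))], (0, 0, 0))
        assert dist == pytest.approx(55.0) and not in_site

    def test_missing_reference_point_errors(self):
        with pytest.raises(ScoringError):
            ds.centroid_reference_distance([_atom("C", (0, 0, 0))], None)
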