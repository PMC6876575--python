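"""Superposition, twist angle, contacts, SASA and clash geometry."""

import numpy as np
import pytest

from capkin import structure as st
from conftest import make_frame


def _rot(axis, deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.radians(deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _quaternion_superpose_rmsd(p, q):
    """Independent quaternion-method superposition RMSD (Horn's method)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = np.sum(pc**2) + np.sum(qc**2)
    return np.sqrt(max(e0 - 2 * lam, 0.0) / len(p))


class TestSuperpose:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        frame = make_frame(rng.normal(size=(20, 3)) * 10)
        sup = st.superpose(frame, frame)
        assert sup.rmsd < 1e-9
        assert sup.angle_deg < 1e-6

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(15, 3)) * 8
        r = _rot([0, 0, 1], 25.0)
        q = p @ r.T + np.array([3.0, -2.0, 7.0])
        sup = st.kabsch(p, q)
        assert sup.angle_deg == pytest.approx(25.0, abs=1e-9)
        assert sup.rmsd < 1e-9

    def test_matches_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = rng.normal(size=(10, 3))
            q = rng.normal(size=(10, 3))
            assert st.kabsch(p, q).rmsd == pytest.approx(
                _quaternion_superpose_rmsd(p, q), abs=1e-9
            )

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3"):
            st.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def _synthetic_actin(rng):
    """Ca-only pseudo-actin covering residues 1..375 of one chain."""
    xyz = rng.normal(size=(375, 3)) * 15
    return make_frame(xyz, chain="A", resnum=np.arange(1, 376))


class TestTwistAngle:
    def test_self_is_zero(self):
        rng = np.random.default_rng(3)
        ref = _synthetic_actin(rng)
        tw = st.actin_twist_angle(ref, "A", ref, "A")
        assert tw.angle_deg < 1e-6
        assert tw.inner_rmsd < 1e-9

    def test_recovers_outer_domain_rotation(self):
        rng = np.random.default_rng(4)
        ref = _synthetic_actin(rng)
        target = ref.select()
        sd1 = ref.mask(resnums=st._subdomain_resnums(st.ACTIN_SUBDOMAINS["SD1"]))
        r = _rot([1, 2, 3], 8.0)
        centroid = target.xyz[sd1].mean(axis=0)
        target.xyz = target.xyz.copy()
        target.xyz[sd1] = (target.xyz[sd1] - centroid) @ r.T + centroid
        tw = st.actin_twist_angle(target, "A", ref, "A")
        assert tw.angle_deg == pytest.approx(8.0, abs=1e-6)

    def test_rotations_about_common_axis_compose(self):
        rng = np.random.default_rng(5)
        ref = _synthetic_actin(rng)
        sd1 = ref.mask(resnums=st._subdomain_resnums(st.ACTIN_SUBDOMAINS["SD1"]))
        centroid = ref.xyz[sd1].mean(axis=0)

        def rotated(deg):
            t = ref.select()
            t.xyz = t.xyz.copy()
            t.xyz[sd1] = (t.xyz[sd1] - centroid) @ _rot([0, 1, 0], deg).T + centroid
            return t

        a = st.actin_twist_angle(rotated(5.0), "A", ref, "A").angle_deg
        b = st.actin_twist_angle(rotated(12.0), "A", ref, "A").angle_deg
        ab = st.actin_twist_angle(rotated(17.0), "A", ref, "A").angle_deg
        assert ab == pytest.approx(a + b, abs=1e-6)

    def test_missing_subdomain_coverage_rejected(self):
        rng = np.random.default_rng(6)
        ref = _synthetic_actin(rng)
        truncated = ref.select(resnums=np.arange(1, 150))  # lacks SD3/SD4
        with pytest.raises(ValueError, match="coverage"):
            st.actin_twist_angle(truncated, "A", ref, "A")


class TestContacts:
    def _two_chain_frame(self, rng, n=60, spread=12.0, sep=5.0):
        a = rng.normal(size=(n, 3)) * spread
        b = rng.normal(size=(n, 3)) * spread + np.array([sep, 0, 0])
        xyz = np.vstack([a, b])
        return make_frame(
            xyz,
            chain=["A"] * n + ["B"] * n,
            resnum=np.concatenate([np.arange(1, n + 1), np.arange(1, n + 1)]),
        )

    def test_far_apart_chains_no_contacts(self):
        rng = np.random.default_rng(7)
        frame = self._two_chain_frame(rng, sep=500.0)
        res = st.interchain_contacts(frame, "A", "B")
        assert res.per_frame_counts[0] == 0
        assert len(res.frequencies) == 0

    def test_touching_pair_counts_both_residues(self):
        frame = make_frame(
            np.array([[0.0, 0, 0], [2.9, 0, 0]]),
            chain=["A", "B"],
            resnum=np.array([1, 1]),
        )
        res = st.interchain_contacts(frame, "A", "B", cutoff=3.0)
        assert res.per_frame_counts[0] == 2

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        frame = self._two_chain_frame(rng)
        c3 = st.interchain_contacts(frame, "A", "B", cutoff=3.0).per_frame_counts[0]
        c4 = st.interchain_contacts(frame, "A", "B", cutoff=4.0).per_frame_counts[0]
        assert c3 <= c4

    def test_symmetric_under_chain_swap(self):
        rng = np.random.default_rng(9)
        frame = self._two_chain_frame(rng)
        ab = st.interchain_contacts(frame, "A", "B", cutoff=4.0)
        ba = st.interchain_contacts(frame, "B", "A", cutoff=4.0)
        assert ab.per_frame_counts[0] == ba.per_frame_counts[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        frame = self._two_chain_frame(rng, n=100)
        res = st.interchain_contacts(frame, "A", "B", cutoff=4.0)
        a = frame.select(chain="A")
        b = frame.select(chain="B")
        d = np.linalg.norm(a.xyz[:, None, :] - b.xyz[None, :, :], axis=2)
        res_a = {int(a.resnum[i]) for i, j in zip(*np.where(d <= 4.0))}
        res_b = {int(b.resnum[j]) for i, j in zip(*np.where(d <= 4.0))}
        assert res.per_frame_counts[0] == len(res_a) + len(res_b)

    def test_frequencies_over_ensemble_with_skip(self):
        near = make_frame(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), chain=["A", "B"], resnum=np.array([1, 1])
        )
        far = make_frame(
            np.array([[0.0, 0, 0], [50.0, 0, 0]]), chain=["A", "B"], resnum=np.array([1, 1])
        )
        model = st.StructureModel(frames=[far, near, far, near])
        res = st.interchain_contacts(model, "A", "B", cutoff=3.0, skip_frames=1)
        # post-skip frames: near, far, near -> each residue in contact 2/3
        assert np.allclose(res.frequencies["frequency"], 2 / 3)
        assert res.summary()["n_frames"] == 3

    def test_unknown_chain_rejected(self):
        frame = make_frame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            st.interchain_contacts(frame, "A", "Z")


class TestSasa:
    def test_two_sphere_analytic_caps(self):
        # two carbon-like spheres: buried area equals the spherical caps
        r_eff, d = 3.1, 3.0
        sasa = st.shrake_rupley_sasa(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.full(2, r_eff), probe_radius=0.0,
            n_points=4000,
        )
        cap = 2 * np.pi * r_eff * (r_eff - d / 2)
        analytic = 2 * (4 * np.pi * r_eff**2 - cap)
        assert sasa.sum() == pytest.approx(analytic, rel=0.02)

    def test_buried_area_of_far_chains_is_zero(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(30, 3)) * 5
        b = a + np.array([200.0, 0, 0])
        frame = make_frame(np.vstack([a, b]), chain=["A"] * 30 + ["B"] * 30)
        area = st.buried_interface_area(frame, "A", "B", n_points=240)
        assert abs(area.buried) < 1.0

    def test_point_density_convergence(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(25, 3)) * 4
        b = rng.normal(size=(25, 3)) * 4 + np.array([6.0, 0, 0])
        frame = make_frame(np.vstack([a, b]), chain=["A"] * 25 + ["B"] * 25)
        lo = st.buried_interface_area(frame, "A", "B", n_points=960).buried
        hi = st.buried_interface_area(frame, "A", "B", n_points=1920).buried
        assert hi == pytest.approx(lo, rel=0.01)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(13)
        xyz = np.vstack(
            [rng.normal(size=(20, 3)) * 4, rng.normal(size=(20, 3)) * 4 + [5.0, 0, 0]]
        )
        chains = ["A"] * 20 + ["B"] * 20
        frame = make_frame(xyz, chain=chains)
        moved = make_frame(xyz @ _rot([1, 1, 0], 37.0).T + [10, -4, 2], chain=chains)
        a0 = st.buried_interface_area(frame, "A", "B", n_points=960).buried
        a1 = st.buried_interface_area(moved, "A", "B", n_points=960).buried
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_cross_check_against_biotite(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(14)
        xyz = rng.normal(size=(40, 3)) * 5
        radii = np.full(40, st.VDW_RADII["C"])
        ours = st.shrake_rupley_sasa(xyz, radii, probe_radius=1.4, n_points=1000).sum()
        arr = biotite_struc.AtomArray(40)
        arr.coord = xyz
        arr.element = np.full(40, "C")
        arr.res_id = np.arange(1, 41)
        arr.atom_name = np.full(40, "CA")
        arr.res_name = np.full(40, "ALA")
        arr.chain_id = np.full(40, "A")
        theirs = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=1000, vdw_radii=radii
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_zero_atom_chain_rejected(self):
        frame = make_frame(np.zeros((3, 3)), chain="A")
        with pytest.raises(ValueError):
            st.buried_interface_area(frame, "A", "B")


class TestClashesAndDistances:
    def test_far_chains_no_clashes(self):
        frame = make_frame(
            np.array([[0.0, 0, 0], [100.0, 0, 0]]), chain=["A", "B"]
        )
        clashes, _ = st.clash_and_distance_report(frame, "A", "B")
        assert len(clashes) == 0

    def test_two_carbons_at_two_angstrom_clash(self):
        # threshold 1.70 + 1.70 - 0.4 = 3.0 A > 2.0 A separation
        frame = make_frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]), chain=["A", "B"])
        clashes, _ = st.clash_and_distance_report(frame, "A", "B")
        assert len(clashes) == 1
        assert clashes.overlap.iloc[0] == pytest.approx(1.0)

    def test_named_distance_query(self):
        frame = make_frame(
            np.array([[0.0, 0, 0], [49.0, 0, 0]]),
            chain=["A", "B"],
            resnum=np.array([39, 39]),
            resname="ALA",
        )
        _, dist = st.clash_and_distance_report(
            frame, "A", "B", named_pairs=[(("A", 39, "CA"), ("B", 39, "CA"))]
        )
        assert dist.distance.iloc[0] == pytest.approx(49.0)

    def test_missing_named_atom_rejected(self):
        frame = make_frame(np.zeros((1, 3)), chain="A")
        with pytest.raises(ValueError, match="named atom"):
            st.clash_and_distance_report(
                frame, "A", "A", named_pairs=[(("A", 99, "CA"), ("A", 1, "CA"))]
            )


class TestReadStructure:
    PDB_TEXT = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CA AGLY A   2      12.685   7.156  -4.888  0.70 10.00           C
ATOM      4  CA BGLY A   2      12.900   7.300  -4.900  0.30 10.00           C
ATOM      5  CA  ALA B   1       2.000   0.000   0.000  1.00 10.00           C
HETATM    6  O   HOH A 101       0.000   0.000   9.000  1.00 10.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CA  GLY A   2      12.685   7.156  -4.888  1.00 10.00           C
ATOM      5  CA  ALA B   1       2.000   0.000   0.000  1.00 10.00           C
ENDMDL
END
"""

    def test_multi_model_parse_altloc_and_waters(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(self.PDB_TEXT)
        model = st.read_structure(path)
        assert model.n_frames == 2
        frame = model[0]
        # waters excluded, altloc deduplicated to highest occupancy
        assert len(frame) == 4
        gly = frame.select(chain="A", resnums=np.array([2]))
        assert len(gly) == 1
        assert gly.xyz[0, 0] == pytest.approx(12.685)
        assert set(frame.chains()) == {"A", "B"}
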