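import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anmpath import (
    PairedSelection,
    Structure,
    StructureError,
    common_residues,
    linear_interpolate,
    make_toy_two_state,
    read_ca_structure,
    read_multimodel_ca,
    rmsd,
    superpose,
    write_multimodel_pdb,
)
from conftest import chain_sites

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY A   2       8.942   5.372  -2.616  1.00  0.00           C
ATOM      4  CB  GLY A   2       8.000   5.000  -2.000  1.00  0.00           C
ATOM      5  CA  SER A   3       7.500  -1.250   3.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       8.600   0.500   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.100   0.200   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.900   0.100   0.300  1.00  0.00           C
ATOM      3  CA  SER A   3       8.700   0.600  -0.200  1.00  0.00           C
ENDMDL
END
"""


class TestReadCA:
    def test_identity_readback(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(THREE_RES_PDB)
        s = read_ca_structure(p)
        assert s.n_sites == 3
        np.testing.assert_allclose(
            s.coords,
            [[11.639, 6.071, -5.147], [8.942, 5.372, -2.616], [7.5, -1.25, 3.0]],
        )
        assert [x.resname for x in s.sites] == ["ALA", "GLY", "SER"]
        # deterministic re-read
        s2 = read_ca_structure(p)
        assert s.sites == s2.sites
        np.testing.assert_array_equal(s.coords, s2.coords)

    def test_second_model_against_hand_parse(self, tmp_path):
        p = tmp_path / "two_model.pdb"
        p.write_text(TWO_MODEL_PDB)
        s = read_ca_structure(p, model=2)
        # independent line-by-line parse of the second MODEL block
        block = TWO_MODEL_PDB.split("MODEL        2")[1]
        expect = [
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            for line in block.splitlines()
            if line.startswith("ATOM") and line[12:16].strip() == "CA"
        ]
        np.testing.assert_allclose(s.coords, expect)

    def test_no_ca_is_fatal(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(THREE_RES_PDB.splitlines()[0] + "\nEND\n")
        with pytest.raises(StructureError):
            read_ca_structure(p)

    def test_chain_filter(self, tmp_path):
        text = THREE_RES_PDB.replace("SER A   3", "SER B   3")
        p = tmp_path / "chains.pdb"
        p.write_text(text)
        s = read_ca_structure(p, chains=["A"])
        assert s.n_sites == 2
        assert all(x.chain == "A" for x in s.sites)


class TestCommonResidues:
    def test_offset_ranges(self):
        a = Structure(chain_sites(10), np.c_[np.arange(10) * 3.8, np.zeros(10), np.zeros(10)])
        sites_b = tuple(s._replace(resnum=s.resnum + 2) for s in chain_sites(10))
        b = Structure(sites_b, a.coords.copy())
        sel = common_residues(a, b)
        assert len(sel) == 8
        assert [a.sites[i].resnum for i in sel.indices_a] == list(range(3, 11))

    def test_identity(self):
        a, _ = make_toy_two_state(8, 150, 100)
        sel = common_residues(a, a)
        np.testing.assert_array_equal(sel.indices_a, sel.indices_b)
        assert len(sel) == 8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        nums_a = sorted(rng.choice(50, size=20, replace=False))
        nums_b = sorted(rng.choice(50, size=20, replace=False))
        make = lambda nums: Structure(
            tuple(chain_sites(1)[0]._replace(resnum=int(n)) for n in nums),
            rng.standard_normal((len(nums), 3)),
        )
        a, b = make(nums_a), make(nums_b)
        sel = common_residues(a, b)
        brute = [
            (i, j)
            for i, sa in enumerate(a.sites)
            for j, sb in enumerate(b.sites)
            if sa.key == sb.key
        ]
        assert list(zip(sel.indices_a, sel.indices_b)) == brute

    def test_empty_intersection_fatal(self):
        a = Structure(chain_sites(4), np.random.default_rng(0).standard_normal((4, 3)))
        sites_b = tuple(s._replace(resnum=s.resnum + 100) for s in a.sites)
        b = Structure(sites_b, a.coords.copy())
        with pytest.raises(StructureError):
            common_residues(a, b)


class TestSuperpose:
    def test_self_superposition_zero(self):
        a, _ = make_toy_two_state(10, 150, 100, jitter=0.3, seed=3)
        _, r = superpose(a, a)
        assert r < 1e-10

    def test_rigid_invariance(self):
        a, _ = make_toy_two_state(10, 150, 100, jitter=0.3, seed=3)
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        moved = a.with_coords(a.coords @ rot.T + np.array([5.0, -2.0, 7.0]))
        fitted, r = superpose(moved, a)
        assert r < 1e-8
        np.testing.assert_allclose(fitted.coords, a.coords, atol=1e-8)

    def test_against_rotation_search_oracle(self):
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        ref = Structure(chain_sites(10), rng.standard_normal((10, 3)) * 5)
        mob = Structure(chain_sites(10), rng.standard_normal((10, 3)) * 5)
        _, fitted_rmsd = superpose(mob, ref)

        xm = mob.coords - mob.coords.mean(0)
        xr = ref.coords - ref.coords.mean(0)

        def cost(rv):
            return np.sqrt(np.mean(np.sum((Rotation.from_rotvec(rv).apply(xm) - xr) ** 2, -1)))

        # multi-start search over rotation space, refined numerically
        best = np.inf
        for v in rng.uniform(-np.pi, np.pi, size=(60, 3)):
            res = minimize(cost, v, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
            best = min(best, res.fun)
        assert abs(fitted_rmsd - best) < 1e-6

    def test_collinear_subset_fatal(self):
        coords = np.c_[np.arange(5) * 3.8, np.zeros(5), np.zeros(5)]
        a = Structure(chain_sites(5), coords)
        with pytest.raises(StructureError):
            superpose(a, a, PairedSelection(np.arange(5), np.arange(5)))


class TestRmsd:
    def test_basics(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((12, 3))
        assert rmsd(a, a) == 0.0
        assert rmsd(a, a + np.array([1.0, 0, 0])) == pytest.approx(1.0)
        b = rng.standard_normal((12, 3))
        direct = np.sqrt(sum(np.sum((ai - bi) ** 2) for ai, bi in zip(a, b)) / 12)
        assert rmsd(a, b) == pytest.approx(direct, rel=1e-12)

    def test_length_mismatch_fatal(self):
        with pytest.raises(StructureError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.standard_normal((3, 6, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12


class TestInterpolate:
    def test_midpoint_and_uniform_spacing(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 7, 3))
        (mid,) = linear_interpolate(a, b, 1)
        np.testing.assert_allclose(mid, 0.5 * (a + b))
        chain = np.concatenate([[a], linear_interpolate(a, b, 9), [b]])
        seps = [rmsd(u, v) for u, v in zip(chain[:-1], chain[1:])]
        assert np.var(seps) < 1e-12

    def test_default_count_excludes_endpoints(self):
        a = np.zeros((4, 3))
        b = np.ones((4, 3))
        interp = linear_interpolate(a, b, 100)
        assert interp.shape[0] == 100
        assert rmsd(interp[0], a) > 0 and rmsd(interp[-1], b) > 0

    def test_bad_count_fatal(self):
        with pytest.raises(StructureError):
            linear_interpolate(np.zeros((4, 3)), np.ones((4, 3)), 0)


class TestToyGenerator:
    def test_equal_angles_identical(self):
        a, b = make_toy_two_state(12, 130, 130, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_seed_determinism(self):
        a1, b1 = make_toy_two_state(12, 150, 100, seed=9, jitter=0.4)
        a2, b2 = make_toy_two_state(12, 150, 100, seed=9, jitter=0.4)
        np.testing.assert_array_equal(a1.coords, a2.coords)
        np.testing.assert_array_equal(b1.coords, b2.coords)

    def test_end_to_end_matches_planar_hinge_formula(self):
        n, spacing = 20, 3.8
        a, b = make_toy_two_state(n, 180, 120)
        hinge = (n - 1) // 2
        l1, l2 = hinge * spacing, (n - 1 - hinge) * spacing
        for s, theta in ((a, 180.0), (b, 120.0)):
            expect = np.sqrt(l1**2 + l2**2 - 2 * l1 * l2 * np.cos(np.deg2rad(theta)))
            got = np.linalg.norm(s.coords[-1] - s.coords[0])
            assert got == pytest.approx(expect, abs=1e-9)

    def test_helix_preserves_bead_spacing(self):
        a, b = make_toy_two_state(14, 150, 100, geometry="helix")
        for s in (a, b):
            d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
            # every bond except the one across the hinge keeps the 3.8 Å step
            assert np.sum(np.abs(d - 3.8) > 1e-6) <= 1


def test_multimodel_roundtrip(tmp_path):
    a, b = make_toy_two_state(8, 150, 100, jitter=0.2, seed=2)
    frames = np.stack([a.coords, b.coords])
    p = tmp_path / "traj.pdb"
    write_multimodel_pdb(a.sites, frames, p)
    first, back = read_multimodel_ca(p)
    assert first.sites == a.sites
    np.testing.assert_allclose(back, frames, atol=5e-4)  # PDB format is 3 decimals
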