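import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xlinktrap.structgeo as sg
from xlinktrap.structgeo import (PDBParseError, ResidueSelector, SiteError,
                                 Structure, com_separation, count_clashes,
                                 fibonacci_sphere, mutate_to_cys,
                                 place_internal, read_structure, sasa,
                                 sg_distance, write_structure)
from conftest import random_structure

TWO_ATOMS = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00"
    "           C\n"
    "ATOM      2  SG  CYS B   2       1.000   2.000   3.000  1.00  0.00"
    "           S\n"
)


def _dihedral(p0, p1, p2, p3):
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return np.degrees(np.arctan2(np.cross(b1, v) @ w / np.linalg.norm(b1),
                                 v @ w))


def _rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestReadStructure:
    def test_two_atom_toy_exact_coordinates(self):
        s = read_structure(TWO_ATOMS)
        assert len(s) == 2
        assert s.chains() == ["A", "B"]
        np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504],
                                   atol=5e-4)
        assert s.vdw_radius[0] == 1.70 and s.vdw_radius[1] == 1.80

    def test_tetramer_roundtrip_preserves_identity(self, toy_tetramer):
        s = read_structure(write_structure(toy_tetramer))
        assert s.chains() == ["A", "B", "C", "D"]
        assert len(s) == len(toy_tetramer)
        np.testing.assert_allclose(s.coords, toy_tetramer.coords, atol=5e-4)
        assert list(s.residue_number) == list(toy_tetramer.residue_number)

    def test_non_numeric_coordinate_names_line(self):
        bad = TWO_ATOMS.replace("1.000", "x.000")
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(PDBParseError):
            read_structure("HEADER only\n")


class TestMutateToCys:
    def test_sg_placed_at_ideal_internal_coordinates(self, toy_tetramer):
        site = ResidueSelector("A", 666)
        mutated = mutate_to_cys(toy_tetramer, site)
        n = mutated.coords[mutated.atom_index(site, "N")]
        ca = mutated.coords[mutated.atom_index(site, "CA")]
        cb = mutated.coords[mutated.atom_index(site, "CB")]
        s = mutated.coords[mutated.atom_index(site, "SG")]
        assert np.linalg.norm(s - cb) == pytest.approx(1.81, abs=1e-9)
        cos = (ca - cb) @ (s - cb) / (np.linalg.norm(ca - cb)
                                      * np.linalg.norm(s - cb))
        assert np.degrees(np.arccos(cos)) == pytest.approx(114.0, abs=1e-6)
        assert _dihedral(n, ca, cb, s) == pytest.approx(-65.0, abs=1e-6)
        assert mutated.residue_name[mutated.atom_index(site, "SG")] == "CYS"

    def test_input_structure_unmodified(self, toy_tetramer):
        before = toy_tetramer.coords.copy()
        mutate_to_cys(toy_tetramer, ResidueSelector("A", 666))
        np.testing.assert_array_equal(toy_tetramer.coords, before)
        assert "SG" not in set(toy_tetramer.name)

    def test_idempotent_up_to_rotamer(self, toy_tetramer):
        site = ResidueSelector("A", 666)
        once = mutate_to_cys(toy_tetramer, site)
        twice = mutate_to_cys(once, site)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_glycine_rejected(self):
        text = ("ATOM      1  N   GLY A   9       0.000   1.400   0.000  "
                "1.00  0.00           N\n"
                "ATOM      2  CA  GLY A   9       0.000   0.000   0.000  "
                "1.00  0.00           C\n"
                "ATOM      3  C   GLY A   9       1.500   0.000   0.000  "
                "1.00  0.00           C\n")
        s = read_structure(text)
        with pytest.raises(SiteError, match="glycine|CB"):
            mutate_to_cys(s, ResidueSelector("A", 9))


class TestDistances:
    def test_simple_sg_distance(self):
        text = ("ATOM      1  SG  CYS A   1       0.000   0.000   0.000  "
                "1.00  0.00           S\n"
                "ATOM      2  SG  CYS B   1       0.000   0.000   5.000  "
                "1.00  0.00           S\n")
        s = read_structure(text)
        assert sg_distance(s, ResidueSelector("A", 1),
                           ResidueSelector("B", 1)) == pytest.approx(5.0)

    def test_constructed_separation_recovered(self):
        import xlinktrap.pipeline as pl
        for sep in (6.0, 12.0, 19.0):
            t = pl.make_toy_tetramer(separation=sep)
            m = mutate_to_cys(mutate_to_cys(t, ResidueSelector("A", 666)),
                              ResidueSelector("C", 666))
            d = sg_distance(m, ResidueSelector("A", 666),
                            ResidueSelector("C", 666))
            assert d == pytest.approx(sep, abs=1e-6)

    def test_missing_sg_rejected(self, toy_tetramer):
        with pytest.raises(SiteError):
            sg_distance(toy_tetramer, ResidueSelector("A", 666),
                        ResidueSelector("C", 666))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n=20)
        moved = s.transformed(rotation=_rotation(rng),
                              translation=rng.uniform(-40, 40, 3))
        for a in range(3):
            for b in range(a + 1, 6):
                d0 = np.linalg.norm(s.coords[a] - s.coords[b])
                d1 = np.linalg.norm(moved.coords[a] - moved.coords[b])
                assert d1 == pytest.approx(d0, abs=1e-6)


class TestComSeparation:
    def test_two_single_atoms(self):
        s = read_structure(TWO_ATOMS)
        s.coords[0] = [0.0, 0.0, 0.0]
        s.coords[1] = [10.0, 0.0, 0.0]
        assert com_separation(s, ["A"], ["B"]) == pytest.approx(10.0)

    def test_translation_invariance(self, toy_tetramer):
        d0 = com_separation(toy_tetramer, ["A", "B"], ["C", "D"])
        moved = toy_tetramer.transformed(translation=np.array([5., -3., 11.]))
        assert com_separation(moved, ["A", "B"], ["C", "D"]) == \
            pytest.approx(d0, abs=1e-9)

    def test_mass_weighting_close_to_unweighted_for_uniform_chains(
            self, toy_tetramer):
        d0 = com_separation(toy_tetramer, ["A", "B"], ["C", "D"])
        d1 = com_separation(toy_tetramer, ["A", "B"], ["C", "D"],
                            mass_weighted=True)
        assert abs(d0 - d1) < 1.0

    def test_empty_group_rejected(self, toy_tetramer):
        with pytest.raises(ValueError):
            com_separation(toy_tetramer, [], ["C"])
        with pytest.raises(ValueError):
            com_separation(toy_tetramer, ["A"], ["A", "C"])


class TestSasa:
    def test_isolated_atom_closed_form(self):
        rng = np.random.default_rng(0)
        s = random_structure(rng, n=1)
        s.vdw_radius[:] = 1.80
        area = sasa(s, probe_radius=1.4, n_points=1024)[0]
        assert area == pytest.approx(4 * np.pi * 3.2**2, rel=1e-12)

    def test_fully_enclosed_atom_is_zero(self):
        pts = fibonacci_sphere(60) * 3.0
        n = len(pts) + 1
        xyz = np.vstack([[0.0, 0.0, 0.0], pts])
        s = Structure(np.array(["S"] + ["C"] * (n - 1)),
                      np.array(["SG"] + [f"C{i}" for i in range(n - 1)]),
                      np.arange(n), np.array(["CYS"] + ["SHL"] * (n - 1)),
                      np.array(["A"] * n), xyz, np.array([1.8] + [1.7] * (n - 1)))
        assert sasa(s, np.array([0]), 1.4, 1024)[0] == 0.0

    def test_random_cluster_matches_high_density_oracle(self):
        rng = np.random.default_rng(7)
        s = random_structure(rng, n=50)
        fast = sasa(s, n_points=1024)
        dense = sasa(s, n_points=16384)
        scale = 4 * np.pi * (1.70 + 1.4) ** 2
        assert np.all(np.abs(fast - dense) <= 0.02 * scale)
        exposed = dense > 0.05 * scale
        rel = np.abs(fast[exposed] / dense[exposed] - 1)
        assert np.median(rel) < 0.02

    def test_monotone_under_added_neighbors(self):
        rng = np.random.default_rng(3)
        s = random_structure(rng, n=30)
        a_few = sasa(s.subset(np.arange(len(s)) < 10), n_points=512)
        a_all = sasa(s, np.arange(10), n_points=512)
        assert np.all(a_all <= a_few + 1e-9)


class TestCountClashes:
    def _pair(self, d):
        xyz = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        return Structure(np.array(["C", "C"]), np.array(["C1", "C2"]),
                         np.array([1, 2]), np.array(["UNK", "UNK"]),
                         np.array(["A", "B"]), xyz, np.array([1.7, 1.7]))

    def test_single_pair_inside_cutoff(self):
        assert count_clashes(self._pair(2.1), ["A"], ["B"], 2.2) == 1

    def test_boundary_is_strict(self):
        assert count_clashes(self._pair(2.2), ["A"], ["B"], 2.2) == 0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(11)
        n = 200
        xyz = rng.uniform(0, 18, size=(2 * n, 3))
        s = Structure(np.array(["C"] * 2 * n),
                      np.array([f"C{i}" for i in range(2 * n)]),
                      np.arange(2 * n), np.array(["UNK"] * 2 * n),
                      np.array(["A"] * n + ["B"] * n), xyz,
                      np.full(2 * n, 1.7))
        for cutoff in (1.0, 2.2, 3.5):
            brute = int(np.sum(np.linalg.norm(
                xyz[:n, None] - xyz[None, n:], axis=-1) < cutoff))
            assert count_clashes(s, ["A"], ["B"], cutoff) == brute

    def test_symmetry(self, toy_tetramer):
        a = count_clashes(toy_tetramer, ["A", "B"], ["C", "D"], 5.0)
        b = count_clashes(toy_tetramer, ["C", "D"], ["A", "B"], 5.0)
        assert a == b

    def test_overlapping_groups_rejected(self, toy_tetramer):
        with pytest.raises(ValueError):
            count_clashes(toy_tetramer, ["A"], ["A", "B"], 2.2)


def test_place_internal_reproduces_inputs():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a, b, c = rng.normal(size=(3, 3)) * 3
        d = place_internal(a, b, c, 1.81, 114.0, -65.0)
        assert np.linalg.norm(d - c) == pytest.approx(1.81, abs=1e-9)
        cos = (b - c) @ (d - c) / (np.linalg.norm(b - c) * 1.81)
        assert np.degrees(np.arccos(cos)) == pytest.approx(114.0, abs=1e-6)
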