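"""Molecular container, file I/O, and geometric primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pepadsorb.structures import (
    Atom,
    InputError,
    ParseError,
    Structure,
    bounding_box_volume,
    min_intermolecular_distance,
    read_charge_file,
    read_structure,
    transform,
    write_xyz,
)

from conftest import random_structure


class TestIO:
    def test_minimal_xyz(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("3\nwater\nO 0.0 0.0 0.0\nH 0.9572 0.0 0.0\nH -0.2399 0.9266 0.0\n")
        s = read_structure(p)
        assert len(s) == 3
        assert s.elements == ["O", "H", "H"]
        assert s.role is None
        assert not s.has_charges

    def test_charge_column_dialect(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("2\n\nO 0 0 0 -0.8\nH 1 0 0 0.8\n")
        s = read_structure(p)
        assert s.has_charges
        np.testing.assert_allclose(s.charges, [-0.8, 0.8])

    def test_charge_sidecar_overrides(self, tmp_path):
        xyz = tmp_path / "m.xyz"
        xyz.write_text("2\n\nO 0 0 0\nH 1 0 0\n")
        qf = tmp_path / "m.q"
        qf.write_text("-0.5\n0.5\n")
        s = read_structure(xyz, charges=qf)
        np.testing.assert_allclose(s.charges, [-0.5, 0.5])

    def test_charge_count_mismatch(self, tmp_path):
        xyz = tmp_path / "m.xyz"
        xyz.write_text("2\n\nO 0 0 0\nH 1 0 0\n")
        qf = tmp_path / "m.q"
        qf.write_text("-0.5\n")
        with pytest.raises(InputError):
            read_structure(xyz, charges=qf)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\n\nO 0 0 0\nH 1 zero 0\n")
        with pytest.raises(ParseError, match="line 4"):
            read_structure(p)

    def test_pdb_first_model(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            "MODEL        1\n"
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00           H\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  O   HOH A   1       9.000   9.000   9.000  1.00  0.00           O\n"
            "ENDMDL\nEND\n"
        )
        s = read_structure(p, format="pdb")
        assert s.elements == ["O", "H"]
        np.testing.assert_allclose(s.atoms[0].position, [0, 0, 0], atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 30), charged=st.booleans())
    def test_roundtrip_preserves_order_and_values(self, seed, n, charged, tmp_path_factory):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n, charged=charged)
        p = tmp_path_factory.mktemp("rt") / "s.xyz"
        write_xyz(s, p)
        s2 = read_structure(p)
        assert s2.elements == s.elements
        np.testing.assert_allclose(s2.positions, s.positions, atol=5e-7)
        if charged:
            np.testing.assert_allclose(s2.charges, s.charges, atol=5e-7)
        else:
            assert not s2.has_charges


class TestBoundingBoxVolume:
    def test_unit_cube(self):
        corners = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        s = Structure([Atom("C", c) for c in corners])
        assert bounding_box_volume(s) == pytest.approx(1.0)

    def test_two_atoms_closed_form(self):
        s = Structure([Atom("C", [0, 0, 0]), Atom("C", [2, 3, 4])])
        assert bounding_box_volume(s) == pytest.approx(24.0)

    def test_single_atom_is_zero(self):
        assert bounding_box_volume(Structure([Atom("O", [1, 2, 3])])) == 0.0

    def test_matches_bruteforce_extrema(self, rng):
        s = random_structure(rng, 50)
        pos = s.positions
        expected = 1.0
        for k in range(3):
            lo = min(p[k] for p in pos)
            hi = max(p[k] for p in pos)
            expected *= hi - lo
        assert bounding_box_volume(s) == pytest.approx(expected, rel=1e-12)

    def test_translation_invariant_and_nonnegative(self, rng):
        s = random_structure(rng, 20)
        v = bounding_box_volume(s)
        shifted = s.with_positions(s.positions + [5.0, -3.0, 11.0])
        assert v >= 0
        assert bounding_box_volume(shifted) == pytest.approx(v, rel=1e-12)


class TestMinIntermolecularDistance:
    def test_single_pair(self):
        a = Structure([Atom("H", [0, 0, 0])])
        b = Structure([Atom("H", [1.7, 0, 0])])
        d, pair = min_intermolecular_distance(a, b)
        assert d == pytest.approx(1.700)
        assert pair == (0, 0)

    def test_matches_exhaustive_scan(self, rng):
        a = random_structure(rng, 20, name="a")
        b = random_structure(rng, 10, name="b")
        d, (i, j) = min_intermolecular_distance(a, b)
        brute = min(
            (float(np.linalg.norm(pa - pb)), ia, ib)
            for ia, pa in enumerate(a.positions)
            for ib, pb in enumerate(b.positions)
        )
        assert d == pytest.approx(brute[0], rel=1e-12)
        assert (i, j) == (brute[1], brute[2])

    def test_symmetry_and_rigid_invariance(self, rng):
        a = random_structure(rng, 8, name="a")
        b = random_structure(rng, 6, name="b")
        d_ab, _ = min_intermolecular_distance(a, b)
        d_ba, _ = min_intermolecular_distance(b, a)
        assert d_ab == pytest.approx(d_ba, rel=1e-14)
        rot = Rotation.random(rng=rng).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        d2, _ = min_intermolecular_distance(transform(a, rot, t), transform(b, rot, t))
        assert d2 == pytest.approx(d_ab, abs=1e-9)

    def test_reference_complex_reproduces_stored_minimum(self):
        """The packaged DSWAADIP/ethanol stand-in realizes the 1.700 Å
        extreme minimum distance, with an H···H closest pair."""
        from importlib import resources

        base = resources.files("pepadsorb.data")
        with resources.as_file(base / "synthetic_dswaadip_ethanol_host.xyz") as p:
            host = read_structure(p)
        with resources.as_file(base / "synthetic_dswaadip_ethanol_analyte.xyz") as p:
            analyte = read_structure(p)
        d, (i, j) = min_intermolecular_distance(host, analyte)
        assert d == pytest.approx(1.700, abs=1e-6)
        assert host.elements[i] == "H" and analyte.elements[j] == "H"


class TestTransform:
    def test_identity(self, water):
        s = transform(water, np.eye(3), [0, 0, 0])
        np.testing.assert_allclose(s.positions, water.positions)

    def test_z_rotation_closed_form(self):
        s = Structure([Atom("C", [1, 0, 0])])
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = transform(s, rot, [0, 0, 0])
        np.testing.assert_allclose(out.positions[0], [0, 1, 0], atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, 12)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-10, 10, 3)
        out = transform(s, rot, t)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(out.positions), pdist(s.positions), atol=1e-9)

    def test_rejects_improper_rotation(self, water):
        flip = np.diag([1.0, 1.0, -1.0])  # det = -1
        with pytest.raises(InputError):
            transform(water, flip, [0, 0, 0])


def test_all_or_none_charges_enforced():
    with pytest.raises(InputError):
        Structure([Atom("O", [0, 0, 0], -0.4), Atom("H", [1, 0, 0])])


def test_charge_file_parse_error(tmp_path):
    p = tmp_path / "bad.q"
    p.write_text("0.1\nnot-a-number\n")
    with pytest.raises(ParseError, match="line 2"):
        read_charge_file(p)
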