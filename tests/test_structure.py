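"""Structural geometry tests: parsing, axis, angles, dimer geometry."""

import math

import numpy as np
import pytest

from nucleocpd.structure import (
    Atom,
    MissingAtomError,
    NucleosomeStructure,
    PdbParseError,
    SuperhelixAxis,
    base_orientation_angle,
    dihedral_angle,
    estimate_superhelix_axis,
    mean_temperature_factor,
    parse_structure,
    photodimer_geometry,
)


PDB_SNIPPET = """\
ATOM      1  P    DT I   1      41.900   0.000   0.000  1.00 20.00           P
ATOM      2  C5   DT I   1      35.000   1.000   0.500  1.00 10.00           C
ATOM      3  C6   DT I   1      34.000   2.000   0.500  1.00 30.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  P  A DT I   1      10.000   0.000   0.000  0.60 20.00           P
ATOM      2  P  B DT I   1      99.000   0.000   0.000  0.40 20.00           P
END
"""

PDB_BAD = """\
ATOM      1  P    DT I   1      41.900   0.000   0.000  1.00 20.00           P
ATOM      2  C5   DT I   1      35.0xx   1.000   0.500  1.00 10.00           C
END
"""


def test_parse_small_snippet():
    st = parse_structure(PDB_SNIPPET)
    assert len(st.atoms) == 3
    np.testing.assert_allclose(st.atom_coord("I", 1, "P"), [41.9, 0.0, 0.0])
    np.testing.assert_allclose(st.atom_coord("I", 1, "C6"), [34.0, 2.0, 0.5])
    assert st.dna_chains == {"I"}


def test_altloc_highest_occupancy_retained():
    st = parse_structure(PDB_ALTLOC)
    assert len(st.atoms) == 1
    assert st.atom_coord("I", 1, "P")[0] == pytest.approx(10.0)


def test_waters_excluded():
    pdb = PDB_SNIPPET.replace("END\n", "") + (
        "HETATM    4  O   HOH W   1       1.000   2.000   3.000  1.00  5.00           O\nEND\n"
    )
    st = parse_structure(pdb)
    assert "HOH" not in set(st.atoms.residue_name)


def test_malformed_coordinate_names_line():
    with pytest.raises(PdbParseError, match="line 2"):
        parse_structure(PDB_BAD)


def _cylinder_structure(axis_rot=None, n=200, turns=8, pitch=0.0):
    rng = np.random.default_rng(0)
    theta = np.linspace(0.0, 2 * np.pi * turns, n, endpoint=False)
    pts = np.column_stack(
        [40 * np.cos(theta), 40 * np.sin(theta), pitch * theta / (2 * np.pi)]
    )
    if axis_rot is not None:
        pts = pts @ np.asarray(axis_rot).T
    atoms = [
        Atom("P", "DT", i + 1, "I", *pts[i], b_factor=1.0, occupancy=1.0)
        for i in range(n)
    ]
    return NucleosomeStructure.from_atoms(atoms)


def _rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def test_axis_of_z_cylinder():
    axis = estimate_superhelix_axis(_cylinder_structure())
    np.testing.assert_allclose(axis.direction, [0.0, 0.0, 1.0], atol=1e-6)


def test_axis_equivariance_under_rotation():
    R = _rotation_matrix([1.0, 2.0, 0.5], 0.7)
    axis = estimate_superhelix_axis(_cylinder_structure(axis_rot=R))
    rotated_z = R @ np.array([0.0, 0.0, 1.0])
    # sign convention may flip the direction; compare up to sign
    dot = abs(float(axis.direction @ rotated_z))
    assert dot == pytest.approx(1.0, abs=1e-6)


def test_axis_degenerate_sphere():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(500, 3))
    pts = 40 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
    atoms = [
        Atom("P", "DT", i + 1, "I", *pts[i], b_factor=1.0, occupancy=1.0)
        for i in range(len(pts))
    ]
    with pytest.raises(ValueError, match="degenerate"):
        estimate_superhelix_axis(NucleosomeStructure.from_atoms(atoms))


def test_axis_needs_enough_phosphorus():
    with pytest.raises(ValueError, match="phosphorus"):
        estimate_superhelix_axis(_cylinder_structure(n=5))


def _base_structure(bisect_dir, centroid=(30.0, 0.0, 0.0), perp=(0.0, 0.0, 1.0)):
    """Hexagonal pyrimidine ring whose C6N1->N3C4 bisector points along
    ``bisect_dir``."""
    b = np.asarray(bisect_dir, dtype=float)
    b /= np.linalg.norm(b)
    c = np.cross(b, perp)
    if np.linalg.norm(c) < 1e-9:
        c = np.cross(b, [0.0, 1.0, 0.0])
    c /= np.linalg.norm(c)
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = []
    for k, name in enumerate(names):
        theta = math.radians(-150.0 + 60.0 * k)
        pos = np.asarray(centroid) + 1.4 * (math.cos(theta) * b + math.sin(theta) * c)
        atoms.append(Atom(name, "DC", 1, "I", *pos, b_factor=5.0, occupancy=1.0))
    return NucleosomeStructure.from_atoms(atoms)


Z_AXIS = SuperhelixAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


@pytest.mark.parametrize(
    "bisect_dir,expected_deg",
    [((1.0, 0.0, 0.0), 0.0), ((-1.0, 0.0, 0.0), 180.0), ((0.0, 0.0, 1.0), 90.0)],
)
def test_base_orientation_constructed_angles(bisect_dir, expected_deg):
    st = _base_structure(bisect_dir)
    bo = base_orientation_angle(st, "I", 1, Z_AXIS)
    assert bo.angle_deg == pytest.approx(expected_deg, abs=1e-6)
    assert bo.radial_distance_A == pytest.approx(30.0, abs=1e-6)


def test_base_orientation_requires_pyrimidine_ring():
    st = _base_structure((1.0, 0.0, 0.0))
    df = st.atoms[st.atoms.name != "N3"].copy()
    broken = NucleosomeStructure(df, st.dna_chains, st.protein_chains)
    with pytest.raises(MissingAtomError):
        base_orientation_angle(broken, "I", 1, Z_AXIS)
    purine = st.atoms.copy()
    purine["residue_name"] = "DG"
    with pytest.raises(ValueError, match="not a pyrimidine"):
        base_orientation_angle(
            NucleosomeStructure(purine, st.dna_chains, st.protein_chains), "I", 1, Z_AXIS
        )


def test_mean_temperature_factor():
    st = parse_structure(PDB_SNIPPET)
    assert mean_temperature_factor(st, "I", 1) == pytest.approx(20.0)
    single = NucleosomeStructure.from_atoms(
        [Atom("P", "DT", 1, "I", 0, 1, 2, b_factor=7.3, occupancy=1.0)]
    )
    assert mean_temperature_factor(single, "I", 1) == pytest.approx(7.3)


def _stacked_bond_structure(shift=(0.0, 0.0, 0.0), torsion_deg=0.0):
    """Two C5-C6 bonds stacked 3.4 A apart along z; the upper bond can be
    twisted about the stacking axis and translated."""
    atoms = []
    c5 = np.array([-0.7, 0.0, 0.0])
    c6 = np.array([0.7, 0.0, 0.0])
    for name, pos in (("C5", c5), ("C6", c6)):
        atoms.append(Atom(name, "DT", 1, "I", *pos, b_factor=1.0, occupancy=1.0))
    ang = math.radians(torsion_deg)
    R = np.array(
        [[math.cos(ang), -math.sin(ang), 0], [math.sin(ang), math.cos(ang), 0], [0, 0, 1]]
    )
    # rotate about the bond centre so eclipsed (0 deg) keeps atoms aligned
    for name, pos in (("C5", c5), ("C6", c6)):
        p = R @ pos + np.array([0.0, 0.0, 3.4]) + np.asarray(shift)
        atoms.append(Atom(name, "DT", 2, "I", *p, b_factor=1.0, occupancy=1.0))
    return NucleosomeStructure.from_atoms(atoms)


def test_photodimer_eclipsed_stack():
    st = _stacked_bond_structure()
    g = photodimer_geometry(st, "I", 1, 2)
    assert g.interbond_distance_A == pytest.approx(3.4, abs=1e-9)
    assert g.improper_torsion_deg == pytest.approx(0.0, abs=1e-9)


def test_photodimer_translation_updates_distance_not_torsion():
    st = _stacked_bond_structure(shift=(1.0, 0.0, 0.0))
    g = photodimer_geometry(st, "I", 1, 2)
    assert g.interbond_distance_A == pytest.approx(math.hypot(1.0, 3.4), abs=1e-9)
    assert g.improper_torsion_deg == pytest.approx(0.0, abs=1e-6)


def test_photodimer_anti_eclipsed():
    st = _stacked_bond_structure(torsion_deg=180.0)
    g = photodimer_geometry(st, "I", 1, 2)
    assert abs(g.improper_torsion_deg) == pytest.approx(180.0, abs=1e-6)


def test_photodimer_requires_sequential_residues():
    st = _stacked_bond_structure()
    with pytest.raises(ValueError, match="sequential"):
        photodimer_geometry(st, "I", 2, 1)


def test_dihedral_symmetries():
    st = _stacked_bond_structure(torsion_deg=35.0)
    c5_1 = st.atom_coord("I", 1, "C5")
    c6_1 = st.atom_coord("I", 1, "C6")
    c5_2 = st.atom_coord("I", 2, "C5")
    c6_2 = st.atom_coord("I", 2, "C6")
    d_fwd = dihedral_angle(c5_1, c6_1, c6_2, c5_2)
    # full reversal of the four points preserves the dihedral ...
    assert dihedral_angle(c5_2, c6_2, c6_1, c5_1) == pytest.approx(d_fwd, abs=1e-9)
    # ... while a mirror reflection flips its sign
    mirror = np.diag([1.0, -1.0, 1.0])
    d_mirror = dihedral_angle(*(mirror @ p for p in (c5_1, c6_1, c6_2, c5_2)))
    assert d_mirror == pytest.approx(-d_fwd, abs=1e-9)
    assert d_fwd != 0.0


def test_dihedral_matches_independent_implementation(rng):
    """Cross-check the four-point dihedral against biotite on random
    coordinate quadruples."""
    from biotite.structure import dihedral as biotite_dihedral

    for _ in range(50):
        pts = rng.normal(size=(4, 3)) * 5.0
        ours = dihedral_angle(*pts)
        ref = math.degrees(float(biotite_dihedral(*pts)))
        # compare circularly; biotite computes in float32
        diff = (ours - ref + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-3


def test_rigid_motion_invariance(helix_structure, rng):
    """Angles, distances, torsions and mean B are unchanged by random
    rigid-body transforms of the whole structure."""
    axis0 = estimate_superhelix_axis(helix_structure)
    ref_angle = base_orientation_angle(helix_structure, "I", 4, axis0)
    ref_geom = photodimer_geometry(helix_structure, "I", 7, 8)
    ref_b = mean_temperature_factor(helix_structure, "I", 4)
    for _ in range(5):
        R = _rotation_matrix(rng.normal(size=3), rng.uniform(0, 2 * np.pi))
        t = rng.normal(size=3) * 50.0
        moved = helix_structure.transformed(R, t)
        axis = estimate_superhelix_axis(moved)
        bo = base_orientation_angle(moved, "I", 4, axis)
        assert bo.angle_deg == pytest.approx(ref_angle.angle_deg, abs=1e-6)
        assert bo.radial_distance_A == pytest.approx(ref_angle.radial_distance_A, abs=1e-6)
        g = photodimer_geometry(moved, "I", 7, 8)
        assert g.interbond_distance_A == pytest.approx(ref_geom.interbond_distance_A, abs=1e-9)
        assert abs(g.improper_torsion_deg) == pytest.approx(
            abs(ref_geom.improper_torsion_deg), abs=1e-6
        )
        assert mean_temperature_factor(moved, "I", 4) == pytest.approx(ref_b)
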