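"""Structure parsing, bond perception and keto-enol fragment measurement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from aiblpka import (Molecule3D, bond_length, detect_keto_enol_fragment,
                     extract_features, perceive_bonds, read_sdf, read_xyz)
from aiblpka.errors import (FragmentNotFoundError, ParseError,
                            UnsupportedDialectError)
from aiblpka.geometry import BondFeatureVector, KetoEnolFragment, dihedral
from aiblpka.synthetic import generate_fragment_geometry, write_xyz


# --- XYZ ------------------------------------------------------------------

WATER = "3\nwater\nO 0 0 0\nH 0.97 0 0\nH -0.24 0.93 0\n"


def test_read_xyz_water(tmp_path):
    p = tmp_path / "w.xyz"
    p.write_text(WATER)
    mol = read_xyz(p)
    assert mol.n_atoms == 3 and mol.bonds == [] and mol.name == "water"
    assert mol.symbols == ["O", "H", "H"]
    np.testing.assert_allclose(mol.coords[1], [0.97, 0, 0])


@pytest.mark.parametrize("content,msg", [
    ("", "empty file"),
    ("2\nc\nO 0 0 0\nH 1 0 0\nH 0 1 0\n", "2 atoms but 3"),
    ("not_a_count\nc\nO 0 0 0\n", "malformed atom count"),
    ("1\nc\nO a b c\n", "non-numeric"),
    ("1\nc\nXx 0 0 0\n", "unknown element"),
], ids=["empty", "count-mismatch", "bad-count", "bad-coord", "bad-element"])
def test_read_xyz_errors(tmp_path, content, msg):
    p = tmp_path / "bad.xyz"
    p.write_text(content)
    with pytest.raises(ParseError, match=msg):
        read_xyz(p)


def test_xyz_roundtrip(tmp_path, ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    p = tmp_path / "frag.xyz"
    write_xyz(mol, p)
    back = read_xyz(p)
    assert back.symbols == mol.symbols
    np.testing.assert_allclose(back.coords, mol.coords, atol=1e-9)


# --- SDF/MOL --------------------------------------------------------------

def ethanol_molblock(counts_extra="", nbonds=8):
    atoms = [("C", -0.89, 0.17, 0.0), ("C", 0.46, -0.44, 0.0),
             ("O", 1.44, 0.55, 0.0), ("H", -1.64, -0.61, 0.0),
             ("H", -1.02, 0.79, 0.88), ("H", -1.02, 0.79, -0.88),
             ("H", 0.59, -1.07, 0.88), ("H", 0.59, -1.07, -0.88),
             ("H", 2.30, 0.12, 0.0)]
    bonds = [(1, 2), (2, 3), (1, 4), (1, 5), (1, 6), (2, 7), (2, 8), (3, 9)]
    lines = ["ethanol", "  test", "",
             f"  9  {nbonds}  0  0  0  0  0  0  0  0999 V2000{counts_extra}"]
    for s, x, y, z in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {s:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b in bonds[:nbonds]:
        lines.append(f"{a:3d}{b:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def test_read_sdf_single(tmp_path):
    p = tmp_path / "e.mol"
    p.write_text(ethanol_molblock())
    mols = read_sdf(p)
    assert len(mols) == 1
    assert mols[0].n_atoms == 9 and len(mols[0].bonds) == 8
    assert mols[0].name == "ethanol"


def test_read_sdf_two_records(tmp_path):
    p = tmp_path / "two.sdf"
    p.write_text(ethanol_molblock() + "$$$$\n" + ethanol_molblock() + "$$$$\n")
    assert len(read_sdf(p)) == 2


def test_read_sdf_bond_atom_zero(tmp_path):
    block = ethanol_molblock().replace("  1  2  1  0", "  0  2  1  0")
    p = tmp_path / "z.mol"
    p.write_text(block)
    with pytest.raises(ParseError, match="1-based"):
        read_sdf(p)


def test_read_sdf_v3000_rejected(tmp_path):
    p = tmp_path / "v3.mol"
    p.write_text("m\n\n\n  0  0  0     0  0            999 V3000\nM  END\n")
    with pytest.raises(UnsupportedDialectError):
        read_sdf(p)


def test_read_sdf_truncated(tmp_path):
    p = tmp_path / "t.mol"
    p.write_text("\n".join(ethanol_molblock().splitlines()[:8]))
    with pytest.raises(ParseError, match="truncated"):
        read_sdf(p)


# --- bond perception & lengths -------------------------------------------

def test_perceive_oh_bonded():
    mol = Molecule3D(["O", "H"], [[0, 0, 0], [0.97, 0, 0]])
    assert perceive_bonds(mol, 1.2).bonds == [(0, 1)]


def test_perceive_distant_carbons_not_bonded():
    mol = Molecule3D(["C", "C"], [[0, 0, 0], [2.0, 0, 0]])
    assert perceive_bonds(mol, 1.2).bonds == []


def benzene():
    ang = np.arange(6) * np.pi / 3
    cc = np.c_[1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)]
    ch = np.c_[(1.39 + 1.09) * np.cos(ang), (1.39 + 1.09) * np.sin(ang), np.zeros(6)]
    return Molecule3D(["C"] * 6 + ["H"] * 6, np.vstack([cc, ch]))


def test_perceive_benzene_matches_bruteforce():
    mol = perceive_bonds(benzene(), 1.2)
    # independent brute force over all pairs with the same rule
    from aiblpka.radii import covalent_radius
    expect = set()
    for i in range(12):
        for j in range(i + 1, 12):
            d = np.linalg.norm(mol.coords[i] - mol.coords[j])
            if d <= 1.2 * (covalent_radius(mol.symbols[i]) + covalent_radius(mol.symbols[j])):
                expect.add((i, j))
    assert set(mol.bonds) == expect and len(mol.bonds) == 12


def test_perceive_unknown_radius():
    mol = Molecule3D(["O"], [[0, 0, 0]])
    mol.symbols = ["Og"]  # bypass parser validation
    with pytest.raises(KeyError, match="Og"):
        perceive_bonds(mol)


@given(st.integers(0, 2**31 - 1))
def test_perceive_bonds_rigid_motion_invariant(seed):
    rng = np.random.default_rng(seed)
    mol = benzene()
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(size=3, scale=5.0)
    moved = Molecule3D(mol.symbols, mol.coords @ rot.T + shift)
    assert perceive_bonds(moved).bonds == perceive_bonds(mol).bonds


def test_bond_length_cases():
    mol = Molecule3D(["C", "C"], [[0, 0, 0], [1, 1, 1]])
    assert bond_length(mol, 0, 1) == pytest.approx(np.sqrt(3), abs=1e-12)
    with pytest.raises(ValueError):
        bond_length(mol, 0, 0)
    with pytest.raises(IndexError):
        bond_length(mol, 0, 5)


# --- fragment detection ---------------------------------------------------

def test_fragment_detection_anti(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    frag = detect_keto_enol_fragment(mol)
    assert frag.ring_size == 6
    assert frag.conformer == "anti"
    assert abs(frag.torsion_deg) == pytest.approx(180.0, abs=1e-9)
    feats = extract_features(mol, frag)
    np.testing.assert_allclose(feats.as_array(), ideal_lengths.as_array(),
                               atol=1e-9)


@pytest.mark.parametrize("torsion,label", [
    (0.0, "syn"), (89.9, "syn"), (90.1, "anti"), (180.0, "anti"),
    (-89.9, "syn"), (-90.1, "anti"),
])
def test_conformer_flips_at_90_degrees(ideal_lengths, torsion, label):
    mol = generate_fragment_geometry(ideal_lengths, torsion)
    assert detect_keto_enol_fragment(mol).conformer == label


def test_cyclohexane_has_no_fragment():
    ang = np.arange(6) * np.pi / 3
    coords = np.c_[1.53 * np.cos(ang), 1.53 * np.sin(ang), np.zeros(6)]
    mol = Molecule3D(["C"] * 6, coords,
                     [(i, (i + 1) % 6) for i in range(6)])
    with pytest.raises(FragmentNotFoundError):
        detect_keto_enol_fragment(mol)


def test_missing_hydroxyl_hydrogen_is_named(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    heavy = [i for i, s in enumerate(mol.symbols) if s != "H"]
    remap = {old: new for new, old in enumerate(heavy)}
    bonds = [(remap[a], remap[b]) for a, b in mol.bonds
             if a in remap and b in remap]
    stripped = Molecule3D([mol.symbols[i] for i in heavy],
                          mol.coords[heavy], bonds)
    with pytest.raises(FragmentNotFoundError, match="no hydroxyl H"):
        detect_keto_enol_fragment(stripped)


def test_extract_features_rigid_motion_and_reordering(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    frag = detect_keto_enol_fragment(mol)
    rng = np.random.default_rng(7)
    rot = Rotation.random(rng=rng).as_matrix()
    perm = rng.permutation(mol.n_atoms)
    inv = np.argsort(perm)
    moved = Molecule3D([mol.symbols[i] for i in perm],
                       (mol.coords @ rot.T + 3.0)[perm],
                       [(int(inv[a]), int(inv[b])) for a, b in mol.bonds])
    remapped = KetoEnolFragment(
        ring_size=frag.ring_size, idx_H=int(inv[frag.idx_H]),
        idx_O_enol=int(inv[frag.idx_O_enol]), idx_C1=int(inv[frag.idx_C1]),
        idx_C2=int(inv[frag.idx_C2]), idx_C3=int(inv[frag.idx_C3]),
        idx_O_keto=int(inv[frag.idx_O_keto]), conformer=frag.conformer,
        torsion_deg=frag.torsion_deg)
    np.testing.assert_allclose(extract_features(moved, remapped).as_array(),
                               extract_features(mol, frag).as_array(),
                               atol=1e-9)


def test_uniform_scaling_scales_features(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    frag = detect_keto_enol_fragment(mol)
    scaled = Molecule3D(mol.symbols, mol.coords * 1.01, mol.bonds)
    np.testing.assert_allclose(extract_features(scaled, frag).as_array(),
                               1.01 * extract_features(mol, frag).as_array(),
                               rtol=1e-12)


def test_extract_features_bad_index(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 180.0)
    frag = detect_keto_enol_fragment(mol)
    small = Molecule3D(mol.symbols[:8], mol.coords[:8],
                       [(a, b) for a, b in mol.bonds if a < 8 and b < 8])
    with pytest.raises(IndexError):
        extract_features(small, frag)


def test_feature_vector_validation():
    with pytest.raises(ValueError):
        BondFeatureVector(0.4, 1.33, 1.37, 1.44, 1.24)   # below window
    with pytest.raises(ValueError):
        BondFeatureVector(1.5, 1.33, 1.37, 1.44, 1.24)   # O-H >= C-O


def test_dihedral_signs(ideal_lengths):
    mol = generate_fragment_geometry(ideal_lengths, 57.3)
    frag = detect_keto_enol_fragment(mol)
    assert dihedral(mol, frag.idx_C2, frag.idx_C1, frag.idx_O_enol,
                    frag.idx_H) == pytest.approx(57.3, abs=1e-9)


def test_multiple_candidates_pick_shortest_oh(ideal_lengths):
    # two disjoint keto-enol fragments in one structure: the one with the
    # shorter O-H bond wins, deterministically, with a warning
    short = generate_fragment_geometry(ideal_lengths, 180.0)
    longer = generate_fragment_geometry(
        BondFeatureVector(1.01, 1.33, 1.37, 1.44, 1.24), 180.0)
    coords = np.vstack([short.coords, longer.coords + [20.0, 0, 0]])
    off = short.n_atoms
    bonds = short.bonds + [(a + off, b + off) for a, b in longer.bonds]
    both = Molecule3D(short.symbols + longer.symbols, coords, bonds, "pair")
    with pytest.warns(UserWarning, match="2 candidate"):
        frag = detect_keto_enol_fragment(both)
    assert frag.n_candidates == 2
    assert bond_length(both, frag.idx_O_enol, frag.idx_H) == pytest.approx(
        0.99, abs=1e-9)
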