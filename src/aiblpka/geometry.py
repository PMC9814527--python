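"""3D structures, bond perception and keto-enol fragment measurement.

The pKa of an enolised cyclic 1,3-dione is encoded in the geometry of its
keto-enol fragment, the C(=O)-C=C-O-H path on the 5- or 6-membered ring.
This module parses optimized geometries (XYZ, MOL/SDF V2000), perceives
covalent bonds from interatomic distances where the file supplies none,
locates the keto-enol fragment, and measures the five diagnostic bond
lengths used as regression features:

    i    O-H      (enolic hydroxyl)
    ii   C-O      (enol C-O single bond)
    iii  C=C      (endocyclic formal double bond)
    iv   C-C      (endocyclic single bond)
    v    C=O      (exocyclic keto carbonyl)

All coordinates and lengths are in angstroms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import FragmentNotFoundError, ParseError, UnsupportedDialectError
from .radii import COVALENT_RADII, covalent_radius

__all__ = [
    "Molecule3D",
    "KetoEnolFragment",
    "BondFeatureVector",
    "read_xyz",
    "read_sdf",
    "perceive_bonds",
    "bond_length",
    "dihedral",
    "detect_keto_enol_fragment",
    "extract_features",
]

BOND_ROMAN = ("i", "ii", "iii", "iv", "v")
FEATURE_NAMES = ("r_OH", "r_CO", "r_CC_double", "r_CC_single", "r_CO_double")


@dataclass
class Molecule3D:
    """A molecule as element symbols plus Cartesian coordinates in Å.

    ``bonds`` holds unordered atom-index pairs; it may be empty until
    perceived from distances or populated from a connection table.
    """

    symbols: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.symbols)
        if n < 1:
            raise ValueError("a molecule needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int]] = []
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) references an atom out of range")
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append(key)
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def neighbors(self, i: int) -> list[int]:
        """Indices bonded to atom ``i``."""
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


@dataclass
class KetoEnolFragment:
    """Atom indices of the O-H / C-O / C=C / C-C / C=O path plus conformer.

    ``torsion_deg`` is the C2-C1-O_enol-H dihedral; the enolic hydroxyl is
    *syn* to the ring near 0° and *anti* near 180°, with the boundary fixed
    at |torsion| = 90°.
    """

    ring_size: int
    idx_H: int
    idx_O_enol: int
    idx_C1: int
    idx_C2: int
    idx_C3: int
    idx_O_keto: int
    conformer: str
    torsion_deg: float
    n_candidates: int = 1

    def __post_init__(self) -> None:
        if self.ring_size not in (5, 6):
            raise ValueError("ring_size must be 5 or 6")
        idx = (self.idx_H, self.idx_O_enol, self.idx_C1, self.idx_C2,
               self.idx_C3, self.idx_O_keto)
        if len(set(idx)) != 6:
            raise ValueError("fragment atom indices must be distinct")
        expected = "anti" if abs(self.torsion_deg) > 90.0 else "syn"
        if self.conformer != expected:
            raise ValueError(
                f"conformer {self.conformer!r} inconsistent with torsion "
                f"{self.torsion_deg:.1f}°"
            )


@dataclass(frozen=True)
class BondFeatureVector:
    """The five keto-enol fragment bond lengths i-v in Å."""

    r_OH: float
    r_CO: float
    r_CC_double: float
    r_CC_single: float
    r_CO_double: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not (0.5 < v < 3.0):
                raise ValueError(f"{name} = {v} Å outside the plausible (0.5, 3.0) window")
        if not self.r_OH < self.r_CO:
            raise ValueError("O-H must be shorter than C-O in a valid fragment")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# file parsing


def read_xyz(path) -> Molecule3D:
    """Read a single-structure XYZ file.

    The first line is the atom count, the second a free-text comment (used
    as the molecule name) and each following line ``symbol x y z``.  Bonds
    are left empty; use :func:`perceive_bonds`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: line 1: empty file or missing atom count")
    try:
        count = int(lines[0].split()[0])
    except ValueError:
        raise ParseError(f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    if count < 1:
        raise ParseError(f"{path}: line 1: atom count must be positive")
    name = lines[1].strip() if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(
            f"{path}: header declares {count} atoms but {len(body)} atom lines found"
        )
    symbols: list[str] = []
    coords = np.empty((count, 3))
    for k, ln in enumerate(body):
        parts = ln.split()
        lineno = 3 + k
        if len(parts) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 'symbol x y z'")
        sym = parts[0].capitalize()
        if sym not in COVALENT_RADII:
            raise ParseError(f"{path}: line {lineno}: unknown element symbol {parts[0]!r}")
        try:
            xyz = [float(p.replace("−", "-")) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric coordinate") from None
        symbols.append(sym)
        coords[k] = xyz
    return Molecule3D(symbols, coords, [], name)


def read_sdf(path) -> list[Molecule3D]:
    """Read all records of an SDF (or single MOL) file, V2000 dialect.

    Bond orders in the connection table are advisory only; the bond list of
    the returned molecules records connectivity alone.
    """
    with open(path) as fh:
        text = fh.read()
    records = [r for r in text.split("$$$$") if r.strip()]
    if not records:
        raise ParseError(f"{path}: no records")
    return [_parse_molblock(rec, path, i) for i, rec in enumerate(records)]


def _parse_molblock(block: str, path, rec_no: int) -> Molecule3D:
    lines = block.strip("\n").split("\n")
    where = f"{path}: record {rec_no + 1}"
    if len(lines) < 4:
        raise ParseError(f"{where}: truncated header")
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedDialectError(f"{where}: MOL V3000 is not supported (V2000 only)")
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError:
        raise ParseError(f"{where}: malformed counts line {counts!r}") from None
    if len(lines) < 4 + natoms + nbonds:
        raise ParseError(f"{where}: truncated record")
    symbols: list[str] = []
    coords = np.empty((natoms, 3))
    for k in range(natoms):
        ln = lines[4 + k]
        try:
            coords[k] = (float(ln[0:10]), float(ln[10:20]), float(ln[20:30]))
            sym = ln[31:34].strip().capitalize()
        except (ValueError, IndexError):
            raise ParseError(f"{where}: malformed atom line {k + 1}") from None
        if sym not in COVALENT_RADII:
            raise ParseError(f"{where}: unknown element symbol {sym!r}")
        symbols.append(sym)
    bonds: list[tuple[int, int]] = []
    for k in range(nbonds):
        ln = lines[4 + natoms + k]
        try:
            a, b = int(ln[0:3]), int(ln[3:6])
        except (ValueError, IndexError):
            raise ParseError(f"{where}: malformed bond line {k + 1}") from None
        if not (1 <= a <= natoms and 1 <= b <= natoms):
            raise ParseError(
                f"{where}: bond line {k + 1} references atom {min(a, b)} "
                f"(MOL indices are 1-based)"
            )
        bonds.append((a - 1, b - 1))
    return Molecule3D(symbols, coords, bonds, lines[0].strip())


# ---------------------------------------------------------------------------
# geometry primitives


def perceive_bonds(mol: Molecule3D, tolerance: float = 1.2) -> Molecule3D:
    """Assign bonds from interatomic distances.

    Atoms i, j are bonded iff d(i, j) <= tolerance * (r_cov(i) + r_cov(j)),
    with covalent radii from the bundled table.  Returns a new molecule;
    any existing bond list is replaced.
    """
    if not (1.0 <= tolerance <= 1.5):
        raise ValueError("tolerance must lie in [1.0, 1.5]")
    radii = np.array([covalent_radius(s) for s in mol.symbols])
    d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    cutoff = tolerance * (radii[:, None] + radii[None, :])
    bonded = (d <= cutoff) & ~np.eye(mol.n_atoms, dtype=bool)
    pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(bonded)))]
    return Molecule3D(list(mol.symbols), mol.coords.copy(), pairs, mol.name)


def bond_length(mol: Molecule3D, i: int, j: int) -> float:
    """Euclidean distance between atoms ``i`` and ``j`` in Å."""
    n = mol.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (molecule has {n} atoms)")
    if i == j:
        raise ValueError("bond length requires two distinct atoms")
    return float(np.linalg.norm(mol.coords[i] - mol.coords[j]))


def dihedral(mol: Molecule3D, a: int, b: int, c: int, d: int) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    p = mol.coords
    b1, b2, b3 = p[b] - p[a], p[c] - p[b], p[d] - p[c]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = float(np.dot(n1, n2)), float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


# ---------------------------------------------------------------------------
# fragment perception


def _rings(mol: Molecule3D, sizes=(5, 6)) -> list[list[int]]:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from(mol.bonds)
    return [list(c) for c in nx.simple_cycles(g, length_bound=max(sizes))
            if len(c) in sizes]


def detect_keto_enol_fragment(mol: Molecule3D) -> KetoEnolFragment:
    """Locate the enolised 1,3-dione fragment on a 5- or 6-membered ring.

    Searches every ring of size 5 or 6 for consecutive ring carbons
    C3-C2-C1 such that C1 bears an exocyclic hydroxyl oxygen (exactly one
    bonded H), C3 bears an exocyclic keto oxygen (no bonded H), and the
    C1-C2 ring bond is shorter than the other ring bond at C1 (the formal
    C=C double bond).  When several candidate fragments exist — e.g. in a
    triketone with two conceivable enolisation sites — the one with the
    shortest O-H bond is returned, a warning is emitted, and the candidate
    count is recorded on the fragment.
    """
    if not mol.bonds:
        raise FragmentNotFoundError("molecule has no bonds; perceive or supply them first")
    candidates: list[KetoEnolFragment] = []
    saw_bare_enol_oxygen = False
    for ring in _rings(mol):
        size = len(ring)
        for k in range(size):
            for step in (1, -1):
                c1 = ring[k]
                c2 = ring[(k + step) % size]
                c3 = ring[(k + 2 * step) % size]
                if any(mol.symbols[a] != "C" for a in (c1, c2, c3)):
                    continue
                ring_set = set(ring)
                o_enol = o_keto = h = None
                for nb in mol.neighbors(c1):
                    if nb not in ring_set and mol.symbols[nb] == "O":
                        hs = [m for m in mol.neighbors(nb) if mol.symbols[m] == "H"]
                        if len(hs) == 1:
                            o_enol, h = nb, hs[0]
                        elif len(hs) == 0:
                            saw_bare_enol_oxygen = True
                if o_enol is None:
                    continue
                for nb in mol.neighbors(c3):
                    if nb not in ring_set and nb != o_enol and mol.symbols[nb] == "O":
                        if not any(mol.symbols[m] == "H" for m in mol.neighbors(nb)):
                            o_keto = nb
                if o_keto is None:
                    continue
                # formal double bond check: C1-C2 shorter than C1's other ring bond
                other = [a for a in mol.neighbors(c1) if a in ring_set and a != c2]
                if other and bond_length(mol, c1, c2) >= bond_length(mol, c1, other[0]):
                    continue
                tors = dihedral(mol, c2, c1, o_enol, h)
                candidates.append(KetoEnolFragment(
                    ring_size=size, idx_H=h, idx_O_enol=o_enol, idx_C1=c1,
                    idx_C2=c2, idx_C3=c3, idx_O_keto=o_keto,
                    conformer="anti" if abs(tors) > 90.0 else "syn",
                    torsion_deg=tors,
                ))
    # the same fragment can be reached from several ring traversals; dedupe
    unique = {(f.idx_H, f.idx_O_enol, f.idx_C1, f.idx_C2, f.idx_C3, f.idx_O_keto): f
              for f in candidates}
    if not unique:
        if saw_bare_enol_oxygen:
            raise FragmentNotFoundError(
                "no hydroxyl H: an enol-like ring oxygen was found but it carries "
                "no hydrogen (heavy-atom-only input?)"
            )
        raise FragmentNotFoundError("no keto-enol fragment found")
    frags = sorted(unique.values(),
                   key=lambda f: (bond_length(mol, f.idx_O_enol, f.idx_H), f.idx_C1))
    best = frags[0]
    best.n_candidates = len(frags)
    if len(frags) > 1:
        warnings.warn(
            f"{len(frags)} candidate keto-enol fragments in {mol.name or 'molecule'}; "
            "returning the one with the shortest O-H bond",
            stacklevel=2,
        )
    return best


def extract_features(mol: Molecule3D, frag: KetoEnolFragment) -> BondFeatureVector:
    """Measure the five fragment bond lengths i-v from a located fragment."""
    for idx in (frag.idx_H, frag.idx_O_enol, frag.idx_C1, frag.idx_C2,
                frag.idx_C3, frag.idx_O_keto):
        if not (0 <= idx < mol.n_atoms):
            raise IndexError(f"fragment atom index {idx} not present in molecule")
    return BondFeatureVector(
        r_OH=bond_length(mol, frag.idx_O_enol, frag.idx_H),
        r_CO=bond_length(mol, frag.idx_C1, frag.idx_O_enol),
        r_CC_double=bond_length(mol, frag.idx_C1, frag.idx_C2),
        r_CC_single=bond_length(mol, frag.idx_C2, frag.idx_C3),
        r_CO_double=bond_length(mol, frag.idx_C3, frag.idx_O_keto),
    )
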