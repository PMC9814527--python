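"""Synthetic congeneric series with linear bond-length/pKa structure.

Within a congeneric series the pKa of an enolised 1,3-dione varies
linearly with the enol C-O bond length, and the remaining fragment bonds
co-vary with it: as acidity increases the O-H and C=C bonds lengthen
while C-O shortens.  The generator emulates exactly that structure — a
per-series slope and intercept on r(C-O), Gaussian pKa noise, and a
one-factor correlation model tying the other four bonds to r(C-O) — so
that every modelling stage (fitting, subset selection, outlier flagging)
can be exercised with known ground truth.  It makes no attempt at
DFT-level geometric realism beyond bond lengths and ring planarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CompoundRecord, Dataset
from .geometry import FEATURE_NAMES, BondFeatureVector, Molecule3D

__all__ = [
    "SeriesSpec", "DEFAULT_LENGTH_RANGES", "default_correlations",
    "generate_series", "generate_two_series", "generate_fragment_geometry",
    "write_xyz",
]

#: Chemically plausible windows for each fragment bond (Å).  r_CO is the
#: driving feature; the others are centred in their window and co-vary.
DEFAULT_LENGTH_RANGES: dict[str, tuple[float, float]] = {
    "r_OH": (0.96, 1.02),
    "r_CO": (1.30, 1.36),
    "r_CC_double": (1.34, 1.40),
    "r_CC_single": (1.42, 1.48),
    "r_CO_double": (1.21, 1.27),
}

#: Correlation of each bond with r_CO, encoding the observed sign pattern:
#: with a positive slope (pKa grows with r_CO, i.e. acidity falls), the
#: O-H and C=C bonds shorten (negative sign) while C-C and C=O co-vary
#: positively.  |rho| = 0.9 is a documented default, not a fitted value.
DEFAULT_RHO = {"r_OH": -0.9, "r_CO": 1.0, "r_CC_double": -0.9,
               "r_CC_single": 0.9, "r_CO_double": 0.9}


def default_correlations() -> np.ndarray:
    """One-factor 5x5 feature correlation matrix, unit diagonal, PSD."""
    rho = np.array([DEFAULT_RHO[n] for n in FEATURE_NAMES])
    R = np.outer(rho, rho)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class SeriesSpec:
    """Parameters of one synthetic congeneric series."""

    label: str = "syn"
    n_compounds: int = 49
    slope: float = 93.381            # pKa per Å of r_CO
    intercept: float = -127.71       # pKa
    length_range: tuple[float, float] = DEFAULT_LENGTH_RANGES["r_CO"]
    noise_sd: float = 0.3            # pKa units
    cross_correlations: np.ndarray = field(default_factory=default_correlations)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 3:
            raise ValueError("a series needs at least 3 compounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        R = np.asarray(self.cross_correlations, dtype=float)
        if R.shape != (5, 5) or not np.allclose(R, R.T):
            raise ValueError("cross_correlations must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix needs a unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        self.cross_correlations = R


def _feature_rows(spec: SeriesSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.length_range
    r_co = rng.uniform(lo, hi, size=spec.n_compounds)
    u = (r_co - r_co.mean()) / (r_co.std() if r_co.std() > 0 else 1.0)
    co_idx = FEATURE_NAMES.index("r_CO")
    rho = spec.cross_correlations[co_idx]
    X = np.empty((spec.n_compounds, 5))
    for j, name in enumerate(FEATURE_NAMES):
        if name == "r_CO":
            X[:, j] = r_co
            continue
        a, b = DEFAULT_LENGTH_RANGES[name]
        centre, scale = 0.5 * (a + b), 0.25 * (b - a)
        eps = rng.normal(size=spec.n_compounds)
        z = rho[j] * u + np.sqrt(max(0.0, 1.0 - rho[j] ** 2)) * eps
        X[:, j] = centre + scale * z
    return X


def generate_series(spec: SeriesSpec) -> Dataset:
    """Draw one congeneric series; fully deterministic given ``spec.seed``.

    r_CO is uniform on ``length_range``; the other four bonds follow the
    one-factor correlation model; pKa = slope*r_CO + intercept + N(0, sd).
    """
    rng = np.random.default_rng(spec.seed)
    X = _feature_rows(spec, rng)
    co = X[:, FEATURE_NAMES.index("r_CO")]
    pka = spec.slope * co + spec.intercept + rng.normal(0.0, spec.noise_sd,
                                                        size=spec.n_compounds)
    records = []
    for i in range(spec.n_compounds):
        feats = BondFeatureVector(**dict(zip(FEATURE_NAMES, X[i])))
        records.append(CompoundRecord(
            id=f"{spec.label}{i + 1}", pka_exp=float(pka[i]),
            series=spec.label, features=feats))
    return Dataset(records, provenance=f"synthetic series {spec.label} seed={spec.seed}")


def generate_two_series(spec_base: SeriesSpec, slope_ratio: float) -> Dataset:
    """Two labelled series whose slopes differ by ``slope_ratio``.

    Emulates a congeneric-series pair whose bond/pKa lines share structure
    but not steepness (e.g. a second series ~22% steeper), the situation in
    which per-series fits outperform one pooled line.
    """
    if slope_ratio <= 0:
        raise ValueError("slope_ratio must be positive")
    ds_a = generate_series(spec_base)
    spec_b = SeriesSpec(
        label=spec_base.label + "b", n_compounds=spec_base.n_compounds,
        slope=spec_base.slope * slope_ratio, intercept=spec_base.intercept,
        length_range=spec_base.length_range, noise_sd=spec_base.noise_sd,
        cross_correlations=spec_base.cross_correlations,
        seed=spec_base.seed + 1)
    ds_b = generate_series(spec_b)
    return Dataset(ds_a.records + ds_b.records,
                   provenance=f"two synthetic series, slope ratio {slope_ratio}")


# ---------------------------------------------------------------------------
# geometry fixture builder


def _place_dihedral(a, b, c, bond: float, angle_deg: float,
                    dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom d given a-b-c, |cd|, angle(b,c,d), dihedral."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               -np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_fragment_geometry(lengths: BondFeatureVector,
                               torsion_deg: float = 180.0,
                               ring_bond: float = 1.50) -> Molecule3D:
    """Build an idealised planar 6-ring keto-enol molecule.

    The measured fragment bonds i-v of the result equal the requested
    lengths to machine precision and the C2-C1-O-H torsion equals
    ``torsion_deg``.  The three ring atoms away from the fragment close the
    hexagon with bonds near ``ring_bond``; an error is raised when the
    requested lengths make ring closure geometrically impossible.

    Atom order: C1..C6, O_enol, O_keto, H.
    """
    iii, iv = lengths.r_CC_double, lengths.r_CC_single
    c2 = np.zeros(3)
    c1 = np.array([iii, 0.0, 0.0])
    c3 = iv * np.array([np.cos(np.radians(120)), np.sin(np.radians(120)), 0.0])
    # continue the ring with 120° interior angles from both ends
    c4 = c3 + ring_bond * np.array([np.cos(np.radians(60)),
                                    np.sin(np.radians(60)), 0.0])
    c6 = c1 + ring_bond * np.array([np.cos(np.radians(60)),
                                    np.sin(np.radians(60)), 0.0])
    gap = np.linalg.norm(c6 - c4)
    if gap > 2.0 * ring_bond or gap < 1e-6:
        raise ValueError("requested bond lengths prevent ring closure")
    mid = 0.5 * (c4 + c6)
    h = np.sqrt(ring_bond ** 2 - (gap / 2.0) ** 2)
    perp = np.cross(np.array([0.0, 0.0, 1.0]), (c6 - c4) / gap)
    c5a, c5b = mid + h * perp, mid - h * perp
    c5 = c5a if c5a[1] > c5b[1] else c5b      # keep the ring convex, interior up
    # exocyclic oxygens point away from the ring, in plane
    o_enol = c1 + lengths.r_CO * np.array([np.cos(np.radians(-60)),
                                           np.sin(np.radians(-60)), 0.0])
    u = -((c2 - c3) / np.linalg.norm(c2 - c3) + (c4 - c3) / np.linalg.norm(c4 - c3))
    o_keto = c3 + lengths.r_CO_double * u / np.linalg.norm(u)
    h_atom = _place_dihedral(c2, c1, o_enol, lengths.r_OH, 109.5, torsion_deg)
    coords = np.vstack([c1, c2, c3, c4, c5, c6, o_enol, o_keto, h_atom])
    symbols = ["C"] * 6 + ["O", "O", "H"]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
             (0, 6), (2, 7), (6, 8)]
    return Molecule3D(symbols, coords, bonds,
                      name=f"synthetic keto-enol fixture torsion={torsion_deg:g}")


def write_xyz(mol: Molecule3D, path) -> None:
    """Emit a generated fixture in XYZ format (count / name / atom lines)."""
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{mol.name}\n")
        for sym, (x, y, z) in zip(mol.symbols, mol.coords):
            fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")
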