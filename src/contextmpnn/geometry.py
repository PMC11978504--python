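"""Pure geometric kinematics: dihedrals, internal-coordinate atom placement,
idealized backbones, and the ideal sidechain geometry tables.

Sidechain atoms are placed sequentially (NeRF) from three already-placed
parents using ideal bond lengths/angles; each atom's torsion is either one of
the four chi angles (possibly with a fixed offset for branch atoms) or a
constant (planar ring continuation). CB is placed with the same virtual-CB
construction used by the featurizer, which both guarantees L-stereochemistry
and keeps the design and packing geometry mutually consistent.
"""

from __future__ import annotations

import numpy as np

# virtual CB construction coefficients
_CB_CROSS = -0.5827
_CB_B = 0.5680
_CB_C = -0.5407


def virtual_cbeta(n, ca, c):
    """Virtual CB from N, CA, C coordinates; broadcasts over leading axes."""
    n = np.asarray(n, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return _CB_CROSS * a + _CB_B * b + _CB_C * cvec + ca


def measure_dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle (radians, (-pi, pi]) of four points; broadcasts."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...k,...k->...", n1, n2)
    y = np.einsum("...k,...k->...", m1, n2)
    return np.arctan2(y, x)


def measure_angle(p0, p1, p2) -> np.ndarray:
    """Bond angle at p1 in radians."""
    v1 = np.asarray(p0, dtype=np.float64) - p1
    v2 = np.asarray(p2, dtype=np.float64) - p1
    cosang = np.einsum("...k,...k->...", v1, v2) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Place atom D from parents A, B, C with |CD| = bond_length, angle
    B-C-D = bond_angle and dihedral A-B-C-D = torsion (radians)."""
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * np.cos(bond_angle),
        bond_length * np.sin(bond_angle) * np.cos(torsion),
        -bond_length * np.sin(bond_angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# idealized backbone construction (used by the synthetic fixture generator)

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_CA_C_O = np.deg2rad(120.8)
OMEGA = np.pi  # trans peptide


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   origin: np.ndarray | None = None) -> np.ndarray:
    """Idealized backbone [L, 4, 3] (N, CA, C, O) from phi/psi arrays.

    phi[0] is unused (no preceding C); the final psi orients the terminal O.
    """
    phi = np.asarray(phi, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    L = len(phi)
    if len(psi) != L:
        raise ValueError("phi and psi must have equal length")
    coords = np.zeros((L, 4, 3))
    # seed residue in a canonical pose
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + BOND_CA_C * np.array([np.cos(np.pi - ANGLE_N_CA_C),
                                     np.sin(np.pi - ANGLE_N_CA_C), 0.0])
    coords[0, 0], coords[0, 1], coords[0, 2] = n0, ca0, c0
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n_i, ca_i, c_i
    # carbonyl O: dihedral N(i+1)-CA-C-O is ~180, i.e. psi - pi about CA-C
    for i in range(L):
        coords[i, 3] = place_atom(coords[i, 0], coords[i, 1], coords[i, 2],
                                  BOND_C_O, ANGLE_CA_C_O, psi[i] - np.pi)
    if origin is not None:
        coords = coords + np.asarray(origin, dtype=np.float64)
    return coords


# ---------------------------------------------------------------------------
# sidechain tables

# atom14 layout: 4 backbone slots then sidechain atoms in placement order
ATOM14_NAMES: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
    "UNK": ("N", "CA", "C", "O", "CB"),
}

CHI_COUNT: dict[str, int] = {
    "ALA": 0, "ARG": 4, "ASN": 2, "ASP": 2, "CYS": 1, "GLN": 3, "GLU": 3,
    "GLY": 0, "HIS": 2, "ILE": 2, "LEU": 2, "LYS": 4, "MET": 3, "PHE": 2,
    "PRO": 2, "SER": 1, "THR": 1, "TRP": 2, "TYR": 2, "VAL": 1, "UNK": 0,
}

# chi-defining atom quadruples
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# chi angles whose terminal atoms are chemically indistinguishable under a
# 180-degree flip (carboxylates and aromatic rings)
SYMMETRIC_CHI: dict[str, int] = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2}

# placement recipes: (atom, (parentA, parentB, parentC), bond, angle_deg, torsion)
# torsion is ("chi", k, offset_deg) or ("fixed", deg); parents must precede.
_R = {
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 111.5, ("chi", 1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 122.3))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, ("chi", 2, 0.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 122.6))],
    "PRO": [("CG", ("N", "CA", "CB"), 1.495, 104.5, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.507, 105.5, ("chi", 2, 0.0))],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 113.3, ("chi", 1, 0.0)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.508, 111.9, ("chi", 3, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.486, 111.7, ("chi", 4, 0.0))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.460, 112.0, ("chi", 3, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, ("chi", 4, 0.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fixed", 180.0))],
    "HIS": [("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 129.7, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, ("fixed", 180.0)),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, ("fixed", 180.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.384, 120.8, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.384, 120.8, ("fixed", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.384, 120.0, ("fixed", 0.0))],
    "TYR": [("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.387, 120.8, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.387, 120.8, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.389, 121.1, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.389, 121.1, ("fixed", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.381, 119.6, ("fixed", 0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0))],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, ("fixed", 180.0)),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, ("fixed", 0.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, ("fixed", 180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.392, 118.7, ("fixed", 180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, ("fixed", 0.0))],
    "GLY": [],
    "UNK": [],
}
SIDECHAIN_RECIPES = _R


def chi_level_of_atoms(res_name: str) -> dict[str, int]:
    """Highest chi index each atom depends on (0 for backbone and CB)."""
    levels = {name: 0 for name in ("N", "CA", "C", "O", "CB")}
    for atom, parents, _, _, tors in SIDECHAIN_RECIPES.get(res_name, []):
        if tors[0] == "chi":
            level = tors[1]
        else:
            level = 0
        level = max([level] + [levels.get(p, 0) for p in parents])
        levels[atom] = level
    return levels


def place_sidechain(res_name: str, backbone: np.ndarray,
                    chi: np.ndarray, max_chi: int | None = None) -> np.ndarray:
    """Build atom14 coordinates [14, 3] for one residue.

    ``backbone`` is [4, 3] (N, CA, C, O); ``chi`` holds up to four chi angles
    in radians. Atoms whose torsion depends on a chi index greater than
    ``max_chi`` (or than the provided chi count) are left NaN.
    """
    names = ATOM14_NAMES.get(res_name, ATOM14_NAMES["UNK"])
    coords = np.full((14, 3), np.nan)
    coords[:4] = backbone
    pos = {"N": backbone[0], "CA": backbone[1], "C": backbone[2], "O": backbone[3]}
    if len(names) > 4:  # CB via the virtual construction
        pos["CB"] = virtual_cbeta(backbone[0], backbone[1], backbone[2])
        coords[4] = pos["CB"]
    chi = np.asarray(chi, dtype=np.float64).ravel()
    n_chi = CHI_COUNT.get(res_name, 0)
    limit = n_chi if max_chi is None else min(max_chi, n_chi)
    levels = chi_level_of_atoms(res_name)
    for atom, parents, bond, angle_deg, tors in SIDECHAIN_RECIPES.get(res_name, []):
        if levels[atom] > limit:
            continue
        if tors[0] == "chi":
            k = tors[1]
            torsion = chi[k - 1] + np.deg2rad(tors[2])
        else:
            torsion = np.deg2rad(tors[1])
        a, b, c = (pos[p] for p in parents)
        xyz = place_atom(a, b, c, bond, np.deg2rad(angle_deg), torsion)
        pos[atom] = xyz
        coords[names.index(atom)] = xyz
    return coords


def measure_chis(res_name: str, atom14: np.ndarray) -> np.ndarray:
    """Measure the residue's chi angles (radians) from atom14 coordinates;
    missing atoms yield NaN."""
    names = ATOM14_NAMES.get(res_name, ATOM14_NAMES["UNK"])
    out = np.full(4, np.nan)
    for k, quad in enumerate(CHI_ATOMS.get(res_name, [])):
        try:
            pts = [atom14[names.index(nm)] for nm in quad]
        except ValueError:
            continue
        if any(not np.isfinite(p).all() for p in pts):
            continue
        out[k] = measure_dihedral(*pts)
    return out


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi)


def circular_difference(a, b) -> np.ndarray:
    """Smallest signed difference a - b on the circle."""
    return wrap_angle(np.asarray(a) - np.asarray(b))
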