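"""Idealized peptide-backbone construction.

Builds poly-peptide backbones atom by atom from ideal bond lengths,
bond angles and user-supplied (phi, psi) dihedrals using the natural
extension reference frame (NeRF) construction, and places ideal
beta-carbons at the tetrahedral position.  Used by the synthetic-data
generator to produce extended strands and helical segments with exact,
reproducible stereochemistry.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone stereochemistry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_STRAND, PSI_STRAND = -139.0, 135.0
PHI_HELIX, PSI_HELIX = -57.0, -47.0


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral beta-carbon from backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


def build_backbone(dihedrals: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone atoms (N, CA, C, O, CB) for a chain of (phi, psi) pairs.

    phi of the first residue is undefined and ignored; the carbonyl O of
    every residue is placed anti to the next amide nitrogen (equivalently
    at dihedral psi + 180 from the chain's own N, CA, C frame).
    """
    n_res = len(dihedrals)
    if n_res == 0:
        return []
    residues: list[dict[str, np.ndarray]] = []
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n, "CA": ca, "C": c})
    for k in range(1, n_res):
        phi, _ = dihedrals[k]
        _, psi_prev = dihedrals[k - 1]
        prev = residues[-1]
        n_next = place_atom(
            prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev
        )
        ca_next = place_atom(
            prev["CA"], prev["C"], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA
        )
        c_next = place_atom(
            prev["C"], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi
        )
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    for k, res in enumerate(residues):
        _, psi = dihedrals[k]
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
        res["CB"] = ideal_cbeta(res["N"], res["CA"], res["C"])
    return residues


def _rotation_to_x(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` (unit) onto +x."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    cth = float(axis @ x)
    if s < 1e-12:
        return np.eye(3) if cth > 0 else np.diag([-1.0, 1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)


def transform(
    residues: list[dict[str, np.ndarray]], rot: np.ndarray, shift: np.ndarray
) -> list[dict[str, np.ndarray]]:
    return [
        {name: rot @ pos + shift for name, pos in res.items()}
        for res in residues
    ]


def canonical_strand(length: int) -> list[dict[str, np.ndarray]]:
    """Extended strand in canonical placement.

    Runs N-to-C along +x with its CA centroid at the origin, and the
    first interior carbonyl oriented toward +y (so strand pairing
    partners sit along the y axis and the side-chain pleat alternates
    along z).
    """
    res = build_backbone([(PHI_STRAND, PSI_STRAND)] * length)
    cas = np.array([r["CA"] for r in res])
    axis = cas[-1] - cas[0]
    if length == 1:
        axis = res[0]["C"] - res[0]["N"]
    axis = axis / np.linalg.norm(axis)
    rot1 = _rotation_to_x(axis)
    res = transform(res, rot1, np.zeros(3))
    # spin about x to put the first carbonyl in the +y half of the yz plane
    ref = res[min(1, length - 1)]
    co = ref["O"] - ref["C"]
    ang = np.arctan2(co[2], co[1])
    ca, sa = np.cos(-ang), np.sin(-ang)
    rot2 = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    res = transform(res, rot2, np.zeros(3))
    centroid = np.array([r["CA"] for r in res]).mean(axis=0)
    return transform(res, np.eye(3), -centroid)


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc
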