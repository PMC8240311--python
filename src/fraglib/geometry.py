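"""Backbone geometry: torsions, pseudo-angles, superposition and reconstruction.

All angles are in degrees on the branch (-180, 180]; an undefined angle is
represented by ``numpy.nan``.  The module provides the geometric primitives the
rest of the package is built on:

* signed dihedral angles (IUPAC convention: cis = 0, sign by the right-hand
  rule about the central bond) and planar angles,
* per-residue backbone angle sets -- the torsions phi/psi/omega plus the
  CA-trace pseudo-angles theta (planar angle of three consecutive CA atoms)
  and tau (dihedral of four consecutive CA atoms),
* virtual C-beta placement from N/CA/C at ideal tetrahedral geometry,
* Kabsch superposition RMSD (proper rotations only),
* NeRF (natural extension reference frame) reconstruction of a full backbone
  from torsions with ideal bond lengths and angles,
* a simple torsion-region three-state secondary-structure assigner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IdealGeometry",
    "AngleSet",
    "normalize_angle",
    "dihedral",
    "planar_angle",
    "virtual_cbeta",
    "kabsch_rmsd",
    "kabsch_superpose",
    "pairwise_distances",
    "reconstruct_backbone_coords",
    "backbone_angles_from_coords",
    "ca_trace_angles",
    "assign_ss3",
]

#: Sentinel used by text formats that cannot express a missing angle.
MISSING_ANGLE_SENTINEL = 9999.0


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal backbone covalent geometry used for NeRF reconstruction.

    Defaults are standard Engh--Huber-like values.  The C-beta placement
    parameters put CB at tetrahedral geometry off the N-CA-C frame with the
    L-amino-acid improper dihedral.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_ca_cb: float = 1.521
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8
    angle_n_ca_cb: float = 110.4
    #: improper dihedral C-N-CA-CB fixing CB chirality (L-residues)
    improper_c_n_ca_cb: float = 122.6

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o", "bond_ca_cb"):
            v = getattr(self, name)
            if not 1.2 <= v <= 1.6:
                raise ValueError(f"{name}={v} outside sane bond-length band 1.2-1.6 A")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca", "angle_ca_c_o",
                     "angle_n_ca_cb"):
            v = getattr(self, name)
            if not 100.0 <= v <= 125.0:
                raise ValueError(f"{name}={v} outside sane bond-angle band 100-125 deg")


DEFAULT_GEOMETRY = IdealGeometry()


@dataclass
class AngleSet:
    """Per-residue backbone angles (degrees, NaN where undefined).

    phi is undefined at the first residue, psi and omega at the last; theta
    needs CA(i-1..i+1) so it is missing at both termini; tau needs
    CA(i-1..i+2) so it is missing at the first residue and the last two.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    theta: np.ndarray
    tau: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"phi": self.phi, "psi": self.psi, "omega": self.omega,
                "theta": self.theta, "tau": self.tau}


def normalize_angle(angle):
    """Map angle(s) in degrees onto the branch (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    out = np.where(out == -180.0, 180.0, out)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees on (-180, 180].

    Returns NaN when the angle is undefined (three consecutive points
    collinear).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return float("nan")
    m = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def planar_angle(p1, p2, p3) -> float:
    """Interior angle at p2 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = p1 - p2
    b = p3 - p2
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("planar_angle: zero-length arm")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom with given internal coordinates relative to a-b-c.

    The new atom D satisfies |CD| = bond, angle(B,C,D) = angle_deg and
    dihedral(A,B,C,D) = torsion_deg.
    """
    theta = np.radians(angle_deg)
    chi = -np.radians(torsion_deg)
    d2 = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("NeRF placement undefined: reference atoms collinear")
    n = n / nn
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d2


def virtual_cbeta(n, ca, c, params: IdealGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Ideal C-beta position constructed from backbone N, CA, C.

    Used for glycine (no real CB) and whenever a format carries backbone atoms
    only.  Deterministic and equivariant under rigid transforms.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    return _nerf_place(c, n, ca, params.bond_ca_cb, params.angle_n_ca_cb,
                       params.improper_c_n_ca_cb)


def kabsch_superpose(A, B):
    """Optimal proper rotation/translation of B onto A.

    Returns ``(rmsd, R, t)`` such that ``B @ R.T + t`` best fits A in the
    least-squares sense with a proper rotation (no reflection).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {A.shape} and {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    Brot = B0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((A0 - Brot) ** 2, axis=1))))
    t = ca - cb @ R.T
    return rmsd, R, t


def kabsch_rmsd(A, B) -> float:
    """Minimal RMSD between matched point sets over rigid superposition."""
    return kabsch_superpose(A, B)[0]


def pairwise_distances(coords, pairs) -> np.ndarray:
    """Euclidean distances for the requested index pairs of ``coords`` (n, 3)."""
    coords = np.asarray(coords, float)
    pairs = np.asarray(pairs, int)
    if pairs.size == 0:
        return np.zeros(0)
    if np.isnan(coords[pairs.ravel()]).any():
        raise ValueError("pairwise_distances: requested atom is missing (NaN)")
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def all_pairs(n: int) -> np.ndarray:
    """All index pairs (i, j) with i < j < n in lexicographic order."""
    idx = np.triu_indices(n, k=1)
    return np.column_stack(idx)


def reconstruct_backbone_coords(phi, psi, omega=None,
                                geometry: IdealGeometry = DEFAULT_GEOMETRY):
    """NeRF sequential backbone construction from torsions.

    Parameters
    ----------
    phi, psi : array-like, length L
        Backbone torsions in degrees.  ``phi[0]`` and ``psi[-1]`` are not used
        by the construction and may be NaN; every interior torsion must be
        finite.
    omega : array-like, optional
        Peptide-bond torsion preceding each residue's CA placement;
        ``omega[i]`` is the C(i-1)-N(i) bond torsion.  Defaults to 180
        (trans) everywhere.

    Returns
    -------
    dict with arrays ``N``, ``CA``, ``C``, ``O``, ``CB`` of shape (L, 3).
    The first residue is placed in a canonical frame, so re-measuring the
    torsions of the built chain returns the inputs.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    L = len(phi)
    if len(psi) != L:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(L, 180.0)
    else:
        omega = np.asarray(omega, float)
        omega = np.where(np.isnan(omega), 180.0, omega)
    if L >= 2:
        if np.isnan(phi[1:]).any():
            raise ValueError("interior phi contains NaN; cannot reconstruct")
        if np.isnan(psi[:-1]).any():
            raise ValueError("interior psi contains NaN; cannot reconstruct")

    g = geometry
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # canonical frame for residue 0
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [g.bond_n_ca, 0.0, 0.0]
    ang = np.radians(180.0 - g.angle_n_ca_c)
    C[0] = CA[0] + g.bond_ca_c * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        N[i] = _nerf_place(N[i - 1], CA[i - 1], C[i - 1], g.bond_c_n,
                           g.angle_ca_c_n, psi[i - 1])
        CA[i] = _nerf_place(CA[i - 1], C[i - 1], N[i], g.bond_n_ca,
                            g.angle_c_n_ca, omega[i])
        C[i] = _nerf_place(C[i - 1], N[i], CA[i], g.bond_ca_c,
                           g.angle_n_ca_c, phi[i])
    O = np.zeros((L, 3))
    for i in range(L):
        # carbonyl O sits opposite the next amide N; trans for the C-terminus
        psi_i = psi[i] if i < L - 1 and np.isfinite(psi[i]) else 0.0
        O[i] = _nerf_place(N[i], CA[i], C[i], g.bond_c_o, g.angle_ca_c_o,
                           normalize_angle(psi_i + 180.0))
    CB = np.array([virtual_cbeta(N[i], CA[i], C[i], g) for i in range(L)])
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def ca_trace_angles(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """theta/tau pseudo-angles of a CA trace.

    theta_i is the planar angle CA(i-1)-CA(i)-CA(i+1); tau_i the dihedral
    CA(i-1)-CA(i)-CA(i+1)-CA(i+2).  Undefined entries are NaN.
    """
    ca = np.asarray(ca, float)
    L = len(ca)
    theta = np.full(L, np.nan)
    tau = np.full(L, np.nan)
    for i in range(1, L - 1):
        if np.isnan(ca[i - 1:i + 2]).any():
            continue
        theta[i] = planar_angle(ca[i - 1], ca[i], ca[i + 1])
    for i in range(1, L - 2):
        if np.isnan(ca[i - 1:i + 3]).any():
            continue
        tau[i] = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
    return theta, tau


def backbone_angles_from_coords(N, CA, C) -> AngleSet:
    """Full AngleSet (phi, psi, omega, theta, tau) from backbone coordinates.

    Angles whose defining atoms fall outside the chain (or are NaN) are NaN.
    """
    N = np.asarray(N, float)
    CA = np.asarray(CA, float)
    C = np.asarray(C, float)
    L = len(CA)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    omega = np.full(L, np.nan)

    def ok(*pts):
        return not any(np.isnan(p).any() for p in pts)

    for i in range(L):
        if i > 0 and ok(C[i - 1], N[i], CA[i], C[i]):
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < L - 1 and ok(N[i], CA[i], C[i], N[i + 1]):
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
        if i > 0 and ok(CA[i - 1], C[i - 1], N[i], CA[i]):
            omega[i] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
    theta, tau = ca_trace_angles(CA)
    return AngleSet(phi=phi, psi=psi, omega=omega, theta=theta, tau=tau)


# Torsion-region three-state assignment.  Region constants are deliberately
# broad; they exist to label synthetic natives and torsion-only fragments, not
# to reproduce DSSP.
SS3_HELIX_PHI = (-100.0, -30.0)
SS3_HELIX_PSI = (-80.0, -5.0)
SS3_STRAND_PHI = (-180.0, -90.0)
SS3_STRAND_PSI_HI = (90.0, 180.0)
SS3_STRAND_PSI_LO = (-180.0, -170.0)


def assign_ss3(phi: float, psi: float) -> str:
    """Three-state secondary structure (H/E/C) from a residue's phi/psi."""
    if phi is None or psi is None or not (np.isfinite(phi) and np.isfinite(psi)):
        return "C"
    if SS3_HELIX_PHI[0] <= phi <= SS3_HELIX_PHI[1] and \
            SS3_HELIX_PSI[0] <= psi <= SS3_HELIX_PSI[1]:
        return "H"
    if SS3_STRAND_PHI[0] <= phi <= SS3_STRAND_PHI[1] and (
            SS3_STRAND_PSI_HI[0] <= psi <= SS3_STRAND_PSI_HI[1]
            or SS3_STRAND_PSI_LO[0] <= psi <= SS3_STRAND_PSI_LO[1]):
        return "E"
    return "C"
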