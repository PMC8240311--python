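"""Toy gradient-descent folding driven by fragment-derived potentials.

This module minimizes the combined fragment potential (plus a soft-sphere
clash term) over a torsion-parameterized backbone: the optimization variables
are the phi/psi angles of every residue (omega fixed trans), the structure is
rebuilt from them with NeRF on ideal geometry at every evaluation, and the
gradient is taken by central finite differences.  It is a deliberately small
stand-in for a production gradient-descent folding engine: correctness and
determinism over speed, at toy chain lengths.

Protocol helpers generate a pool of decoys from different random torsion
initializations (50 by default) and rank them by energy; the lowest-energy
decoy is "top1".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import cos, log, radians, sin, sqrt

import numpy as np

from .core import TargetStructure
from .geometry import DEFAULT_GEOMETRY, normalize_angle
from .potentials import PDF_FLOOR, PROPERTIES_1D, PositionPotentialSet
from .synthetic import CANONICAL_TORSIONS, COIL_BASINS

logger = logging.getLogger(__name__)

__all__ = [
    "Decoy",
    "PackedPotential",
    "random_torsion_init",
    "fold",
    "generate_decoys",
    "rank_decoys",
]

CLASH_DISTANCE = 3.4  # A; soft-sphere radius for CA pairs
CLASH_WEIGHT = 1.0
FD_STEP = 0.1  # degrees; central-difference step
_LOG_FLOOR = log(PDF_FLOOR)

#: sampling mixture for torsion initialization: (ss-type fraction)
INIT_BASIN_PROBS = {"H": 0.35, "E": 0.30, "C": 0.35}
INIT_JITTER_SD = 15.0


# ---------------------------------------------------------------------------
# Fast scalar NeRF (CA/CB only) -- hot path of the finite-difference gradient
# ---------------------------------------------------------------------------

def _build_ca_cb(phi: np.ndarray, psi: np.ndarray):
    """CA and CB coordinates from torsions; matches geometry.reconstruct_backbone_coords.

    Scalar-math NeRF specialised for the folding loop (numpy 3-vectors are an
    order of magnitude slower at this size).
    """
    g = DEFAULT_GEOMETRY
    L = len(phi)

    def place(a, b, c, bond, ang_deg, tor_deg):
        th = radians(ang_deg)
        chi = -radians(tor_deg)
        d0 = -bond * cos(th)
        d1 = bond * sin(th) * cos(chi)
        d2 = bond * sin(th) * sin(chi)
        bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
        nb = sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
        abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        return (
            c[0] + bcx * d0 + mx * d1 + nx * d2,
            c[1] + bcy * d0 + my * d1 + ny * d2,
            c[2] + bcz * d0 + mz * d1 + nz * d2,
        )

    N = [(0.0, 0.0, 0.0)]
    CA = [(g.bond_n_ca, 0.0, 0.0)]
    ang = radians(180.0 - g.angle_n_ca_c)
    C = [(CA[0][0] + g.bond_ca_c * cos(ang), g.bond_ca_c * sin(ang), 0.0)]
    for i in range(1, L):
        n_i = place(N[i - 1], CA[i - 1], C[i - 1], g.bond_c_n, g.angle_ca_c_n, psi[i - 1])
        ca_i = place(CA[i - 1], C[i - 1], n_i, g.bond_n_ca, g.angle_c_n_ca, 180.0)
        c_i = place(C[i - 1], n_i, ca_i, g.bond_ca_c, g.angle_n_ca_c, phi[i])
        N.append(n_i)
        CA.append(ca_i)
        C.append(c_i)
    CB = [place(C[i], N[i], CA[i], g.bond_ca_cb, g.angle_n_ca_cb,
                g.improper_c_n_ca_cb) for i in range(L)]
    return np.asarray(CA), np.asarray(CB)


def _ca_theta_tau(ca: np.ndarray):
    """Vectorized theta/tau of a CA trace (NaN at undefined termini)."""
    L = len(ca)
    theta = np.full(L, np.nan)
    tau = np.full(L, np.nan)
    if L >= 3:
        v1 = ca[:-2] - ca[1:-1]
        v2 = ca[2:] - ca[1:-1]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        theta[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if L >= 4:
        b1 = ca[1:-2] - ca[:-3]
        b2 = ca[2:-1] - ca[1:-2]
        b3 = ca[3:] - ca[2:-1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
        m = np.cross(n1, b2n)
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(m * n2, axis=1)
        tau[1:-2] = np.degrees(np.arctan2(y, x))
    return theta, tau


# ---------------------------------------------------------------------------
# Packed potential evaluation
# ---------------------------------------------------------------------------

class PackedPotential:
    """All wGMM models of a target flattened into arrays for fast evaluation."""

    _PROP_ID = {p: i for i, p in enumerate(PROPERTIES_1D)}

    def __init__(self, potential_sets: dict[int, PositionPotentialSet],
                 combine_weights: dict | None = None):
        if not potential_sets:
            raise ValueError("need at least one position potential set")
        self.potential_sets = potential_sets
        any_set = next(iter(potential_sets.values()))
        self.combine_weights = dict(combine_weights or any_set.combine_weights)

        t1 = {"pos": [], "prop": [], "idx": [], "params": []}
        t2 = {"pos": [], "prop": [], "atom": [], "i1": [], "i2": [], "params": []}
        for pos, pset in potential_sets.items():
            base = pos - 1
            for (prop, slot), model in pset.models.items():
                w, mu, var = model._params()
                if prop in self._PROP_ID:
                    t1["pos"].append(pos)
                    t1["prop"].append(self._PROP_ID[prop])
                    t1["idx"].append(base + slot)
                    t1["params"].append((w, mu, var))
                else:
                    j1, j2 = slot
                    t2["pos"].append(pos)
                    t2["prop"].append(prop)
                    t2["atom"].append(0 if prop == "dCA" else 1)
                    t2["i1"].append(base + j1)
                    t2["i2"].append(base + j2)
                    t2["params"].append((w, mu, var))

        def pack(params, weights_per_term):
            kmax = max(len(p[0]) for p in params)
            M = len(params)
            const = np.full((M, kmax), -np.inf)
            mu = np.zeros((M, kmax))
            inv2v = np.ones((M, kmax))
            for m, (w, mm, vv) in enumerate(params):
                k = len(w)
                const[m, :k] = np.log(w) - 0.5 * np.log(2 * np.pi * vv)
                mu[m, :k] = mm
                inv2v[m, :k] = 1.0 / (2.0 * vv)
            return const, mu, inv2v, np.asarray(weights_per_term)

        self._has_1d = bool(t1["params"])
        if self._has_1d:
            w_terms = [self.combine_weights.get(PROPERTIES_1D[p], 1.0) for p in t1["prop"]]
            self.c1, self.mu1, self.iv1, self.w1 = pack(t1["params"], w_terms)
            self.pos1 = np.asarray(t1["pos"])
            self.prop1 = np.asarray(t1["prop"])
            self.idx1 = np.asarray(t1["idx"])
        self._has_2d = bool(t2["params"])
        if self._has_2d:
            w_terms = [self.combine_weights.get(p, 1.0) for p in t2["prop"]]
            self.c2, self.mu2, self.iv2, self.w2 = pack(t2["params"], w_terms)
            self.pos2 = np.asarray(t2["pos"])
            self.prop2 = t2["prop"]
            self.atom2 = np.asarray(t2["atom"])
            self.i21 = np.asarray(t2["i1"])
            self.i22 = np.asarray(t2["i2"])

    @staticmethod
    def _term_nll(y, const, mu, inv2v):
        # exact log-domain mixture evaluation: no underflow, so no floor is
        # needed and the quadratic tails keep their gradient far from the modes
        comp = const - (y[:, None] - mu) ** 2 * inv2v
        m = comp.max(axis=1)
        lp = m + np.log(np.exp(comp - m[:, None]).sum(axis=1))
        return -lp

    def term_energies(self, props: dict):
        """Per-term weighted energies and positions for the given properties."""
        energies = []
        positions = []
        if self._has_1d:
            L = len(props["phi"])
            ang = np.stack([np.asarray(props[p], float) for p in PROPERTIES_1D])
            inb = (self.idx1 >= 0) & (self.idx1 < L)
            y = np.where(inb, ang[self.prop1, np.clip(self.idx1, 0, L - 1)], np.nan)
            ok = np.isfinite(y)
            e = np.zeros(len(y))
            if ok.any():
                e[ok] = self._term_nll(y[ok], self.c1[ok], self.mu1[ok], self.iv1[ok])
            energies.append(e * self.w1 * ok)
            positions.append(self.pos1)
        if self._has_2d and props.get("ca") is not None:
            coords = np.stack([np.asarray(props["ca"], float),
                               np.asarray(props["cb"], float)])
            Lc = coords.shape[1]
            inb = (self.i21 < Lc) & (self.i22 < Lc)
            d = np.full(len(self.i21), np.nan)
            a = coords[self.atom2[inb], self.i21[inb]]
            b = coords[self.atom2[inb], self.i22[inb]]
            d[inb] = np.linalg.norm(a - b, axis=1)
            ok = np.isfinite(d)
            e = np.zeros(len(d))
            if ok.any():
                e[ok] = self._term_nll(d[ok], self.c2[ok], self.mu2[ok], self.iv2[ok])
            energies.append(e * self.w2 * ok)
            positions.append(self.pos2)
        if not energies:
            return np.zeros(0), np.zeros(0, dtype=int)
        return np.concatenate(energies), np.concatenate(positions)

    def energy(self, props: dict) -> float:
        e, _ = self.term_energies(props)
        return float(e.sum())

    def position_energies(self, props: dict) -> dict[int, float]:
        """Combined energy aggregated per position."""
        e, pos = self.term_energies(props)
        out: dict[int, float] = {}
        for p in np.unique(pos):
            out[int(p)] = float(e[pos == p].sum())
        return out


def structure_properties(phi, psi, ca, cb) -> dict:
    theta, tau = _ca_theta_tau(np.asarray(ca))
    return {"phi": np.asarray(phi, float), "psi": np.asarray(psi, float),
            "theta": theta, "tau": tau, "ca": np.asarray(ca), "cb": np.asarray(cb)}


def clash_energy(ca: np.ndarray, min_dist: float = CLASH_DISTANCE) -> float:
    """Soft-sphere CA-CA penalty: sum of max(0, min_dist - d)^2 over i < j - 1."""
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    iu = np.triu_indices(len(ca), k=2)
    viol = np.maximum(0.0, min_dist - d[iu])
    return float(np.sum(viol ** 2))


# ---------------------------------------------------------------------------
# Decoy generation
# ---------------------------------------------------------------------------

@dataclass
class Decoy:
    phi: np.ndarray
    psi: np.ndarray
    energy: float
    seed: int
    initial_energy: float

    def structure(self, sequence: str | None = None) -> TargetStructure:
        L = len(self.phi)
        seq = sequence or "A" * L
        phi = self.phi.copy()
        psi = self.psi.copy()
        phi[0] = np.nan
        psi[-1] = np.nan
        return TargetStructure.from_torsions(seq, phi, psi)

    def ca_coords(self) -> np.ndarray:
        return _build_ca_cb(self.phi, self.psi)[0]


def random_torsion_init(length: int, seed: int):
    """Seeded torsions drawn from a helix/strand/coil basin mixture."""
    if length < 3:
        raise ValueError("length must be >= 3")
    rng = np.random.default_rng(seed)
    kinds = list(INIT_BASIN_PROBS)
    probs = np.array([INIT_BASIN_PROBS[k] for k in kinds])
    phi = np.empty(length)
    psi = np.empty(length)
    for i in range(length):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        if kind in CANONICAL_TORSIONS:
            p0, s0 = CANONICAL_TORSIONS[kind]
        else:
            b = COIL_BASINS[rng.choice(len(COIL_BASINS),
                                       p=np.array([x[2] for x in COIL_BASINS]) /
                                       sum(x[2] for x in COIL_BASINS))]
            p0, s0 = b[0], b[1]
        phi[i] = normalize_angle(p0 + rng.normal(0.0, INIT_JITTER_SD))
        psi[i] = normalize_angle(s0 + rng.normal(0.0, INIT_JITTER_SD))
    return phi, psi


def _decoy_energy(packed: PackedPotential, phi, psi, clash_weight: float) -> float:
    ca, cb = _build_ca_cb(phi, psi)
    props = structure_properties(phi, psi, ca, cb)
    # the chain's own first phi / last psi are undefined observables
    props["phi"] = props["phi"].copy()
    props["psi"] = props["psi"].copy()
    props["phi"][0] = np.nan
    props["psi"][-1] = np.nan
    e = packed.energy(props)
    if clash_weight:
        e += clash_weight * clash_energy(ca)
    return e


def _descend(f, x, steps: int, step_size: float, fd_step: float):
    """Finite-difference gradient descent with a backtracking line search.

    Direction is the negative gradient scaled to unit infinity-norm, so the
    largest torsion move per accepted step equals the current step size (in
    degrees).  Energy is non-increasing over accepted steps by construction.
    """
    e = f(x)
    if not np.isfinite(e):
        raise RuntimeError("non-finite energy at initialization")
    s = step_size
    for _ in range(steps):
        g = np.empty_like(x)
        for i in range(len(x)):
            xi = x[i]
            x[i] = xi + fd_step
            ep = f(x)
            x[i] = xi - fd_step
            em = f(x)
            x[i] = xi
            g[i] = (ep - em) / (2 * fd_step)
        gmax = np.max(np.abs(g))
        if gmax < 1e-12:
            break
        direction = -g / gmax
        accepted = False
        st = s
        for _ in range(10):
            xn = x + st * direction
            en = f(xn)
            if not np.isfinite(en):
                raise RuntimeError("energy diverged to non-finite value")
            if en < e:
                x, e = xn, en
                accepted = True
                break
            st *= 0.5
        if not accepted:
            break
        s = min(st * 1.5, step_size)
    return x, e


def fold(length: int, potential_sets: dict[int, PositionPotentialSet],
         combine_weights: dict | None = None, steps: int = 50,
         step_size: float = 4.0, seed: int = 0,
         clash_weight: float = CLASH_WEIGHT, fd_step: float = FD_STEP,
         init: tuple | None = None, torsion_steps: int = 60) -> Decoy:
    """Minimize the combined fragment potential over phi/psi by descent.

    Two-stage schedule: the torsion (phi/psi) potentials alone are minimized
    first -- they are cheap (no reconstruction needed) and nearly separable
    per residue, so they funnel the chain into the library's torsion basins
    -- and the full six-property potential plus the clash term polishes from
    there.  Each stage uses central finite differences (``fd_step`` degrees)
    with a backtracking line search, so accepted steps never increase that
    stage's energy.  Deterministic for a given seed.
    """
    packed = (potential_sets if isinstance(potential_sets, PackedPotential)
              else PackedPotential(potential_sets, combine_weights))
    if init is None:
        phi, psi = random_torsion_init(length, seed)
    else:
        phi, psi = (np.array(init[0], float), np.array(init[1], float))
        phi = np.where(np.isnan(phi), -60.0, phi)
        psi = np.where(np.isnan(psi), -40.0, psi)

    L = length

    def unpack_x(x):
        ph = np.empty(L)
        ps = np.empty(L)
        ph[0] = phi[0]
        ph[1:] = x[:L - 1]
        ps[-1] = psi[-1]
        ps[:-1] = x[L - 1:]
        return ph, ps

    def f_full(x):
        ph, ps = unpack_x(x)
        return _decoy_energy(packed, ph, ps, clash_weight)

    # stage-1 objective: phi/psi 1D terms only, evaluated directly on the
    # torsion variables (no NeRF)
    if packed._has_1d:
        tors = packed.prop1 <= 1  # phi=0, psi=1
        c1, mu1, iv1 = packed.c1[tors], packed.mu1[tors], packed.iv1[tors]
        w1 = packed.w1[tors]
        prop_t = packed.prop1[tors]
        idx_t = packed.idx1[tors]

        def f_torsion(x):
            ph, ps = unpack_x(x)
            ph = ph.copy()
            ps = ps.copy()
            ph[0] = np.nan
            ps[-1] = np.nan
            ang = np.stack([ph, ps])
            y = ang[prop_t, idx_t]
            ok = np.isfinite(y)
            if not ok.any():
                return 0.0
            e = PackedPotential._term_nll(y[ok], c1[ok], mu1[ok], iv1[ok])
            return float((e * w1[ok]).sum())
    else:
        f_torsion = None

    x = np.concatenate([phi[1:], psi[:-1]])
    e0 = f_full(x)
    if f_torsion is not None and torsion_steps > 0:
        x, _ = _descend(f_torsion, x, torsion_steps, step_size, fd_step)
    x, e = _descend(f_full, x, steps, step_size, fd_step)
    if e > e0:  # pathological stage-1 excursion: fall back to pure full descent
        x0 = np.concatenate([phi[1:], psi[:-1]])
        x, e = _descend(f_full, x0, steps, step_size, fd_step)

    phi_f, psi_f = unpack_x(x)
    phi_f = normalize_angle(phi_f)
    psi_f = normalize_angle(psi_f)
    return Decoy(phi=phi_f, psi=psi_f, energy=float(e), seed=seed,
                 initial_energy=float(e0))


def generate_decoys(length: int, potential_sets, n: int = 50, seed: int = 0,
                    **fold_kwargs) -> list[Decoy]:
    """Run ``n`` independent folds with seeds seed, seed+1, ..., seed+n-1."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    packed = (potential_sets if isinstance(potential_sets, PackedPotential)
              else PackedPotential(potential_sets,
                                   fold_kwargs.pop("combine_weights", None)))
    return [fold(length, packed, seed=seed + i, **fold_kwargs) for i in range(n)]


def rank_decoys(decoys: list[Decoy]):
    """Decoys sorted by ascending energy (ties broken by seed); returns (ordered, top1)."""
    if not decoys:
        raise ValueError("no decoys to rank")
    if any(not np.isfinite(d.energy) for d in decoys):
        raise ValueError("cannot rank decoys with non-finite energy")
    ordered = sorted(decoys, key=lambda d: (d.energy, d.seed))
    return ordered, ordered[0]
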