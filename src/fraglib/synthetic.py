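"""Synthetic natives and fragment libraries with known ground truth.

The generator emulates the output of a modern fragment-library construction
pipeline at toy scale: a native backbone is built from canonical
secondary-structure torsions (NeRF on ideal geometry), and each position of
the target receives fragments whose torsions are the native window's plus
seeded Gaussian noise, rebuilt into coordinates.  Every fragment's true CA
RMSD to its native window is recorded, and its *predicted* RMSD is the true
RMSD plus seeded noise (floored at zero) -- the simplest confidence model
that preserves the property real predictors are valued for: low predicted
RMSD implies a truly better fragment.

Fragments are sampled with two residues of native context on each side, so
window-boundary torsions and CA pseudo-angles are defined from the source
context exactly as they would be for fragments cut from real proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .core import Fragment, FragmentLibrary, FragmentResidue, TargetStructure
from .geometry import kabsch_rmsd, normalize_angle, reconstruct_backbone_coords

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "CANONICAL_TORSIONS",
    "make_toy_native",
    "sample_fragment_library",
    "make_worked_example",
]

#: canonical (phi, psi) per secondary-structure type
CANONICAL_TORSIONS = {"H": (-57.0, -47.0), "E": (-120.0, 130.0)}

#: coil torsion basins (phi, psi, probability): PPII-like, bridge-like and
#: left-handed; constants are the generator's own convention.
COIL_BASINS = ((-75.0, 145.0, 0.4), (-90.0, 0.0, 0.3), (60.0, 45.0, 0.3))

#: amino-acid alphabet used for synthetic sequences (no G/P: keeps the toy
#: chains free of the special-case residues)
SYNTH_AA = "ADEFIKLMNQRSTVWY"


@dataclass
class LibrarySpec:
    """Parameters of one synthetic library draw."""

    n_frags_per_pos: int = 10
    length_range: tuple[int, int] = (7, 10)
    angle_noise_sd: float = 5.0
    pred_rmsd_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frags_per_pos < 1:
            raise ValueError("need at least one fragment per position")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.angle_noise_sd < 0 or self.pred_rmsd_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _segment_torsions(segments, rng, jitter_sd: float):
    phi, psi, ss = [], [], []
    for kind, length in segments:
        for _ in range(length):
            if kind in CANONICAL_TORSIONS:
                p0, s0 = CANONICAL_TORSIONS[kind]
            elif kind == "C":
                probs = np.array([b[2] for b in COIL_BASINS])
                b = COIL_BASINS[rng.choice(len(COIL_BASINS), p=probs / probs.sum())]
                p0, s0 = b[0], b[1]
            else:
                raise ValueError(f"unknown segment type {kind!r}")
            phi.append(normalize_angle(p0 + rng.normal(0.0, jitter_sd)))
            psi.append(normalize_angle(s0 + rng.normal(0.0, jitter_sd)))
            ss.append(kind)
    return np.array(phi), np.array(psi), ss


def make_toy_native(segments, seed: int = 0, jitter_sd: float = 2.0) -> TargetStructure:
    """NeRF-built native from canonical torsions per segment, with small jitter.

    ``segments`` is a list of (ss_type, length) with ss_type in H/E/C.
    Secondary structure is assigned by construction.  Deterministic per seed.
    """
    total = sum(n for _, n in segments)
    if total < 3:
        raise ValueError("native must have at least 3 residues")
    rng = np.random.default_rng(seed)
    phi, psi, ss = _segment_torsions(segments, rng, jitter_sd)
    phi[0] = np.nan
    psi[-1] = np.nan
    seq = "".join(SYNTH_AA[i % len(SYNTH_AA)] for i in range(total))
    return TargetStructure.from_torsions(seq, phi, psi, ss=ss)


def _native_torsion_table(native: TargetStructure):
    a = native.angles
    return np.array(a.phi), np.array(a.psi), np.array(a.omega)


def sample_fragment_library(native: TargetStructure, spec: LibrarySpec):
    """Draw a noisy fragment library around a native structure.

    Returns ``(library, truth)`` where truth is a DataFrame with one row per
    emitted fragment: position, index within position, length, true CA RMSD
    to the native window and the noisy pred_rmsd derived from it.

    For each fragment the native window's torsions -- extended by two residues
    of context on each side where the chain allows -- receive i.i.d. Gaussian
    noise (sd ``angle_noise_sd``); the chain is rebuilt with NeRF and trimmed
    back to the window, so boundary angles and theta/tau keep source context.
    Fragments whose drawn length would overrun the chain are shortened to the
    longest feasible length, or skipped (logged) if even the minimum does not
    fit.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(native)
    phi_n, psi_n, _ = _native_torsion_table(native)
    positions: dict[int, list[Fragment]] = {}
    rows = []
    n_skipped = 0
    lo, hi = spec.length_range

    for pos in range(1, L + 1):
        for k in range(spec.n_frags_per_pos):
            length = int(rng.integers(lo, hi + 1))
            if pos + length - 1 > L:
                length = L - pos + 1
                if length < min(lo, 3):
                    n_skipped += 1
                    continue
            # context window [c0, c1) in 0-based residue indices; two flanking
            # residues so boundary theta/tau stay defined (tau needs CA two
            # residues past the window end)
            c0 = max(pos - 3, 0)
            c1 = min(pos - 1 + length + 2, L)
            off = pos - 1 - c0  # index of the fragment's first residue in context
            phi_c = phi_n[c0:c1].copy()
            psi_c = psi_n[c0:c1].copy()
            nres = c1 - c0
            noise_phi = rng.normal(0.0, spec.angle_noise_sd, nres)
            noise_psi = rng.normal(0.0, spec.angle_noise_sd, nres)
            phi_c = normalize_angle(np.where(np.isnan(phi_c), np.nan, phi_c + noise_phi))
            psi_c = normalize_angle(np.where(np.isnan(psi_c), np.nan, psi_c + noise_psi))
            # NeRF needs finite interior torsions; context termini may be NaN
            phi_b = phi_c.copy()
            psi_b = psi_c.copy()
            if np.isnan(phi_b[0]):
                phi_b[0] = 0.0
            if np.isnan(psi_b[-1]):
                psi_b[-1] = 0.0
            bb = reconstruct_backbone_coords(phi_b, psi_b)
            aset = geometry.backbone_angles_from_coords(bb["N"], bb["CA"], bb["C"])

            residues = []
            for j in range(length):
                cj = off + j
                gi = pos - 1 + j
                coords = {a: bb[a][cj] for a in ("N", "CA", "C", "O", "CB")}
                phi_j = phi_c[cj] if cj > 0 else np.nan
                psi_j = psi_c[cj] if cj < nres - 1 else np.nan
                residues.append(FragmentResidue(
                    aa=native.sequence[gi],
                    ss=geometry.assign_ss3(phi_j, psi_j),
                    phi=phi_j, psi=psi_j,
                    omega=aset.omega[cj] if cj > 0 else np.nan,
                    theta=aset.theta[cj], tau=aset.tau[cj],
                    coords=coords))
            frag = Fragment(start_pos=pos, residues=residues,
                            source_id=f"synth_{pos:03d}_{k:03d}")
            true_rmsd = kabsch_rmsd(native.window_atoms(pos, length, "CA"),
                                    frag.atom_array("CA"))
            pred = max(0.0, true_rmsd + rng.normal(0.0, spec.pred_rmsd_noise_sd))
            frag.pred_rmsd = pred
            positions.setdefault(pos, []).append(frag)
            rows.append({"position": pos, "index": k, "length": length,
                         "true_rmsd": true_rmsd, "pred_rmsd": pred})

    if n_skipped:
        logger.info("skipped %d fragments that could not fit the chain end", n_skipped)
    lib = FragmentLibrary(target_length=L, positions=positions)
    truth = pd.DataFrame(rows)
    return lib, truth


WORKED_EXAMPLE_SEED = 42
WORKED_EXAMPLE_SPEC = LibrarySpec(n_frags_per_pos=10, length_range=(7, 10),
                                  angle_noise_sd=5.0, pred_rmsd_noise_sd=0.2,
                                  seed=WORKED_EXAMPLE_SEED)


def make_worked_example():
    """The package's deterministic worked example: a 20-residue helix target
    with 10 fragments per position (seed 42).

    Returns ``(native, library, truth)``; regenerating is bit-stable, so the
    example serves docs, tests and the acceptance script without shipping a
    large data file.
    """
    native = make_toy_native([("H", 20)], seed=WORKED_EXAMPLE_SEED)
    lib, truth = sample_fragment_library(native, WORKED_EXAMPLE_SPEC)
    return native, lib, truth
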