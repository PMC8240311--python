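"""Core domain types: fragments, fragment libraries and target structures.

A :class:`FragmentLibrary` is the central container of the package: for each
position of a target protein it holds a list of candidate local structures
(:class:`Fragment`), each a short run of residues with secondary structure,
backbone torsions, optionally full backbone coordinates and optionally a
predicted RMSD that acts as a confidence score.

Positions are 1-based throughout; a fragment of length n at position p spans
target residues [p, p + n - 1] (closed interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import (
    AngleSet,
    DEFAULT_GEOMETRY,
    backbone_angles_from_coords,
    virtual_cbeta,
)

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
SS_LETTERS = set("HEC")

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


def _check_angle(name: str, value) -> float:
    if value is None:
        return float("nan")
    v = float(value)
    if np.isnan(v):
        return v
    if not (-180.0 < v <= 180.0):
        raise ValueError(f"{name}={v} outside (-180, 180]")
    return v


@dataclass
class FragmentResidue:
    """One residue of a fragment.

    Angles are degrees on (-180, 180] or NaN when unknown.  ``theta``/``tau``
    are CA-trace pseudo-angles; they are carried here (rather than recomputed
    on demand) because a fragment's boundary values come from its source
    protein's context, which the fragment's own coordinates cannot supply.

    ``coords`` maps atom name (N/CA/C/O/CB) to a length-3 array in Angstrom.
    """

    aa: str
    ss: str
    phi: float = float("nan")
    psi: float = float("nan")
    omega: float = float("nan")
    theta: float = float("nan")
    tau: float = float("nan")
    coords: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"unknown amino-acid letter {self.aa!r}")
        if len(self.ss) != 1 or self.ss not in SS_LETTERS:
            raise ValueError(f"secondary-structure letter must be one of H/E/C, got {self.ss!r}")
        for name in ("phi", "psi", "omega", "theta", "tau"):
            setattr(self, name, _check_angle(name, getattr(self, name)))
        if self.coords is not None:
            missing = [a for a in ("N", "CA", "C") if a not in self.coords]
            if missing:
                raise ValueError(f"coords present but lacking backbone atoms {missing}")
            self.coords = {k: np.asarray(v, float).reshape(3) for k, v in self.coords.items()}

    def angle(self, which: str) -> float:
        return getattr(self, which)


@dataclass
class Fragment:
    """A candidate local structure assigned to one target position."""

    start_pos: int
    residues: list[FragmentResidue]
    pred_rmsd: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.start_pos < 1:
            raise ValueError("start_pos is 1-based and must be >= 1")
        if len(self.residues) < 1:
            raise ValueError("fragment must have at least one residue")
        if self.pred_rmsd is not None:
            self.pred_rmsd = float(self.pred_rmsd)
            if self.pred_rmsd < 0:
                raise ValueError(f"pred_rmsd must be >= 0, got {self.pred_rmsd}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_pos(self) -> int:
        """Last target position covered (closed interval)."""
        return self.start_pos + len(self.residues) - 1

    @property
    def has_coords(self) -> bool:
        return all(r.coords is not None for r in self.residues)

    def atom_array(self, atom: str = "CA") -> np.ndarray:
        """Coordinates of one backbone atom for every residue, shape (n, 3).

        Glycine-style missing CB falls back to the virtual construction.
        """
        if not self.has_coords:
            raise ValueError("fragment has no coordinates")
        out = np.empty((len(self.residues), 3))
        for i, r in enumerate(self.residues):
            if atom in r.coords:
                out[i] = r.coords[atom]
            elif atom == "CB":
                out[i] = virtual_cbeta(r.coords["N"], r.coords["CA"], r.coords["C"])
            else:
                raise ValueError(f"residue {i} lacks atom {atom}")
        return out

    def angles(self, which: str) -> np.ndarray:
        """Per-residue values of one angle property (phi/psi/omega/theta/tau)."""
        return np.array([r.angle(which) for r in self.residues])

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ss_string(self) -> str:
        return "".join(r.ss for r in self.residues)


@dataclass
class FragmentLibrary:
    """Per-position fragment lists for a target of ``target_length`` residues."""

    target_length: int
    positions: dict[int, list[Fragment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")
        for pos, frags in self.positions.items():
            for f in frags:
                if f.start_pos != pos:
                    raise ValueError(
                        f"fragment at position {pos} has start_pos {f.start_pos}")
                if f.end_pos > self.target_length:
                    raise ValueError(
                        f"fragment at position {pos} (length {len(f)}) overruns "
                        f"target of length {self.target_length}")

    def n_fragments(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def iter_fragments(self):
        for pos in sorted(self.positions):
            for frag in self.positions[pos]:
                yield frag

    def add(self, frag: Fragment) -> None:
        self.positions.setdefault(frag.start_pos, []).append(frag)
        if frag.end_pos > self.target_length:
            raise ValueError("fragment overruns target")


@dataclass
class TargetStructure:
    """A native/target backbone with derived angles and secondary structure.

    ``backbone`` maps atom name N/CA/C/O to (L, 3) arrays; ``cb`` holds CB
    positions (virtual for glycine).  ``angles`` is the derived
    :class:`~fraglib.geometry.AngleSet`; ``ss`` the per-residue H/E/C letters.
    ``chain_breaks`` holds indices i (0-based) where the CA(i)-CA(i+1)
    distance falls outside the sanity band: windows crossing a break are not
    valid fragment references.
    """

    sequence: str
    backbone: dict[str, np.ndarray]
    cb: np.ndarray
    angles: AngleSet
    ss: list[str]
    chain_breaks: set[int] = field(default_factory=set)

    CA_CA_BAND = (2.5, 4.5)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_backbone(cls, sequence: str, N, CA, C, O=None, ss=None,
                      cb=None) -> "TargetStructure":
        """Build a structure from backbone coordinates, deriving everything else."""
        N = np.asarray(N, float)
        CA = np.asarray(CA, float)
        C = np.asarray(C, float)
        L = len(sequence)
        if not (len(N) == len(CA) == len(C) == L):
            raise ValueError("sequence length and coordinate arrays disagree")
        angles = backbone_angles_from_coords(N, CA, C)
        if O is None:
            O = np.full((L, 3), np.nan)
        else:
            O = np.asarray(O, float)
        if cb is None:
            cb = np.array([virtual_cbeta(N[i], CA[i], C[i]) for i in range(L)])
        else:
            cb = np.asarray(cb, float)
        if ss is None:
            ss = [geometry.assign_ss3(angles.phi[i], angles.psi[i]) for i in range(L)]
        breaks = set()
        d = np.linalg.norm(np.diff(CA, axis=0), axis=1)
        lo, hi = cls.CA_CA_BAND
        for i, di in enumerate(d):
            if not (lo <= di <= hi):
                logger.warning("chain break between residues %d and %d (CA-CA %.2f A)",
                               i + 1, i + 2, di)
                breaks.add(i)
        return cls(sequence=sequence, backbone={"N": N, "CA": CA, "C": C, "O": O},
                   cb=cb, angles=angles, ss=list(ss), chain_breaks=breaks)

    @classmethod
    def from_torsions(cls, sequence: str, phi, psi, omega=None,
                      ss=None, ideal=DEFAULT_GEOMETRY) -> "TargetStructure":
        bb = geometry.reconstruct_backbone_coords(phi, psi, omega, ideal)
        return cls.from_backbone(sequence, bb["N"], bb["CA"], bb["C"], O=bb["O"],
                                 cb=bb["CB"], ss=ss)

    def window_crosses_break(self, start_pos: int, length: int) -> bool:
        """True if the 1-based window [start_pos, start_pos+length-1] spans a break."""
        lo = start_pos - 1
        return any(lo <= b < lo + length - 1 for b in self.chain_breaks)

    def window_atoms(self, start_pos: int, length: int, atom: str = "CA") -> np.ndarray:
        if start_pos < 1 or start_pos + length - 1 > len(self):
            raise ValueError(f"window [{start_pos}, {start_pos + length - 1}] outside target")
        if self.window_crosses_break(start_pos, length):
            raise ValueError(f"window at {start_pos} crosses a chain break")
        lo = start_pos - 1
        if atom == "CB":
            return self.cb[lo:lo + length]
        return self.backbone[atom][lo:lo + length]

    def window_angles(self, start_pos: int, length: int, which: str) -> np.ndarray:
        lo = start_pos - 1
        return self.angles.as_dict()[which][lo:lo + length]

    def window_ss(self, start_pos: int, length: int) -> list[str]:
        lo = start_pos - 1
        return self.ss[lo:lo + length]

    def extract_fragment(self, start_pos: int, length: int) -> Fragment:
        """Cut a verbatim fragment out of the native structure."""
        if self.window_crosses_break(start_pos, length):
            raise ValueError(f"window at {start_pos} crosses a chain break")
        residues = []
        for j in range(length):
            i = start_pos - 1 + j
            coords = {a: self.backbone[a][i] for a in ("N", "CA", "C")}
            if np.isfinite(self.backbone["O"][i]).all():
                coords["O"] = self.backbone["O"][i]
            coords["CB"] = self.cb[i]
            residues.append(FragmentResidue(
                aa=self.sequence[i], ss=self.ss[i],
                phi=self.angles.phi[i], psi=self.angles.psi[i],
                omega=self.angles.omega[i], theta=self.angles.theta[i],
                tau=self.angles.tau[i], coords=coords))
        return Fragment(start_pos=start_pos, residues=residues, source_id="native")
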