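"""Fragment-library quality metrics.

Two classical whole-library metrics and seven fragment-level metrics are
implemented.  *Precision* is the fraction of good fragments in the library and
*coverage* the fraction of target positions spanned by at least one good
fragment, where a good fragment has CA RMSD to its native window below a
cutoff (grid 0.1-2.0 A by default).

The fragment-level metrics are nested expectations: an inner mean over the
fragments of one position, then an outer mean over positions,

    ACC_ss(FL)  = E_p [ E_f [ I(SS(f) == SS(native window)) ] ]
    ERR_ang(FL) = E_p [ E_f [ mean_j min(|d_j|, 360 - |d_j|) ] ]
    ERR_dist(FL)= E_p [ E_f [ MAE over within-fragment atom pairs ] ]

covering fragment secondary-structure class (majority H/E/C, else O), the
four angle properties phi/psi/theta/tau, and CA-CA / CB-CB pairwise
distances.  The *weighted* variants replace the inner mean by a
softmax-confidence weighted average over each position's fragments (weights
from predicted RMSD at temperature T = 0.1), which rewards libraries whose
confidence scores actually track fragment quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Fragment, FragmentLibrary, TargetStructure
from .geometry import all_pairs, kabsch_rmsd, pairwise_distances

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "fragment_rmsd",
    "precision",
    "coverage",
    "fragment_ss_class",
    "acc_ss",
    "err_angle",
    "err_distance",
    "evaluate_library",
    "weighted_metrics",
]

DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))

ANGLE_PROPERTIES = ("phi", "psi", "theta", "tau")


@dataclass
class MetricsReport:
    """All library metrics in one record (fractions in [0,1], errors >= 0)."""

    precision: dict[float, float]
    coverage: dict[float, float]
    acc_ss: float
    err_phi: float
    err_psi: float
    err_theta: float
    err_tau: float
    err_ca_dist: float
    err_cb_dist: float
    weighted: bool = False
    temperature: float | None = None

    def to_dict(self) -> dict:
        return {
            "precision": {f"{k:.1f}": v for k, v in self.precision.items()},
            "coverage": {f"{k:.1f}": v for k, v in self.coverage.items()},
            "acc_ss": self.acc_ss,
            "err_phi": self.err_phi,
            "err_psi": self.err_psi,
            "err_theta": self.err_theta,
            "err_tau": self.err_tau,
            "err_ca_dist": self.err_ca_dist,
            "err_cb_dist": self.err_cb_dist,
            "weighted": self.weighted,
            "temperature": self.temperature,
        }


def _fragment_ca(frag: Fragment) -> np.ndarray:
    if frag.has_coords:
        return frag.atom_array("CA")
    # torsion-only fragments: rebuild on ideal geometry
    from .geometry import reconstruct_backbone_coords
    phi = frag.angles("phi")
    psi = frag.angles("psi")
    omega = frag.angles("omega")
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        raise ValueError("fragment lacks both coordinates and complete torsions")
    return reconstruct_backbone_coords(phi, psi, omega)["CA"]


def fragment_rmsd(frag: Fragment, native: TargetStructure) -> float:
    """CA RMSD between a fragment and its native window after superposition."""
    ca_native = native.window_atoms(frag.start_pos, len(frag), "CA")
    return kabsch_rmsd(ca_native, _fragment_ca(frag))


def _all_rmsds(lib: FragmentLibrary, native: TargetStructure) -> list[tuple[Fragment, float]]:
    out = []
    for frag in lib.iter_fragments():
        out.append((frag, fragment_rmsd(frag, native)))
    return out


def precision(lib: FragmentLibrary, native: TargetStructure, cutoff: float) -> float:
    """Fraction of fragments with RMSD strictly below ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if lib.n_fragments() == 0:
        raise ValueError("empty library")
    rmsds = [r for _, r in _all_rmsds(lib, native)]
    return float(np.mean([r < cutoff for r in rmsds]))


def coverage(lib: FragmentLibrary, native: TargetStructure, cutoff: float) -> float:
    """Fraction of target positions spanned by at least one good fragment."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if lib.n_fragments() == 0:
        raise ValueError("empty library")
    covered: set[int] = set()
    for frag, r in _all_rmsds(lib, native):
        if r < cutoff:
            covered.update(range(frag.start_pos, frag.end_pos + 1))
    return len(covered) / lib.target_length


def fragment_ss_class(frag_ss) -> str:
    """H/E/C if a strict majority of residues carries that letter, else O."""
    letters = list(frag_ss.ss_string()) if isinstance(frag_ss, Fragment) else list(frag_ss)
    n = len(letters)
    for cls in "HEC":
        if letters.count(cls) * 2 > n:
            return cls
    return "O"


def _inner_mean(values: np.ndarray, weights: np.ndarray | None) -> float:
    """Mean over one position's fragments, optionally confidence-weighted."""
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    if not ok.any():
        return float("nan")
    if weights is None:
        return float(values[ok].mean())
    w = np.asarray(weights, float)[ok]
    return float(np.sum(w * values[ok]) / np.sum(w))


def _position_weights(frags: list[Fragment], temperature: float) -> np.ndarray:
    from .potentials import fragment_weights
    rmsds = [f.pred_rmsd for f in frags]
    if any(r is None for r in rmsds):
        raise ValueError("weighted metrics require pred_rmsd on every fragment")
    return fragment_weights(rmsds, temperature)


def _nested_metric(lib: FragmentLibrary, per_fragment, weights_of=None) -> float:
    """Outer mean over positions of the (weighted) inner mean of a per-fragment score.

    Positions whose fragments all yield NaN (or with no fragments) are
    excluded from the outer mean.
    """
    position_means = []
    for pos in sorted(lib.positions):
        frags = lib.positions[pos]
        if not frags:
            continue
        vals = np.array([per_fragment(f) for f in frags], float)
        w = weights_of(frags) if weights_of is not None else None
        m = _inner_mean(vals, w)
        if np.isfinite(m):
            position_means.append(m)
    if not position_means:
        raise ValueError("no position produced a defined metric value")
    return float(np.mean(position_means))


def _ss_indicator(frag: Fragment, native: TargetStructure) -> float:
    native_cls = fragment_ss_class(native.window_ss(frag.start_pos, len(frag)))
    return 1.0 if fragment_ss_class(frag) == native_cls else 0.0


def _angle_error(frag: Fragment, native: TargetStructure, which: str) -> float:
    fa = frag.angles(which)
    na = native.window_angles(frag.start_pos, len(frag), which)
    ok = np.isfinite(fa) & np.isfinite(na)
    if not ok.any():
        return float("nan")
    d = np.abs(fa[ok] - na[ok])
    return float(np.mean(np.minimum(d, 360.0 - d)))


def _distance_error(frag: Fragment, native: TargetStructure, atom: str) -> float:
    n = len(frag)
    if n < 2:
        return float("nan")
    pairs = all_pairs(n)
    df = pairwise_distances(frag.atom_array(atom), pairs)
    dn = pairwise_distances(native.window_atoms(frag.start_pos, n, atom), pairs)
    return float(np.mean(np.abs(df - dn)))


def acc_ss(lib: FragmentLibrary, native: TargetStructure,
           weights_of=None) -> float:
    """Fragment-level secondary-structure accuracy (nested expectation)."""
    return _nested_metric(lib, lambda f: _ss_indicator(f, native), weights_of)


def err_angle(lib: FragmentLibrary, native: TargetStructure, which: str,
              weights_of=None) -> float:
    """Fragment-level angular error (degrees) for phi/psi/theta/tau."""
    if which not in ANGLE_PROPERTIES:
        raise ValueError(f"unknown angle property {which!r}")
    return _nested_metric(lib, lambda f: _angle_error(f, native, which), weights_of)


def err_distance(lib: FragmentLibrary, native: TargetStructure, atom: str,
                 weights_of=None) -> float:
    """Fragment-level pairwise-distance MAE (Angstrom) for CA or CB."""
    if atom not in ("CA", "CB"):
        raise ValueError("atom must be 'CA' or 'CB'")
    return _nested_metric(lib, lambda f: _distance_error(f, native, atom), weights_of)


def evaluate_library(lib: FragmentLibrary, native: TargetStructure,
                     cutoffs=DEFAULT_CUTOFF_GRID, weighted: bool = False,
                     temperature: float = 0.1) -> MetricsReport:
    """Compute the full metrics report for a library against its native."""
    weights_of = None
    if weighted:
        weights_of = lambda frags: _position_weights(frags, temperature)  # noqa: E731
    rmsds = _all_rmsds(lib, native)
    prec, cov = {}, {}
    for c in cutoffs:
        good = [(f, r) for f, r in rmsds if r < c]
        prec[float(c)] = len(good) / len(rmsds)
        covered: set[int] = set()
        for f, _ in good:
            covered.update(range(f.start_pos, f.end_pos + 1))
        cov[float(c)] = len(covered) / lib.target_length
    return MetricsReport(
        precision=prec,
        coverage=cov,
        acc_ss=acc_ss(lib, native, weights_of),
        err_phi=err_angle(lib, native, "phi", weights_of),
        err_psi=err_angle(lib, native, "psi", weights_of),
        err_theta=err_angle(lib, native, "theta", weights_of),
        err_tau=err_angle(lib, native, "tau", weights_of),
        err_ca_dist=err_distance(lib, native, "CA", weights_of),
        err_cb_dist=err_distance(lib, native, "CB", weights_of),
        weighted=weighted,
        temperature=temperature if weighted else None,
    )


def weighted_metrics(lib: FragmentLibrary, native: TargetStructure,
                     temperature: float = 0.1,
                     cutoffs=DEFAULT_CUTOFF_GRID) -> MetricsReport:
    """Confidence-weighted metrics report (softmax weights from pred_rmsd)."""
    return evaluate_library(lib, native, cutoffs=cutoffs, weighted=True,
                            temperature=temperature)
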