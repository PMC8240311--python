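"""Protein-specific potentials from weighted Gaussian mixtures of fragment properties.

Pipeline: a fragment library is first *smoothed* -- every fragment is cut into
7-residue sub-fragments by a sliding window so all windows share one length.
For each target position the sub-fragments assigned there provide samples of
six structural properties: the torsions phi/psi, the CA-trace pseudo-angles
theta/tau (one sample per residue offset 0..6 of the window -- 7 slots per 1D
property) and the within-window CA-CA and CB-CB distances (one sample per
residue pair, 21 slots per 2D property).  Each slot's samples are fitted with
a *weighted* Gaussian mixture (wGMM, K = 4 components by default): a fragment
with predicted RMSD r contributes with softmax confidence weight

    w_i = exp((5.0 - r_i)/T) / sum_j exp((5.0 - r_j)/T),        T = 0.1,

so that fragments believed to be near-native dominate the fit.  With all
slots defined this yields 7*4 + 21*2 = 70 models per position.

A fitted model becomes an energy term through its negative log likelihood:
for a candidate structure x the 1D potential of, e.g., phi is

    L_phi(x) = - sum_i log sum_t w_{i,t} p(phi_i; mu_{i,t}, sigma_{i,t})

and the 2D potentials sum over the 21 within-window pairs of each position.
The combined fragment potential is the weighted sum of the six per-property
potentials; its gradient-descent minimisation is exercised by
:mod:`fraglib.folding`.

Angles are fitted on the linear degree scale on the branch (-180, 180]; no
circular density is used, so properties with mass near the +/-180 seam are a
documented limitation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .core import Fragment, FragmentLibrary
from .geometry import all_pairs, ca_trace_angles

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothedLibrary",
    "WGMMComponent",
    "WGMMModel",
    "PositionPotentialSet",
    "smooth_library",
    "fragment_weights",
    "fit_weighted_gmm",
    "wgmm_bic",
    "select_n_components",
    "build_position_potentials",
    "build_all_potentials",
    "nll_potential_1d",
    "nll_potential_2d",
    "combined_potential",
    "save_potentials",
    "load_potentials",
]

WINDOW = 7
DEFAULT_TEMPERATURE = 0.1
DEFAULT_K = 4
VARIANCE_FLOOR = 1e-3
EM_TOL = 1e-6
EM_MAX_ITER = 500
PDF_FLOOR = 1e-30
#: constant offset in the confidence softmax (cancels; kept for fidelity)
SOFTMAX_OFFSET = 5.0

PROPERTIES_1D = ("phi", "psi", "theta", "tau")
PROPERTIES_2D = ("dCA", "dCB")
PAIRS_2D = tuple(map(tuple, all_pairs(WINDOW)))  # 21 pairs, lexicographic


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

@dataclass
class SmoothedLibrary:
    """Per-position lists of fixed-length (7-residue) sub-fragments."""

    target_length: int
    window: int
    positions: dict[int, list[Fragment]] = field(default_factory=dict)
    n_dropped: int = 0

    def n_fragments(self) -> int:
        return sum(len(v) for v in self.positions.values())


def _ensure_pseudo_angles(frag: Fragment) -> None:
    """Fill theta/tau on a fragment's residues from its CA trace if absent."""
    if not frag.has_coords:
        return
    need_theta = len(frag) > 2 and np.isnan(frag.angles("theta")[1:-1]).any()
    need_tau = len(frag) > 3 and np.isnan(frag.angles("tau")[1:-2]).any()
    if not (need_theta or need_tau):
        return
    theta, tau = ca_trace_angles(frag.atom_array("CA"))
    for j, r in enumerate(frag.residues):
        if not np.isfinite(r.theta):
            r.theta = theta[j]
        if not np.isfinite(r.tau):
            r.tau = tau[j]


def smooth_library(lib: FragmentLibrary, window: int = WINDOW) -> SmoothedLibrary:
    """Cut every fragment into ``window``-residue sub-fragments (sliding window).

    A parent of length n >= window at position p yields n - window + 1
    sub-fragments at positions p .. p + n - window; shorter parents are
    dropped (counted and logged).  Sub-fragments inherit the parent's
    pred_rmsd, source_id and per-residue angles; theta/tau are computed over
    the parent's full CA trace first so that window-boundary values keep
    their parent context.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    out: dict[int, list[Fragment]] = {}
    dropped = 0
    for parent in lib.iter_fragments():
        n = len(parent)
        if n < window:
            dropped += 1
            continue
        _ensure_pseudo_angles(parent)
        for off in range(n - window + 1):
            residues = parent.residues[off:off + window]
            sub = Fragment(start_pos=parent.start_pos + off,
                           residues=residues,
                           pred_rmsd=parent.pred_rmsd,
                           source_id=parent.source_id)
            out.setdefault(sub.start_pos, []).append(sub)
    if dropped:
        logger.info("smoothing dropped %d fragments shorter than %d residues",
                    dropped, window)
    return SmoothedLibrary(target_length=lib.target_length, window=window,
                           positions=out, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Confidence weights
# ---------------------------------------------------------------------------

def fragment_weights(pred_rmsds, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Softmax confidence weights from predicted RMSDs (lower RMSD => higher weight).

    Computed with a max-shift for numerical stability; the constant offset in
    the score cancels in the normalisation.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    arr = np.asarray([np.nan if r is None else float(r) for r in pred_rmsds], float)
    if arr.size == 0:
        raise ValueError("empty pred_rmsd list")
    if np.isnan(arr).any():
        raise ValueError("pred_rmsd missing for some fragments")
    scores = (SOFTMAX_OFFSET - arr) / temperature
    scores -= scores.max()
    w = np.exp(scores)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Weighted EM for 1D Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class WGMMComponent:
    weight: float
    mean: float
    variance: float


@dataclass
class WGMMModel:
    """One property's weighted Gaussian mixture at one (position, slot)."""

    components: list[WGMMComponent]
    prop: str | None = None
    slot: object = None  # residue offset 0..6 or pair (j1, j2)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("model needs at least one component")
        s = sum(c.weight for c in self.components)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {s}, not 1")
        for c in self.components:
            if c.variance < VARIANCE_FLOOR * (1 - 1e-12):
                raise ValueError(f"variance {c.variance} below floor {VARIANCE_FLOOR}")

    @property
    def K(self) -> int:
        return len(self.components)

    def _params(self):
        w = np.array([c.weight for c in self.components])
        mu = np.array([c.mean for c in self.components])
        var = np.array([c.variance for c in self.components])
        return w, mu, var

    def logpdf(self, y) -> np.ndarray:
        """Log mixture density at y (scalar or array)."""
        y = np.atleast_1d(np.asarray(y, float))
        w, mu, var = self._params()
        comp = (np.log(w) - 0.5 * np.log(2 * np.pi * var)
                - (y[:, None] - mu) ** 2 / (2 * var))
        return logsumexp(comp, axis=1)

    def pdf(self, y) -> np.ndarray:
        return np.exp(self.logpdf(y))

    def nll(self, y) -> float:
        """Negative log likelihood of one value, with the density floored."""
        p = float(np.exp(self.logpdf(y)[0]))
        return -math.log(max(p, PDF_FLOOR))


def _weighted_quantile(sorted_x: np.ndarray, cum_w: np.ndarray, q: float) -> float:
    """Inverse-CDF quantile of the weighted empirical distribution.

    Depends on the distribution only, so duplicating a sample while halving
    its weight leaves the result unchanged.
    """
    idx = int(np.searchsorted(cum_w, q, side="left"))
    idx = min(idx, len(sorted_x) - 1)
    return float(sorted_x[idx])


def fit_weighted_gmm(samples, weights=None, K: int = DEFAULT_K, seed: int = 0,
                     var_floor: float = VARIANCE_FLOOR, tol: float = EM_TOL,
                     max_iter: int = EM_MAX_ITER, return_history: bool = False):
    """Fit a K-component 1D Gaussian mixture with per-sample weights by EM.

    Weights act as multiplicities: the E-step responsibilities are standard,
    and every M-step statistic multiplies the responsibility by the sample
    weight.  Initialisation places component means at weighted quantiles of
    the sample distribution (variances at the weighted total variance, mixing
    uniform), which is deterministic and invariant to sample duplication; the
    ``seed`` argument is accepted for API stability but the fit does not
    consume randomness.  K is reduced (and logged) when the effective sample
    size or the number of distinct values cannot support it.  Variances are
    floored at ``var_floor``.
    """
    x = np.asarray(samples, float).ravel()
    if x.size == 0:
        raise ValueError("no samples")
    if np.isnan(x).any():
        raise ValueError("samples contain NaN")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights shape mismatch")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative and not all zero")
        w = w / w.sum()

    ess = 1.0 / float(np.sum(w ** 2))
    n_distinct = np.unique(x).size
    K_eff = max(1, min(K, int(math.floor(ess)), n_distinct))
    if K_eff < K:
        logger.info("reducing K from %d to %d (ESS %.1f, %d distinct values)",
                    K, K_eff, ess, n_distinct)

    mean_all = float(np.sum(w * x))
    var_all = max(float(np.sum(w * (x - mean_all) ** 2)), var_floor)
    if n_distinct == 1:
        model = WGMMModel([WGMMComponent(1.0, mean_all, var_floor)])
        return (model, [0.0]) if return_history else model

    order = np.argsort(x, kind="stable")
    xs = x[order]
    cw = np.cumsum(w[order])
    mu = np.array([_weighted_quantile(xs, cw, (2 * k + 1) / (2 * K_eff))
                   for k in range(K_eff)])
    var = np.full(K_eff, var_all)
    pi = np.full(K_eff, 1.0 / K_eff)

    history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step in the log domain
        log_comp = (np.log(pi) - 0.5 * np.log(2 * np.pi * var)
                    - (x[:, None] - mu) ** 2 / (2 * var))
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(np.sum(w * log_norm))
        history.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        # M-step with weights as multiplicities
        wr = w[:, None] * resp
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pi = nk / nk.sum()
        mu = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    order = np.argsort(mu, kind="stable")
    comps = [WGMMComponent(float(pi[k]), float(mu[k]), float(var[k])) for k in order]
    model = WGMMModel(comps)
    return (model, history) if return_history else model


def _weighted_loglik(model: WGMMModel, samples, weights=None) -> tuple[float, float]:
    x = np.asarray(samples, float).ravel()
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, float).ravel()
        w = w / w.sum()
    ll = float(np.sum(w * model.logpdf(x)))
    ess = 1.0 / float(np.sum(w ** 2))
    return ll, ess


def wgmm_bic(model: WGMMModel, samples, weights=None) -> float:
    """Bayesian Information Criterion of a fitted weighted mixture (lower = better).

    Uses the weighted mean log likelihood scaled by the Kish effective sample
    size n_eff: BIC = -2 n_eff llbar + p ln(n_eff) with p = 3K - 1 free
    parameters (K means, K variances, K - 1 mixing weights).
    """
    llbar, ess = _weighted_loglik(model, samples, weights)
    p = 3 * model.K - 1
    return float(-2.0 * ess * llbar + p * math.log(ess))


def select_n_components(samples, weights=None, k_range=range(2, 31), seed: int = 0):
    """Scan K over ``k_range`` and return (best_K, {K: BIC})."""
    scores = {}
    for K in k_range:
        m = fit_weighted_gmm(samples, weights, K=K, seed=seed)
        scores[K] = wgmm_bic(m, samples, weights)
    best = min(scores, key=lambda k: (scores[k], k))
    return best, scores


# ---------------------------------------------------------------------------
# Per-position potential sets
# ---------------------------------------------------------------------------

@dataclass
class PositionPotentialSet:
    """All wGMM models of one position plus the six combination weights.

    ``models`` maps (property, slot) -> WGMMModel, where slot is a residue
    offset 0..6 for the 1D properties phi/psi/theta/tau and a pair
    (j1, j2), 0 <= j1 < j2 <= 6, for the distance properties dCA/dCB.  A
    fully populated position has 4*7 + 2*21 = 70 models.
    """

    position: int
    models: dict = field(default_factory=dict)
    combine_weights: dict = field(default_factory=lambda: {
        "phi": 1.0, "psi": 1.0, "theta": 1.0, "tau": 1.0, "dCA": 1.0, "dCB": 1.0})

    def n_models(self) -> int:
        return len(self.models)

    def models_for(self, prop: str) -> dict:
        return {slot: m for (p, slot), m in self.models.items() if p == prop}


def build_position_potentials(smoothed: SmoothedLibrary, position: int,
                              K: int = DEFAULT_K,
                              temperature: float = DEFAULT_TEMPERATURE,
                              seed: int = 0) -> PositionPotentialSet:
    """Fit the (up to) 70 wGMM models of one position of a smoothed library.

    Slots where no sub-fragment has a defined value are omitted and logged.
    Fragments without pred_rmsd get uniform weights (with a log note).
    """
    frags = smoothed.positions.get(position)
    if not frags:
        raise ValueError(f"no sub-fragments at position {position}")
    rmsds = [f.pred_rmsd for f in frags]
    if any(r is None for r in rmsds):
        logger.info("position %d: pred_rmsd missing, using uniform weights", position)
        base_w = np.full(len(frags), 1.0 / len(frags))
    else:
        base_w = fragment_weights(rmsds, temperature)

    pset = PositionPotentialSet(position=position)
    n_omitted = 0

    def fit_slot(prop, slot, values):
        nonlocal n_omitted
        values = np.asarray(values, float)
        ok = np.isfinite(values)
        if not ok.any():
            n_omitted += 1
            return
        w = base_w[ok]
        model = fit_weighted_gmm(values[ok], w / w.sum(), K=K, seed=seed)
        model.prop = prop
        model.slot = slot
        pset.models[(prop, slot)] = model

    for prop in PROPERTIES_1D:
        per_frag = [f.angles(prop) for f in frags]
        for off in range(smoothed.window):
            fit_slot(prop, off, [a[off] for a in per_frag])

    with_coords = [i for i, f in enumerate(frags) if f.has_coords]
    if with_coords:
        pairs = np.asarray(all_pairs(smoothed.window))
        for prop, atom in (("dCA", "CA"), ("dCB", "CB")):
            dmat = np.full((len(frags), len(pairs)), np.nan)
            for i in with_coords:
                coords = frags[i].atom_array(atom)
                d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
                dmat[i] = np.linalg.norm(d, axis=1)
            for k, (j1, j2) in enumerate(map(tuple, pairs)):
                fit_slot(prop, (int(j1), int(j2)), dmat[:, k])
    else:
        n_omitted += 2 * len(PAIRS_2D)
        logger.info("position %d: no coordinates, 2D slots omitted", position)

    if n_omitted:
        logger.info("position %d: %d slots omitted (no defined values)",
                    position, n_omitted)
    return pset


def build_all_potentials(lib: FragmentLibrary, K: int = DEFAULT_K,
                         temperature: float = DEFAULT_TEMPERATURE,
                         seed: int = 0, window: int = WINDOW,
                         ) -> dict[int, PositionPotentialSet]:
    """Smooth a library and fit potential sets for every populated position."""
    smoothed = smooth_library(lib, window)
    out = {}
    for pos in sorted(smoothed.positions):
        out[pos] = build_position_potentials(smoothed, pos, K=K,
                                             temperature=temperature, seed=seed)
    return out


# ---------------------------------------------------------------------------
# NLL potentials
# ---------------------------------------------------------------------------

def nll_potential_1d(values, models: dict) -> float:
    """Sum of -log mixture density over the 1D slots of one position.

    ``values`` maps slot -> property value (or is a sequence indexed by
    offset); slots with a NaN value or no model are skipped.  Raises if no
    slot overlaps.
    """
    if not isinstance(values, dict):
        values = {i: v for i, v in enumerate(values)}
    energy = 0.0
    n_terms = 0
    for slot, model in models.items():
        v = values.get(slot)
        if v is None or not np.isfinite(v):
            continue
        energy += model.nll(v)
        n_terms += 1
    if n_terms == 0:
        raise ValueError("no overlapping slots between values and models")
    return energy


def nll_potential_2d(pair_values: dict, models: dict) -> float:
    """Sum of -log mixture density over the pair slots of one position."""
    return nll_potential_1d(pair_values, models)


def combined_potential(structure_properties: dict,
                       potential_sets: dict[int, PositionPotentialSet],
                       combine_weights: dict | None = None):
    """Weighted sum of the six per-property potentials over all positions.

    ``structure_properties`` holds per-residue arrays ``phi``, ``psi``,
    ``theta``, ``tau`` (degrees, NaN where undefined) and coordinate arrays
    ``ca``, ``cb`` of shape (L, 3).  Overlapping windows each contribute
    their own terms (shared residue pairs are deliberately counted once per
    window, matching the per-position modelling).

    Returns ``(energy, breakdown)`` where breakdown maps property -> summed
    unweighted potential.
    """
    breakdown = {p: 0.0 for p in PROPERTIES_1D + PROPERTIES_2D}
    ang = {p: np.asarray(structure_properties[p], float) for p in PROPERTIES_1D}
    ca = structure_properties.get("ca")
    cb = structure_properties.get("cb")

    for pos, pset in potential_sets.items():
        base = pos - 1  # 0-based first residue of the window
        if combine_weights is None:
            cw = pset.combine_weights
        else:
            cw = combine_weights
        for prop in PROPERTIES_1D:
            models = pset.models_for(prop)
            if not models:
                continue
            vals = {}
            for off in models:
                idx = base + off
                if 0 <= idx < len(ang[prop]):
                    vals[off] = ang[prop][idx]
            if any(np.isfinite(v) for v in vals.values()):
                breakdown[prop] += nll_potential_1d(vals, models)
        for prop, coords in (("dCA", ca), ("dCB", cb)):
            models = pset.models_for(prop)
            if not models or coords is None:
                continue
            vals = {}
            for (j1, j2) in models:
                i1, i2 = base + j1, base + j2
                if 0 <= i1 < len(coords) and 0 <= i2 < len(coords):
                    vals[(j1, j2)] = float(np.linalg.norm(coords[i1] - coords[i2]))
            if vals:
                breakdown[prop] += nll_potential_2d(vals, models)

    weights = combine_weights
    if weights is None:
        any_set = next(iter(potential_sets.values()), None)
        weights = any_set.combine_weights if any_set else {}
    energy = sum(weights.get(p, 1.0) * breakdown[p] for p in breakdown)
    return float(energy), breakdown


# ---------------------------------------------------------------------------
# Serialization (documented structured text: JSON)
# ---------------------------------------------------------------------------

def save_potentials(potential_sets: dict[int, PositionPotentialSet], path) -> Path:
    """Write potential sets as JSON: components per slot per position."""
    doc = {"format": "fraglib-potentials", "version": 1, "positions": {}}
    for pos, pset in potential_sets.items():
        models = []
        for (prop, slot), m in pset.models.items():
            models.append({
                "property": prop,
                "slot": list(slot) if isinstance(slot, tuple) else slot,
                "components": [{"weight": c.weight, "mean": c.mean,
                                "variance": c.variance} for c in m.components],
            })
        doc["positions"][str(pos)] = {
            "combine_weights": pset.combine_weights,
            "models": models,
        }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_potentials(path) -> dict[int, PositionPotentialSet]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fraglib-potentials":
        raise ValueError(f"{path}: not a fraglib potentials file")
    out = {}
    for pos_str, entry in doc["positions"].items():
        pos = int(pos_str)
        pset = PositionPotentialSet(position=pos,
                                    combine_weights=dict(entry["combine_weights"]))
        for m in entry["models"]:
            slot = tuple(m["slot"]) if isinstance(m["slot"], list) else m["slot"]
            comps = [WGMMComponent(c["weight"], c["mean"], c["variance"])
                     for c in m["components"]]
            pset.models[(m["property"], slot)] = WGMMModel(
                comps, prop=m["property"], slot=slot)
        out[pos] = pset
    return out
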