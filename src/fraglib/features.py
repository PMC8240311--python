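"""Fragment-library featurization for property-prediction networks.

A library is encoded as a rank-4 tensor of shape (L, n_frags, pad_len, D):
for each of the L target positions, the ``n_frags`` (default 50) fragments
with the lowest predicted RMSD are kept, each padded to ``pad_len`` (default
15) residues.  Per real residue slot the feature vector is a 3-state
secondary-structure one-hot followed by the sine/cosine of the four angle
properties phi, psi, theta, tau, giving D = 3 + 8 = 11.  A missing angle is
encoded as the (0, 0) sin/cos pair, distinguishable from any real angle whose
pair has unit norm; padded residue slots are all-zero with the mask unset.

The module also provides the monotone distance mapping used to compress
inter-residue distances into (-1, 1),

    d' = tanh((d - 10) / 2.4),

and its exact inverse, applied to network outputs to recover Angstrom-valued
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Fragment, FragmentLibrary

__all__ = [
    "FeatureTensor",
    "select_top_fragments",
    "featurize_library",
    "map_distance",
    "inverse_map_distance",
]

DEFAULT_N_FRAGS = 50
DEFAULT_PAD_LEN = 15
FEATURE_DIM = 11  # 3 SS one-hot + sin/cos of phi, psi, theta, tau

_SS_INDEX = {"H": 0, "E": 1, "C": 2}
_ANGLE_ORDER = ("phi", "psi", "theta", "tau")

DISTANCE_MAP_CENTER = 10.0
DISTANCE_MAP_SCALE = 2.4


@dataclass
class FeatureTensor:
    """Featurized library: values (L, n_frags, pad_len, D), mask (L, n_frags, pad_len)."""

    values: np.ndarray
    mask: np.ndarray

    @property
    def shape(self):
        return self.values.shape

    def save(self, path) -> None:
        """Serialize as a NumPy .npz container with shape/dtype preserved."""
        np.savez_compressed(path, values=self.values, mask=self.mask)

    @classmethod
    def load(cls, path) -> "FeatureTensor":
        with np.load(path) as data:
            return cls(values=data["values"], mask=data["mask"])


def select_top_fragments(position_frags, n: int = DEFAULT_N_FRAGS) -> list[Fragment]:
    """The n fragments with lowest predicted RMSD; ties keep original order.

    Returns all fragments when fewer than n are available.
    """
    frags = list(position_frags)
    if any(f.pred_rmsd is None for f in frags):
        raise ValueError("fragment selection requires pred_rmsd on every fragment")
    order = sorted(range(len(frags)), key=lambda i: (frags[i].pred_rmsd, i))
    return [frags[i] for i in order[:n]]


def _residue_features(res) -> np.ndarray:
    v = np.zeros(FEATURE_DIM)
    v[_SS_INDEX[res.ss]] = 1.0
    for k, prop in enumerate(_ANGLE_ORDER):
        a = res.angle(prop)
        if np.isfinite(a):
            r = np.radians(a)
            v[3 + 2 * k] = np.sin(r)
            v[3 + 2 * k + 1] = np.cos(r)
    return v


def featurize_library(lib: FragmentLibrary, n_frags: int = DEFAULT_N_FRAGS,
                      pad_len: int = DEFAULT_PAD_LEN) -> FeatureTensor:
    """Build the (L, n_frags, pad_len, D) feature tensor of a library."""
    L = lib.target_length
    values = np.zeros((L, n_frags, pad_len, FEATURE_DIM))
    mask = np.zeros((L, n_frags, pad_len), dtype=bool)
    for pos, frags in lib.positions.items():
        top = select_top_fragments(frags, n_frags)
        for fi, frag in enumerate(top):
            if len(frag) > pad_len:
                raise ValueError(
                    f"fragment at position {pos} (source {frag.source_id}) has "
                    f"{len(frag)} residues, longer than pad_len {pad_len}")
            for j, res in enumerate(frag.residues):
                values[pos - 1, fi, j] = _residue_features(res)
                mask[pos - 1, fi, j] = True
    return FeatureTensor(values=values, mask=mask)


def map_distance(d):
    """Compress a distance (A) into (-1, 1): tanh((d - 10)/2.4)."""
    d = np.asarray(d, float)
    out = np.tanh((d - DISTANCE_MAP_CENTER) / DISTANCE_MAP_SCALE)
    return float(out) if out.ndim == 0 else out


def inverse_map_distance(dp):
    """Exact inverse of :func:`map_distance`; defined on (-1, 1) only."""
    dp = np.asarray(dp, float)
    if np.any(np.abs(dp) >= 1.0):
        raise ValueError("mapped distance must lie strictly inside (-1, 1)")
    out = DISTANCE_MAP_CENTER + DISTANCE_MAP_SCALE * np.arctanh(dp)
    return float(out) if out.ndim == 0 else out
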