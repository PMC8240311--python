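"""Library metrics: nested expectations, precision/coverage, weighted variants."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fraglib.core import Fragment, FragmentLibrary, FragmentResidue
from fraglib.geometry import all_pairs
from fraglib.metrics import (
    acc_ss,
    coverage,
    err_angle,
    err_distance,
    evaluate_library,
    fragment_rmsd,
    fragment_ss_class,
    precision,
    weighted_metrics,
)
from fraglib.potentials import fragment_weights
from fraglib.synthetic import LibrarySpec, make_toy_native, sample_fragment_library


def verbatim_library(native, length=7):
    """Library whose fragments are exact copies of the native windows."""
    lib = FragmentLibrary(target_length=len(native))
    for pos in range(1, len(native) - length + 2):
        lib.add(native.extract_fragment(pos, length))
    return lib


# --- independent brute-force oracle -----------------------------------------

def oracle_nested_metric(lib, per_fragment_error):
    """Plain double loop over positions then fragments; NaN-aware."""
    pos_means = []
    for pos in sorted(lib.positions):
        vals = []
        for frag in lib.positions[pos]:
            v = per_fragment_error(frag)
            if v == v:  # not NaN
                vals.append(v)
        if vals:
            pos_means.append(sum(vals) / len(vals))
    return sum(pos_means) / len(pos_means)


def oracle_angle_error(frag, native, which):
    total, n = 0.0, 0
    for j, r in enumerate(frag.residues):
        a = r.angle(which)
        b = native.window_angles(frag.start_pos, len(frag), which)[j]
        if a == a and b == b:
            d = abs(a - b)
            total += min(d, 360.0 - d)
            n += 1
    return total / n if n else float("nan")


def oracle_distance_error(frag, native, atom):
    coords_f = frag.atom_array(atom)
    coords_n = native.window_atoms(frag.start_pos, len(frag), atom)
    total, n = 0.0, 0
    for i in range(len(frag)):
        for j in range(i + 1, len(frag)):
            df = np.linalg.norm(coords_f[i] - coords_f[j])
            dn = np.linalg.norm(coords_n[i] - coords_n[j])
            total += abs(df - dn)
            n += 1
    return total / n if n else float("nan")


class TestFragmentRmsd:
    def test_verbatim_fragment_is_zero(self, mixed_native):
        frag = mixed_native.extract_fragment(3, 7)
        assert fragment_rmsd(frag, mixed_native) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_removed(self, mixed_native):
        frag = mixed_native.extract_fragment(3, 7)
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True)
        for r in frag.residues:
            r.coords = {a: R.apply(v) + np.array([5.0, -3.0, 2.0])
                        for a, v in r.coords.items()}
        assert fragment_rmsd(frag, mixed_native) == pytest.approx(0.0, abs=1e-9)

    def test_matches_orientation_search_oracle(self, mixed_native, rng):
        frag = mixed_native.extract_fragment(2, 5)
        for r in frag.residues:
            r.coords = {a: v + rng.normal(0, 0.4, 3) for a, v in r.coords.items()}
        A = mixed_native.window_atoms(2, 5, "CA") - mixed_native.window_atoms(2, 5, "CA").mean(0)
        B = frag.atom_array("CA") - frag.atom_array("CA").mean(0)

        def cost(rv):
            return np.sqrt(np.mean(np.sum((A - Rotation.from_rotvec(rv).apply(B)) ** 2, axis=1)))

        rs = np.random.RandomState(0)
        best = min(minimize(cost, Rotation.random(random_state=rs).as_rotvec(),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000}).fun
                   for _ in range(200))
        assert fragment_rmsd(frag, mixed_native) == pytest.approx(best, abs=1e-6)


class TestPrecisionCoverage:
    def test_perfect_library(self, mixed_native):
        lib = verbatim_library(mixed_native)
        for c in (0.1, 1.0, 2.0):
            assert precision(lib, mixed_native, c) == 1.0
            assert coverage(lib, mixed_native, c) == 1.0

    def test_precision_matches_enumeration(self, mixed_native, small_library):
        lib, truth = small_library
        cutoff = float(np.median(truth.true_rmsd))
        expected = (truth.true_rmsd < cutoff).mean()
        assert precision(lib, mixed_native, cutoff) == pytest.approx(expected, abs=1e-9)

    def test_coverage_partial_span(self):
        native = make_toy_native([("H", 14)], seed=0)
        lib = FragmentLibrary(target_length=14)
        lib.add(native.extract_fragment(1, 7))
        assert coverage(lib, native, 0.5) == pytest.approx(0.5)

    def test_no_good_fragments(self, mixed_native, small_library):
        lib, truth = small_library
        tiny = float(truth.true_rmsd.min()) * 0.5
        if tiny == 0:
            tiny = 1e-6
        assert coverage(lib, mixed_native, tiny) == pytest.approx(
            0.0 if (truth.true_rmsd >= tiny).all() else coverage(lib, mixed_native, tiny))

    def test_monotone_in_cutoff(self, mixed_native, small_library):
        lib, _ = small_library
        rep = evaluate_library(lib, mixed_native)
        grid = sorted(rep.precision)
        p = [rep.precision[c] for c in grid]
        cov = [rep.coverage[c] for c in grid]
        assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(cov, cov[1:]))

    def test_empty_library_raises(self, mixed_native):
        with pytest.raises(ValueError):
            precision(FragmentLibrary(target_length=10), mixed_native, 1.0)


class TestFragmentSSClass:
    @pytest.mark.parametrize("letters,expected", [
        ("HHHHCCC", "H"),
        ("HHHEEE", "O"),
        ("EEEEEEE", "E"),
        ("CCCCHHE", "C"),
        ("HEC", "O"),
    ])
    def test_majority_rule(self, letters, expected):
        assert fragment_ss_class(letters) == expected


class TestNestedMetrics:
    def test_perfect_library_fixed_point(self, mixed_native):
        lib = verbatim_library(mixed_native)
        assert acc_ss(lib, mixed_native) == 1.0
        for which in ("phi", "psi", "theta", "tau"):
            assert err_angle(lib, mixed_native, which) == pytest.approx(0.0, abs=1e-9)
        for atom in ("CA", "CB"):
            assert err_distance(lib, mixed_native, atom) == pytest.approx(0.0, abs=1e-9)

    def test_outer_mean_is_over_positions(self):
        """Two positions with different fragment counts: the nested mean
        weights positions equally, unlike a pooled per-fragment mean."""
        native = make_toy_native([("H", 10)], seed=2)
        lib = FragmentLibrary(target_length=10)
        # position 1: one fragment matching the native class (H)
        lib.add(native.extract_fragment(1, 7))
        # position 2: three fragments forced to class E
        for _ in range(3):
            frag = native.extract_fragment(2, 7)
            for r in frag.residues:
                r.ss = "E"
            lib.add(frag)
        assert acc_ss(lib, native) == pytest.approx(0.5)  # (1 + 0) / 2

    def test_wraparound_angle_error(self):
        native = make_toy_native([("E", 6)], seed=4)
        frag = native.extract_fragment(2, 1)
        true_psi = native.angles.psi[1]
        frag.residues[0].psi = ((true_psi + 340.0 + 180.0) % 360.0) - 180.0
        frag.residues[0].phi = np.nan
        frag.residues[0].theta = np.nan
        frag.residues[0].tau = np.nan
        lib = FragmentLibrary(target_length=6)
        lib.add(frag)
        assert err_angle(lib, native, "psi") == pytest.approx(20.0, abs=1e-9)

    def test_single_pair_distance_error(self, mixed_native):
        frag = mixed_native.extract_fragment(2, 2)
        ca = frag.atom_array("CA")
        direction = (ca[1] - ca[0]) / np.linalg.norm(ca[1] - ca[0])
        frag.residues[1].coords["CA"] = ca[1] + 0.2 * direction
        lib = FragmentLibrary(target_length=len(mixed_native))
        lib.add(frag)
        assert err_distance(lib, mixed_native, "CA") == pytest.approx(0.2, abs=1e-9)

    def test_matches_bruteforce_oracle(self, mixed_native, small_library):
        lib, _ = small_library
        for which in ("phi", "psi", "theta", "tau"):
            got = err_angle(lib, mixed_native, which)
            exp = oracle_nested_metric(lib, lambda f: oracle_angle_error(f, mixed_native, which))
            assert got == pytest.approx(exp, abs=1e-9)
        for atom in ("CA", "CB"):
            got = err_distance(lib, mixed_native, atom)
            exp = oracle_nested_metric(lib, lambda f: oracle_distance_error(f, mixed_native, atom))
            assert got == pytest.approx(exp, abs=1e-9)


class TestWeightedMetrics:
    def test_equal_pred_rmsd_reduces_to_unweighted(self, mixed_native, small_library):
        lib, _ = small_library
        for f in lib.iter_fragments():
            f.pred_rmsd = 1.0
        plain = evaluate_library(lib, mixed_native)
        weighted = weighted_metrics(lib, mixed_native)
        assert weighted.err_phi == pytest.approx(plain.err_phi, abs=1e-9)
        assert weighted.acc_ss == pytest.approx(plain.acc_ss, abs=1e-9)
        assert weighted.err_cb_dist == pytest.approx(plain.err_cb_dist, abs=1e-9)

    def test_low_temperature_limit_selects_best(self, mixed_native, small_library):
        lib, _ = small_library
        cold = weighted_metrics(lib, mixed_native, temperature=1e-6)
        # oracle: argmin-pred_rmsd fragment per position (ties share weight)
        def best_frag_metric(which):
            vals = []
            for pos in sorted(lib.positions):
                frags = lib.positions[pos]
                lo = min(f.pred_rmsd for f in frags)
                tied = [oracle_angle_error(f, mixed_native, which)
                        for f in frags if f.pred_rmsd == lo]
                tied = [v for v in tied if v == v]
                if tied:
                    vals.append(float(np.mean(tied)))
            return float(np.mean(vals))
        assert cold.err_phi == pytest.approx(best_frag_metric("phi"), abs=1e-6)

    def test_informative_confidence_improves_errors(self):
        """With pred_rmsd = true RMSD, weighting must not hurt any error metric."""
        native = make_toy_native([("H", 16)], seed=9)
        lib, _ = sample_fragment_library(native, LibrarySpec(
            n_frags_per_pos=8, length_range=(7, 8), angle_noise_sd=12.0,
            pred_rmsd_noise_sd=0.0, seed=9))
        plain = evaluate_library(lib, native)
        weighted = weighted_metrics(lib, native)
        assert weighted.err_phi <= plain.err_phi
        assert weighted.err_psi <= plain.err_psi
        assert weighted.err_ca_dist <= plain.err_ca_dist
        assert weighted.err_cb_dist <= plain.err_cb_dist

    def test_missing_pred_rmsd_raises(self, mixed_native, small_library):
        lib, _ = small_library
        next(lib.iter_fragments()).pred_rmsd = None
        with pytest.raises(ValueError):
            weighted_metrics(lib, mixed_native)
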