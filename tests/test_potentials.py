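"""Smoothing, confidence weights, weighted EM, BIC and NLL potentials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fraglib.core import Fragment, FragmentLibrary, FragmentResidue
from fraglib.potentials import (
    PAIRS_2D,
    WGMMComponent,
    WGMMModel,
    build_position_potentials,
    combined_potential,
    fit_weighted_gmm,
    fragment_weights,
    load_potentials,
    nll_potential_1d,
    nll_potential_2d,
    save_potentials,
    select_n_components,
    smooth_library,
    wgmm_bic,
)
from fraglib.synthetic import LibrarySpec, make_toy_native, sample_fragment_library


def make_fragment(pos, n, pred_rmsd=1.0):
    residues = [FragmentResidue(aa="A", ss="H", phi=-57.0, psi=-47.0, omega=180.0)
                for _ in range(n)]
    return Fragment(start_pos=pos, residues=residues, pred_rmsd=pred_rmsd)


class TestSmoothing:
    def test_nine_residue_parent_gives_three_windows(self):
        lib = FragmentLibrary(target_length=20)
        lib.add(make_fragment(4, 9))
        sm = smooth_library(lib)
        assert sm.n_fragments() == 3
        assert sorted(sm.positions) == [4, 5, 6]
        assert all(len(f) == 7 for fr in sm.positions.values() for f in fr)

    def test_window_length_parent_maps_to_itself(self):
        lib = FragmentLibrary(target_length=10)
        lib.add(make_fragment(2, 7))
        sm = smooth_library(lib)
        assert sm.n_fragments() == 1
        assert len(sm.positions[2][0]) == 7

    def test_short_parent_dropped_and_counted(self):
        lib = FragmentLibrary(target_length=10)
        lib.add(make_fragment(1, 6))
        sm = smooth_library(lib)
        assert sm.n_fragments() == 0
        assert sm.n_dropped == 1

    def test_subfragments_keep_parent_metadata(self):
        lib = FragmentLibrary(target_length=20)
        lib.add(Fragment(start_pos=3, residues=make_fragment(3, 9).residues,
                         pred_rmsd=0.7, source_id="1abc_A"))
        sm = smooth_library(lib)
        for frags in sm.positions.values():
            for f in frags:
                assert f.pred_rmsd == 0.7
                assert f.source_id == "1abc_A"


class TestFragmentWeights:
    def test_equal_scores_are_uniform(self):
        assert np.allclose(fragment_weights([0.8, 0.8]), [0.5, 0.5])

    def test_sum_to_one(self, rng):
        w = fragment_weights(rng.uniform(0, 5, 40))
        assert abs(w.sum() - 1.0) < 1e-12

    def test_shift_invariance(self, rng):
        r = rng.uniform(0, 3, 10)
        assert np.allclose(fragment_weights(r), fragment_weights(r + 2.5), atol=1e-12)

    def test_hand_computed_two_fragment_case(self):
        w = fragment_weights([1.0, 2.0], temperature=0.1)
        z = math.exp(10.0)
        assert w[0] == pytest.approx(z / (z + 1.0), rel=1e-12)
        assert w[1] == pytest.approx(1.0 / (z + 1.0), rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_limits(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0, 5, 8)
        hot = fragment_weights(r, temperature=1e9)
        assert np.allclose(hot, 1.0 / len(r), atol=1e-6)
        cold = fragment_weights(r, temperature=1e-9)
        winners = np.flatnonzero(r == r.min())
        assert cold[winners].sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_pred_rmsd_raises(self):
        with pytest.raises(ValueError):
            fragment_weights([1.0, None])


class TestWeightedEM:
    def test_uniform_weights_match_sklearn(self, rng):
        from sklearn.mixture import GaussianMixture
        x = np.concatenate([rng.normal(-60, 5, 400), rng.normal(60, 5, 400)])
        model, _ = fit_weighted_gmm(x, K=2, return_history=True)
        # same init as ours: weighted-quantile means, pooled variance, uniform mixing
        mu0 = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
        gm = GaussianMixture(n_components=2, means_init=mu0.reshape(-1, 1),
                             weights_init=[0.5, 0.5],
                             precisions_init=1.0 / np.var(x) * np.ones((2, 1, 1)),
                             tol=1e-10, max_iter=1000, reg_covar=0.0)
        gm.fit(x.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        for k, comp in enumerate(model.components):
            assert comp.mean == pytest.approx(gm.means_.ravel()[order][k], abs=1e-4)
            assert comp.variance == pytest.approx(
                gm.covariances_.ravel()[order][k], rel=1e-3)
            assert comp.weight == pytest.approx(gm.weights_[order][k], abs=1e-5)

    def test_duplication_equals_split_weight(self, rng):
        # splitting one sample into two copies with half its weight each
        # must not change the fit (weights act as multiplicities)
        x = rng.normal(0, 10, 60)
        w = rng.uniform(0.5, 2.0, 60)
        x_dup = np.concatenate([x, x[:1]])
        w_half = np.concatenate([w, [w[0] / 2]])
        w_half[0] = w[0] / 2
        m1 = fit_weighted_gmm(x, w, K=3)
        m2 = fit_weighted_gmm(x_dup, w_half, K=3)
        for c1, c2 in zip(m1.components, m2.components):
            assert c2.mean == pytest.approx(c1.mean, abs=1e-9)
            assert c2.variance == pytest.approx(c1.variance, abs=1e-9)
            assert c2.weight == pytest.approx(c1.weight, abs=1e-9)

    def test_integer_weights_equal_sample_duplication(self, rng):
        x = rng.normal(0, 10, 40)
        mult = rng.integers(1, 4, 40)
        x_dup = np.repeat(x, mult)
        m_w = fit_weighted_gmm(x, mult.astype(float), K=3)
        m_d = fit_weighted_gmm(x_dup, K=3)
        for c1, c2 in zip(m_w.components, m_d.components):
            assert c2.mean == pytest.approx(c1.mean, abs=1e-9)
            assert c2.variance == pytest.approx(c1.variance, abs=1e-9)
            assert c2.weight == pytest.approx(c1.weight, abs=1e-9)

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-60, 5, 1000), rng.normal(60, 5, 1000)])
        model = fit_weighted_gmm(x, K=2)
        means = sorted(c.mean for c in model.components)
        assert means[0] == pytest.approx(-60.0, abs=1.0)
        assert means[1] == pytest.approx(60.0, abs=1.0)

    def test_loglik_nondecreasing_each_iteration(self, rng):
        x = np.concatenate([rng.normal(-40, 8, 150), rng.normal(30, 4, 100)])
        w = rng.uniform(0.1, 1.0, 250)
        _, history = fit_weighted_gmm(x, w, K=4, return_history=True)
        diffs = np.diff(history)
        assert (diffs >= -1e-8).all()

    def test_identical_samples_collapse_to_single_component(self):
        model = fit_weighted_gmm(np.full(50, 3.3), K=4)
        assert model.K == 1
        assert model.components[0].mean == pytest.approx(3.3)

    def test_k_reduced_for_tiny_samples(self):
        model = fit_weighted_gmm([1.0, 2.0], K=4)
        assert model.K <= 2

    def test_component_densities_integrate_to_one(self, rng):
        x = rng.normal(0, 20, 300)
        model = fit_weighted_gmm(x, rng.uniform(0.1, 1, 300), K=4)
        for c in model.components:
            sd = math.sqrt(c.variance)
            val, _ = quad(lambda y: math.exp(-(y - c.mean) ** 2 / (2 * c.variance))
                          / math.sqrt(2 * math.pi * c.variance),
                          c.mean - 8 * sd, c.mean + 8 * sd)
            assert val == pytest.approx(1.0, abs=1e-6)


class TestBIC:
    def test_scan_recovers_four_modes(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(m, 4, 250) for m in (-120, -40, 40, 120)])
        best, scores = select_n_components(x, k_range=range(2, 11))
        assert best == 4

    def test_empty_duplicate_component_never_lowers_bic(self, rng):
        x = rng.normal(0, 5, 200)
        m1 = fit_weighted_gmm(x, K=1)
        c = m1.components[0]
        m2 = WGMMModel([WGMMComponent(1.0 - 1e-12, c.mean, c.variance),
                        WGMMComponent(1e-12, c.mean + 100, c.variance)])
        assert wgmm_bic(m2, x) >= wgmm_bic(m1, x)

    def test_penalty_monotone_in_parameters(self, rng):
        x = rng.normal(0, 5, 500)
        m1 = fit_weighted_gmm(x, K=1)
        # same component twice with split weight: identical likelihood, more params
        c = m1.components[0]
        m2 = WGMMModel([WGMMComponent(0.5, c.mean, c.variance),
                        WGMMComponent(0.5, c.mean, c.variance)])
        assert wgmm_bic(m2, x) > wgmm_bic(m1, x)


@pytest.fixture(scope="module")
def helix_smoothed():
    native = make_toy_native([("H", 20)], seed=42)
    lib, _ = sample_fragment_library(native, LibrarySpec(
        n_frags_per_pos=10, length_range=(7, 10), angle_noise_sd=5.0,
        pred_rmsd_noise_sd=0.2, seed=42))
    return native, smooth_library(lib)


class TestPositionPotentials:
    def test_full_position_has_seventy_models(self, helix_smoothed):
        _, smoothed = helix_smoothed
        pset = build_position_potentials(smoothed, 5)
        assert pset.n_models() == 70
        for prop in ("phi", "psi", "theta", "tau"):
            assert len(pset.models_for(prop)) == 7
        for prop in ("dCA", "dCB"):
            assert len(pset.models_for(prop)) == 21

    def test_pair_slots_lexicographic(self, helix_smoothed):
        _, smoothed = helix_smoothed
        pset = build_position_potentials(smoothed, 5)
        slots = list(pset.models_for("dCB"))
        assert slots == list(PAIRS_2D)

    def test_no_coords_gives_1d_only(self):
        lib = FragmentLibrary(target_length=10)
        lib.add(make_fragment(2, 8))
        sm = smooth_library(lib)
        pset = build_position_potentials(sm, 2)
        props = {p for (p, _) in pset.models}
        assert props <= {"phi", "psi", "theta", "tau"}
        assert not pset.models_for("dCA")

    def test_empty_position_raises(self, helix_smoothed):
        _, smoothed = helix_smoothed
        with pytest.raises(ValueError):
            build_position_potentials(smoothed, 99)

    def test_serialization_round_trip(self, helix_smoothed, tmp_path):
        _, smoothed = helix_smoothed
        sets = {5: build_position_potentials(smoothed, 5)}
        p = tmp_path / "potentials.json"
        save_potentials(sets, p)
        loaded = load_potentials(p)
        assert loaded[5].n_models() == 70
        m0 = sets[5].models[("phi", 0)]
        m1 = loaded[5].models[("phi", 0)]
        for c0, c1 in zip(m0.components, m1.components):
            assert c1.mean == pytest.approx(c0.mean)
            assert c1.variance == pytest.approx(c0.variance)


class TestNLLPotentials:
    def test_peak_energy_closed_form(self):
        var = 4.0
        model = WGMMModel([WGMMComponent(1.0, -57.0, var)])
        expected = -math.log(1.0 / math.sqrt(2 * math.pi * var))
        assert nll_potential_1d({0: -57.0}, {0: model}) == pytest.approx(expected, abs=1e-9)

    def test_energy_minimized_near_mode(self, helix_smoothed):
        _, smoothed = helix_smoothed
        pset = build_position_potentials(smoothed, 5)
        model = pset.models[("phi", 3)]
        grid = np.linspace(-180, 180, 3601)
        energies = [-float(model.logpdf(g)[0]) for g in grid]
        gmin = grid[int(np.argmin(energies))]
        # the library is helical: the densest mode must sit near -57 deg
        assert abs(gmin - (-57.0)) < 10.0

    def test_monotone_away_from_isolated_mode(self):
        model = WGMMModel([WGMMComponent(1.0, 10.0, 9.0)])
        e = [nll_potential_1d({0: v}, {0: model}) for v in (10.0, 15.0, 25.0, 60.0)]
        assert e[0] < e[1] < e[2] < e[3]

    def test_2d_equals_shared_kernel(self, rng):
        models = {}
        vals = {}
        for (j1, j2) in [(0, 1), (0, 2), (1, 5)]:
            comps = [WGMMComponent(0.4, rng.uniform(4, 9), rng.uniform(0.1, 1.0)),
                     WGMMComponent(0.6, rng.uniform(4, 9), rng.uniform(0.1, 1.0))]
            models[(j1, j2)] = WGMMModel(comps)
            vals[(j1, j2)] = rng.uniform(3, 10)
        assert nll_potential_2d(vals, models) == pytest.approx(
            nll_potential_1d(vals, models), abs=1e-12)

    def test_sum_matches_independent_oracle(self, rng):
        models = {}
        vals = {}
        expected = 0.0
        for slot in range(5):
            w = rng.dirichlet(np.ones(3))
            mu = rng.uniform(-100, 100, 3)
            var = rng.uniform(0.5, 30.0, 3)
            models[slot] = WGMMModel([WGMMComponent(*t) for t in zip(w, mu, var)])
            v = rng.uniform(-150, 150)
            vals[slot] = v
            dens = sum(wk / math.sqrt(2 * math.pi * vk)
                       * math.exp(-(v - mk) ** 2 / (2 * vk))
                       for wk, mk, vk in zip(w, mu, var))
            expected += -math.log(max(dens, 1e-30))  # same density floor
        assert nll_potential_1d(vals, models) == pytest.approx(expected, abs=1e-9)

    def test_no_overlap_raises(self):
        model = WGMMModel([WGMMComponent(1.0, 0.0, 1.0)])
        with pytest.raises(ValueError):
            nll_potential_1d({3: float("nan")}, {3: model})


class TestCombinedPotential:
    @pytest.fixture()
    def props_and_sets(self, helix_potentials, worked_example):
        native, _, _ = worked_example
        from fraglib.folding import structure_properties
        a = native.angles
        props = structure_properties(a.phi, a.psi, native.backbone["CA"], native.cb)
        return props, helix_potentials

    def test_zero_weights_zero_energy(self, props_and_sets):
        props, sets = props_and_sets
        zero = {p: 0.0 for p in ("phi", "psi", "theta", "tau", "dCA", "dCB")}
        e, _ = combined_potential(props, sets, zero)
        assert e == 0.0

    def test_single_weight_selects_one_term(self, props_and_sets):
        props, sets = props_and_sets
        w = {"phi": 1.0, "psi": 0.0, "theta": 0.0, "tau": 0.0, "dCA": 0.0, "dCB": 0.0}
        e, breakdown = combined_potential(props, sets, w)
        assert e == pytest.approx(breakdown["phi"])

    def test_homogeneous_in_weights(self, props_and_sets):
        props, sets = props_and_sets
        w1 = {p: 1.0 for p in ("phi", "psi", "theta", "tau", "dCA", "dCB")}
        w2 = {p: 2.0 for p in w1}
        e1, _ = combined_potential(props, sets, w1)
        e2, _ = combined_potential(props, sets, w2)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)
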