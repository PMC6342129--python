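"""Sampler correctness: likelihoods, full conditionals, and fit contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lesscr import (
    CaptureHistory,
    DetectorArray,
    SpatialDomain,
    psi_individual,
)
from lesscr.model import MCMCState, SCRModel


def _seed_stream(master: int, n: int) -> np.ndarray:
    """Distinct high-quality 31-bit kernel seeds for repeated single updates."""
    return np.random.SeedSequence(master).generate_state(n) % (2**31 - 1) + 1


@pytest.fixture(scope="module")
def augmented_only_model(square_domain20):
    """20 augmented individuals on a 20x20 all-suitable domain; every
    width-10 tile lies fully inside, so prop_habitat = 1 for all."""
    detectors = DetectorArray.grid(5, 5, spacing=4.0, origin=(2.0, 2.0))
    captures = CaptureHistory(y=np.zeros((0, 25), dtype=np.int8))
    model = SCRModel.from_captures(
        captures, detectors, square_domain20, ac_width=10, extension=4, n_layers=5
    )
    assert np.allclose(model.less.prop_habitat, 1.0)
    return model


class TestPsiIndividual:
    def test_limiting_cases_and_value(self):
        assert psi_individual(0.7, 1.0) == pytest.approx(0.7)
        assert psi_individual(0.7, 0.0) == 0.0
        assert psi_individual(0.5, 0.5) == pytest.approx(1 - math.sqrt(0.5))

    def test_range_validation(self):
        with pytest.raises(ValueError):
            psi_individual(1.2, 0.5)
        with pytest.raises(ValueError):
            psi_individual(0.5, -0.1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        psi0=st.floats(0.01, 0.98),
        d_psi=st.floats(0.001, 0.02),
        prop=st.floats(0.01, 0.98),
        d_prop=st.floats(0.001, 0.02),
    )
    def test_monotone_in_both_arguments(self, psi0, d_psi, prop, d_prop):
        base = psi_individual(psi0, prop)
        assert psi_individual(psi0 + d_psi, prop) > base
        assert psi_individual(psi0, prop + d_prop) > base


class TestLoglikIndividual:
    def _one_detector_model(self):
        detectors = DetectorArray(np.array([[0.0, 0.0]]))
        domain = SpatialDomain.around_detectors(detectors, buffer_width=2.0)
        y = np.ones((1, 1), dtype=np.int8)
        return SCRModel.from_captures(
            CaptureHistory(y=y), detectors, domain, ac_width=4, extension=2,
            n_layers=1,
        )

    def test_single_detection_at_distance_zero(self):
        model = self._one_detector_model()
        state = model.initial_state(np.random.default_rng(0), overdisperse=False)
        state.sx[0], state.sy[0] = 0.0, 0.0
        state.p0, state.sigma = 0.07, 2.0
        assert model.loglik_individual(0, state) == pytest.approx(math.log(0.07))

    def test_excluded_individual_contributes_zero(self, augmented_only_model):
        model = augmented_only_model
        state = model.initial_state(np.random.default_rng(1), overdisperse=False)
        state.z[:] = 0
        assert model.loglik_individual(0, state) == 0.0

    def test_detected_with_z_zero_is_a_contract_violation(self):
        model = self._one_detector_model()
        state = model.initial_state(np.random.default_rng(0), overdisperse=False)
        state.z[0] = 0
        with pytest.raises(ValueError, match="z = 1"):
            model.loglik_individual(0, state)

    def test_local_equals_full_likelihood_with_spanning_windows(
        self, design15, dataset15
    ):
        """With windows covering all detectors the local likelihood equals an
        independently computed full-matrix likelihood to 1e-12."""
        detectors, domain = design15
        _, captures = dataset15
        model = SCRModel.from_captures(
            captures, detectors, domain, ac_width=200.0, extension=5.0, n_layers=1
        )
        assert np.all(model.less.n_detectors == detectors.count)
        rng = np.random.default_rng(3)
        state = model.initial_state(rng, overdisperse=False)
        state.sigma, state.p0 = 1.7, 0.09
        # full-likelihood oracle: plain numpy over the complete y matrix
        live = state.z.astype(bool)
        live[: model.n_detected] = True
        s = np.column_stack([state.sx, state.sy])[live]
        y_full = np.zeros((model.m, detectors.count))
        y_full[: model.n_detected] = captures.y
        y_live = y_full[live]
        d2 = (
            (s[:, None, 0] - detectors.x) ** 2 + (s[:, None, 1] - detectors.y) ** 2
        )
        p = state.p0 * np.exp(-d2 / (2 * state.sigma**2))
        oracle = float(
            (y_live * np.log(p) + (1 - y_live) * np.log1p(-p)).sum()
        )
        ours = sum(
            model.loglik_individual(i, state)
            for i in range(model.m)
            if live[np.arange(model.m)][i]
        )
        assert ours == pytest.approx(oracle, abs=1e-12 * max(1, abs(oracle)))


class TestInclusionUpdate:
    def test_conditional_matches_enumeration_oracle(self, augmented_only_model):
        """P(z=1 | rest) agrees with brute-force enumeration over z in {0,1}."""
        model = augmented_only_model
        state = model.initial_state(np.random.default_rng(2), overdisperse=False)
        state.sigma, state.p0, state.psi0 = 2.0, 0.3, 0.45
        i = 0
        state.sx[i], state.sy[i] = 2.5, 3.5  # near two detectors
        dets = model.less.detectors_of(i)
        coords = model.detectors.coordinates[dets]
        d2 = ((coords - [state.sx[i], state.sy[i]]) ** 2).sum(axis=1)
        p = state.p0 * np.exp(-d2 / (2 * state.sigma**2))
        psi = psi_individual(state.psi0, model.less.prop_habitat[i])
        w1 = psi * np.prod(1 - p)  # z=1: must be undetected everywhere
        w0 = (1 - psi) * 1.0  # z=0: detections impossible
        assert model.z_conditional(i, state) == pytest.approx(
            w1 / (w1 + w0), rel=1e-12
        )

    def test_psi_zero_forces_exclusion(self, augmented_only_model):
        model = augmented_only_model
        state = model.initial_state(np.random.default_rng(2), overdisperse=False)
        state.psi0 = 0.0
        assert model.z_conditional(0, state) == 0.0
        for sd in _seed_stream(5, 20):
            model.update_z(state, int(sd))
            assert state.z[model.n_detected :].sum() == 0

    def test_far_ac_gives_conditional_psi(self, augmented_only_model):
        """q = 1 (no detectors in reach) reduces the conditional to psi_i."""
        model = augmented_only_model
        state = model.initial_state(np.random.default_rng(2), overdisperse=False)
        state.sigma, state.p0, state.psi0 = 0.05, 0.3, 0.37
        state.sx[0], state.sy[0] = 0.05, 0.05  # far from any detector at tiny sigma
        assert model.z_conditional(0, state) == pytest.approx(0.37, abs=1e-9)


class TestStationaryDistributions:
    def test_psi0_marginal_matches_conjugate_beta(self, augmented_only_model):
        """With all prop_habitat = 1 and z frozen, repeated psi0 updates must
        sample Beta(1 + sum z, 1 + M - sum z) (KS on 5,000 thinned draws)."""
        model = augmented_only_model
        m = model.m
        z = np.zeros(m, dtype=np.int8)
        z[:8] = 1
        state = MCMCState(
            sx=np.full(m, 5.0), sy=np.full(m, 5.0), z=z,
            sigma=2.0, p0=0.05, psi0=0.4,
        )
        draws = []
        for k, sd in enumerate(_seed_stream(123, 100_000)):
            model.update_psi0(state, int(sd), sd=0.6)
            if k % 20 == 19:
                draws.append(state.psi0)
        ks = stats.kstest(np.array(draws), stats.beta(1 + 8, 1 + m - 8).cdf)
        assert len(draws) == 5000
        assert ks.pvalue > 0.01

    def test_s_uniform_over_window_when_p0_zero(self, square_domain20):
        """A flat likelihood (p0 = 0) must leave the AC marginal uniform over
        its window, and reflection must never move it outside."""
        detectors = DetectorArray.grid(5, 5, spacing=4.0, origin=(2.0, 2.0))
        captures = CaptureHistory(y=np.zeros((0, 25), dtype=np.int8))
        model = SCRModel.from_captures(
            captures, detectors, square_domain20, ac_width=10, extension=4,
            n_layers=1,
        )
        m = model.m
        z = np.zeros(m, dtype=np.int8)
        z[0] = 1
        state = MCMCState(
            sx=np.array([5.0, 15.0, 5.0, 15.0]), sy=np.array([5.0, 5.0, 15.0, 15.0]),
            z=z, sigma=2.0, p0=0.0, psi0=0.4,
        )
        w = model.less.ac_windows[0]
        xs, ys = [], []
        for k, sd in enumerate(_seed_stream(7, 30_000)):
            model.update_s(state, int(sd), sd=4.0)
            assert w.contains(state.sx[0], state.sy[0])
            if k % 10 == 9:
                xs.append(state.sx[0])
                ys.append(state.sy[0])
        assert stats.kstest(np.array(xs), stats.uniform(w.x_lo, w.width).cdf).pvalue > 0.01
        assert stats.kstest(np.array(ys), stats.uniform(w.y_lo, w.width).cdf).pvalue > 0.01

    def test_s_conditional_truncated_gaussian_one_detector_toy(self):
        """sigma, p0, z frozen: the AC conditional of a single individual
        detected once at one detector is a truncated Gaussian centered on
        that detector (KS check)."""
        detectors = DetectorArray(np.array([[0.0, 0.0]]))
        domain = SpatialDomain.around_detectors(detectors, buffer_width=4.0)
        y = np.ones((1, 1), dtype=np.int8)
        model = SCRModel.from_captures(
            CaptureHistory(y=y), detectors, domain, ac_width=6, extension=2,
            n_layers=1,
        )
        state = model.initial_state(np.random.default_rng(0), overdisperse=False)
        state.sigma, state.p0 = 1.5, 0.3
        w = model.less.ac_windows[0]
        xs = []
        for k, sd in enumerate(_seed_stream(11, 40_000)):
            model.update_s(state, int(sd), sd=2.0)
            if k % 10 == 9:
                xs.append(state.sx[0])
        # p(y=1|s) = p0 exp(-d^2/2sig^2) factorizes; x-marginal is a
        # truncated normal on the window
        tn = stats.truncnorm(
            (w.x_lo - 0) / state.sigma, (w.x_hi - 0) / state.sigma,
            loc=0.0, scale=state.sigma,
        )
        assert stats.kstest(np.array(xs), tn.cdf).pvalue > 0.01


@pytest.fixture(scope="module")
def fitted(design15, dataset15):
    detectors, domain = design15
    _, captures = dataset15
    model = SCRModel.from_captures(
        captures, detectors, domain, ac_width=10, extension=4, expected_n=20
    )
    res = model.fit(n_adapt=500, n_iter=1200, n_chains=3, thin=3, seed=77)
    return model, res


class TestFitContracts:
    def test_kept_iterations_and_thinning(self, fitted):
        _, res = fitted
        assert res.n_kept == 1200 // 3
        assert res.sigma.shape == (3, 400)

    def test_abundance_conservation(self, fitted):
        """n_detected <= N <= M at every kept iteration; detected z fixed."""
        model, res = fitted
        assert np.all(res.N >= model.n_detected)
        assert np.all(res.N <= model.m)
        assert np.all(res.z[:, : model.n_detected] == 1)

    def test_scalar_acceptance_in_healthy_range(self, fitted):
        """Post-adaptation Metropolis acceptance for sigma / p0 in [0.2, 0.6]."""
        _, res = fitted
        for acc in res.acceptance:
            assert 0.2 <= acc["sigma"] <= 0.6
            assert 0.2 <= acc["p0"] <= 0.6

    def test_fit_is_deterministic_under_a_seed(self, design15, dataset15):
        detectors, domain = design15
        _, captures = dataset15
        model = SCRModel.from_captures(
            captures, detectors, domain, ac_width=10, extension=4, expected_n=20
        )
        r1 = model.fit(n_adapt=100, n_iter=200, n_chains=2, thin=2, seed=5)
        r2 = model.fit(n_adapt=100, n_iter=200, n_chains=2, thin=2, seed=5)
        np.testing.assert_array_equal(r1.sigma, r2.sigma)
        np.testing.assert_array_equal(r1.N, r2.N)
        np.testing.assert_array_equal(r1.s, r2.s)

    def test_zero_iteration_fit(self, design15, dataset15):
        detectors, domain = design15
        _, captures = dataset15
        model = SCRModel.from_captures(
            captures, detectors, domain, ac_width=10, extension=4, expected_n=20
        )
        res = model.fit(n_adapt=50, n_iter=0, n_chains=2, thin=3, seed=1)
        assert res.n_kept == 0
        assert res.config["n_iter"] == 0
        assert np.isnan(res.summary().loc["sigma", "mean"])

    def test_posterior_summary_table(self, fitted):
        _, res = fitted
        tab = res.summary()
        assert list(tab.index) == ["sigma", "p0", "psi0", "N", "density"]
        assert (tab["ci_lo"] <= tab["mean"]).all() and (tab["mean"] <= tab["ci_hi"]).all()

    def test_unsuitable_window_fails_at_initialization(self):
        detectors = DetectorArray.grid(5, 5)
        hab = np.zeros((9, 9), dtype=bool)
        hab[:, 8:] = True  # suitable habitat only far east of the detections
        domain = SpatialDomain(bounds=(-2.5, 6.5, -2.5, 6.5), habitat=hab)
        y = np.zeros((1, 25), dtype=np.int8)
        y[0, 0] = 1
        model = SCRModel.from_captures(
            CaptureHistory(y=y), detectors, domain, ac_width=2, extension=2,
            n_layers=1,
        )
        with pytest.raises(ValueError, match="no suitable habitat"):
            model.initial_state(np.random.default_rng(0))
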