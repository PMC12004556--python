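import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsameta import (SimulationSpec, effect_estimates, estimate_tau2,
                     generalized_q, generate_meta_dataset)
from tsameta.tau2 import METHODS

from conftest import make_effects

# External oracle: R metafor 4.8-0 (rma with method=...) run on the
# seeded 12-study fixture (conftest.seeded_records), values frozen here.
METAFOR_TAU2 = {
    "DL": 0.0383613249,
    "REML": 0.0412182946,
    "ML": 0.0300732057,
    "PM": 0.0372599165,
    "SJ": 0.0725654476,
    "HS": 0.0275116515,
}


def profile_loglik(y, v, tau2, restricted):
    """Normal (restricted) log-likelihood profiled over the pooled mean."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    ll = -0.5 * np.sum(np.log(v + tau2)) - 0.5 * np.sum(w * (y - mu) ** 2)
    if restricted:
        ll -= 0.5 * math.log(np.sum(w))
    return ll


def grid_search_tau2(y, v, restricted):
    """Independent oracle: zooming dense-grid maximization of the likelihood."""
    lo, hi = 0.0, max(4.0 * float(np.var(y)), 0.5)
    for _ in range(6):
        grid = np.linspace(lo, hi, 2001)
        lls = [profile_loglik(y, v, t, restricted) for t in grid]
        best = int(np.argmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
    return 0.5 * (lo + hi)


class TestClosedForms:
    """Hand-derivable values on y = (0, 2), v = (1, 1): Q = 2, k = 2."""

    @pytest.mark.parametrize("method, expected",
                             [("DL", 1.0), ("HS", 0.0), ("SJ", 1.0),
                              ("PM", 1.0)])
    def test_two_study_example(self, two_effects, method, expected):
        est = estimate_tau2(two_effects, method)
        assert est.value == pytest.approx(expected, abs=1e-10)
        assert est.converged

    def test_truncation_at_zero_when_homogeneous(self):
        effects = make_effects([0.5, 0.5, 0.5], [1.0, 1.0, 1.0])
        for method in METHODS:
            assert estimate_tau2(effects, method).value == 0.0

    def test_sj_divisor_option(self, two_effects):
        # divisor k gives tau0 = 1; divisor k-1 gives tau0 = 2
        k_div = estimate_tau2(two_effects, "SJ", sj_initial_divisor="k")
        k1_div = estimate_tau2(two_effects, "SJ", sj_initial_divisor="k-1")
        assert k_div.value == pytest.approx(1.0)
        assert k1_div.value != pytest.approx(k_div.value)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            estimate_tau2(make_effects([1.0], [1.0]), "DL")

    def test_unknown_method_rejected(self, two_effects):
        with pytest.raises(ValueError):
            estimate_tau2(two_effects, "EB")


class TestAgainstMetafor:
    @pytest.mark.parametrize("method", METHODS)
    def test_frozen_metafor_values(self, seeded_effects, method):
        est = estimate_tau2(seeded_effects, method)
        assert est.value == pytest.approx(METAFOR_TAU2[method], abs=1e-5)
        assert est.converged


class TestLikelihoodEstimators:
    @pytest.mark.parametrize("method, restricted",
                             [("ML", False), ("REML", True)])
    def test_matches_grid_search_oracle(self, seeded_effects_k20, method,
                                        restricted):
        y = np.array([e.y for e in seeded_effects_k20])
        v = np.array([e.v for e in seeded_effects_k20])
        oracle = grid_search_tau2(y, v, restricted)
        est = estimate_tau2(seeded_effects_k20, method)
        assert est.value == pytest.approx(oracle, abs=1e-6)

    def test_pm_solves_generalized_q_equation(self, seeded_effects):
        k = len(seeded_effects)
        tau2 = estimate_tau2(seeded_effects, "PM").value
        if tau2 > 0:
            assert generalized_q(seeded_effects, tau2) == \
                pytest.approx(k - 1, abs=1e-8)
        else:
            assert generalized_q(seeded_effects, 0.0) <= k - 1


class TestGeneralizedQ:
    def test_equals_cochran_q_at_zero(self, two_effects):
        assert generalized_q(two_effects, 0.0) == pytest.approx(2.0)

    def test_vanishes_in_the_large_tau2_limit(self, two_effects):
        assert generalized_q(two_effects, 1e9) < 1e-6

    def test_monotone_decreasing(self, seeded_effects):
        grid = [0.0, 0.01, 0.05, 0.2, 1.0, 5.0]
        vals = [generalized_q(seeded_effects, t) for t in grid]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestInvariances:
    @given(shift=st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=25, derandomize=True)
    def test_shift_invariance(self, shift):
        y = [0.2, -0.5, 0.9, 0.1, -0.3]
        v = [0.4, 0.9, 0.6, 1.2, 0.5]
        for method in METHODS:
            base = estimate_tau2(make_effects(y, v), method).value
            moved = estimate_tau2(
                make_effects([yi + shift for yi in y], v), method).value
            assert moved == pytest.approx(base, rel=1e-6, abs=1e-9)

    @given(c=st.floats(0.2, 4.0, allow_nan=False))
    @settings(max_examples=25, derandomize=True)
    def test_scale_equivariance(self, c):
        y = [0.2, -0.5, 0.9, 0.1, -0.3]
        v = [0.4, 0.9, 0.6, 1.2, 0.5]
        for method in METHODS:
            base = estimate_tau2(make_effects(y, v), method).value
            scaled = estimate_tau2(
                make_effects([yi * c for yi in y],
                             [vi * c * c for vi in v]), method).value
            assert scaled == pytest.approx(c * c * base, rel=1e-5, abs=1e-9)

    def test_all_estimates_non_negative(self, seeded_effects):
        for method in METHODS:
            assert estimate_tau2(seeded_effects, method).value >= 0.0


def test_sj_overestimates_relative_to_reml_under_homogeneity():
    """With a homogeneous truth (tau2 = 0), the Sidik-Jonkman two-step
    systematically overshoots while REML stays near zero on average."""
    sj_vals, reml_vals = [], []
    for rep in range(1000):
        spec = SimulationSpec(k=10, theta=-0.3, tau2=0.0,
                              p_control=(0.1, 0.3), n_min=50, n_max=200,
                              seed=50_000 + rep)
        effects = [e for e in effect_estimates(generate_meta_dataset(spec))
                   if e.included]
        if len(effects) < 2:
            continue
        sj_vals.append(estimate_tau2(effects, "SJ").value)
        reml_vals.append(estimate_tau2(effects, "REML").value)
    assert np.mean(sj_vals) > np.mean(reml_vals)
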