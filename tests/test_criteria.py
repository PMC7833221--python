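"""Whole-minus-sum criteria: exact values, estimators, surrogates, verdicts."""

import numpy as np
import pytest

from emergence.criteria import delta, evaluate, psi, surrogate_test
from emergence.prob import ArgumentError, ProbabilityTable, SampleMatrix
from emergence.toys import (
    ParitySystemSpec,
    binary_entropy,
    joint_with_feature,
    parity_of_states,
    sample_trajectories,
    state_names,
)

from conftest import random_feature_table


def exact_eval(spec, **kw):
    joint = joint_with_feature(spec)
    past, future = state_names(spec.n)
    return evaluate(
        joint, feature_labels=("v", "v'"), system_labels=(past, future), **kw
    )


def parity_samples(spec, trials, seed):
    sm = sample_trajectories(spec, trials=trials, steps=1, seed=seed)
    par = parity_of_states(sm.values @ (1 << np.arange(spec.n)), spec.n)
    feature = SampleMatrix(par[..., None], cardinalities=(2,))
    return sm, feature


class TestExactCriteria:
    @pytest.mark.parametrize("n", [2, 4, 6])
    @pytest.mark.parametrize("g", [0.6, 0.99])
    def test_example1_decoupled(self, n, g):
        r = exact_eval(ParitySystemSpec(n=n, gamma=g, variant="example1"))
        assert r.psi == pytest.approx(1 - binary_entropy(g), abs=1e-9)
        assert r.delta == pytest.approx(0.0, abs=1e-10)
        assert r.gamma == pytest.approx(0.0, abs=1e-10)
        assert r.verdicts["emergent"] and r.verdicts["decoupled"]
        assert not r.verdicts["downward"]

    def test_example2_downward(self):
        """The determined first bit gives Delta = Gamma = 1 bit; Psi is 0
        because the fresh coins scramble the parity of the next state, so
        the Psi-based emergence verdict is (correctly) inconclusive."""
        r = exact_eval(ParitySystemSpec(n=3, variant="example2"))
        assert r.psi == pytest.approx(0.0, abs=1e-9)
        assert r.delta == pytest.approx(1.0, abs=1e-9)
        assert r.gamma == pytest.approx(1.0, abs=1e-9)
        assert r.verdicts["downward"]
        assert not r.verdicts["emergent"] and not r.verdicts["decoupled"]

    def test_example3_both_modalities(self):
        r = exact_eval(ParitySystemSpec(n=3, gamma=0.9, variant="example3"))
        assert r.psi > 1e-10 and r.delta > 1e-10

    def test_independent_noise_feature(self):
        """A feature independent of the system scores exactly zero."""
        spec = ParitySystemSpec(n=2, gamma=0.9, variant="example1")
        past, future = state_names(2)
        m = joint_with_feature(spec).marginal(past + future).masses
        coin = np.array([0.5, 0.5])
        full = (
            coin[:, None, None, None, None, None]
            * m[None, :, :, None, :, :]
            * coin[None, None, None, :, None, None]
        )
        t = ProbabilityTable(("v",) + past + ("v'",) + future, full, check=False)
        r = evaluate(t, feature_labels=("v", "v'"),
                     system_labels=(past, future))
        assert r.psi == pytest.approx(0.0, abs=1e-10)
        assert not r.verdicts["emergent"]

    def test_copy_dynamics_self_feature_delta(self):
        """V = X^1 in a copy system: the subtracted self-term dominates."""
        m = np.zeros((2,) * 6)
        for a in range(2):
            for b in range(2):
                m[a, a, b, a, a, b] = 0.25
        t = ProbabilityTable(("v", "x1", "x2", "v'", "x1'", "x2'"), m)
        d = delta(t, feature_labels=("v", "v'"),
                  system_labels=(("x1", "x2"), ("x1'", "x2'")))
        assert d <= 1e-10


class TestGeneralisedK:
    def test_psi_non_increasing_in_k(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            t = random_feature_table(rng, 3)
            past = ("x1", "x2", "x3")
            future = ("x1'", "x2'", "x3'")
            kw = dict(feature_labels=("v", "v'"), system_labels=(past, future))
            p1 = psi(t, k=1, **kw)
            p2 = psi(t, k=2, **kw)
            assert p2 <= p1 + 1e-10

    def test_duplicating_a_variable_never_raises_psi(self):
        """Adding an exact copy of one part double-counts its redundancy."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            t2 = random_feature_table(rng, 2)
            base_names = t2.names
            m = t2.masses
            # duplicate x1 (axis 1) and x1' (axis 4) as new trailing axes
            idx = np.indices(m.shape)
            dup = np.zeros(m.shape + (2, 2))
            it = np.nditer(m, flags=["multi_index"])
            for val in it:
                i = it.multi_index
                dup[i + (i[1], i[4])] = val
            names = base_names + ("x9", "x9'")
            t3 = ProbabilityTable(names, dup, check=False)
            p_before = psi(
                t2, feature_labels=("v", "v'"),
                system_labels=(("x1", "x2"), ("x1'", "x2'")),
            )
            p_after = psi(
                t3, feature_labels=("v", "v'"),
                system_labels=(("x1", "x2", "x9"), ("x1'", "x2'", "x9'")),
            )
            assert p_after <= p_before + 1e-10


class TestSampledCriteria:
    def test_converges_to_exact(self):
        """Plug-in and Bayesian Psi at N = 1e5 match the enumerated value
        within 0.02 bits."""
        spec = ParitySystemSpec(n=3, gamma=0.99, variant="example1")
        exact = 1 - binary_entropy(0.99)
        system, feature = parity_samples(spec, trials=100_000, seed=21)
        for est in ("plug_in", "bayesian"):
            val = psi(system, feature, estimator=est)
            assert val == pytest.approx(exact, abs=0.02)

    def test_mixed_kinds_rejected(self):
        spec = ParitySystemSpec(n=2, gamma=0.9, variant="example1")
        system, feature = parity_samples(spec, trials=100, seed=0)
        cont = SampleMatrix(feature.values.astype(float), kind="continuous")
        with pytest.raises(TypeError):
            psi(system, cont)

    def test_estimator_data_mismatch(self):
        spec = ParitySystemSpec(n=2, gamma=0.9, variant="example1")
        system, feature = parity_samples(spec, trials=100, seed=0)
        with pytest.raises(TypeError):
            psi(system, feature, estimator="gaussian")

    def test_group_guard(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(1, 50, 50))
        system = SampleMatrix(vals, cardinalities=(2,) * 50)
        feature = SampleMatrix(vals[:, :, :1].copy(), cardinalities=(2,))
        with pytest.raises(MemoryError):
            psi(system, feature, k=25)


class TestSurrogates:
    def setup_method(self):
        self.spec = ParitySystemSpec(n=4, gamma=0.99, variant="example1")
        sm = sample_trajectories(self.spec, trials=2000, steps=5, seed=1)
        par = parity_of_states(sm.values @ (1 << np.arange(4)), 4)
        self.system = sm
        self.feature = SampleMatrix(par[..., None], cardinalities=(2,))

    def test_null_centred_at_zero(self):
        s = surrogate_test("psi", self.system, self.feature,
                           n_surrogates=30, seed=5)
        assert abs(s.mean) < 0.01
        assert s.observed > s.values.max()

    def test_zero_surrogates_returns_observed(self):
        s = surrogate_test("psi", self.system, self.feature,
                           n_surrogates=0, seed=5)
        assert s.mean == s.observed and s.n_surrogates == 0

    def test_deterministic_under_seed(self):
        a = surrogate_test("gamma", self.system, self.feature,
                           n_surrogates=25, seed=9)
        b = surrogate_test("gamma", self.system, self.feature,
                           n_surrogates=25, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_too_few_surrogates_for_alpha(self):
        with pytest.raises(ArgumentError):
            surrogate_test("psi", self.system, self.feature,
                           n_surrogates=5, seed=0, alpha=0.05)


class TestEvaluateReport:
    def test_sampled_report_fields(self):
        spec = ParitySystemSpec(n=3, gamma=0.99, variant="example1")
        system, feature = parity_samples(spec, trials=3000, seed=2)
        r = evaluate(system, feature, estimator="bayesian",
                     n_surrogates=30, seed=4, alpha=0.05)
        assert r.estimator == "bayesian"
        assert set(r.surrogate_mean) == {"psi", "delta", "gamma"}
        assert r.p_value["psi"] <= 0.05
        assert r.verdicts["emergent"]
        assert r.verdicts["decoupled"]
        assert r.bias_corrected["psi"] == pytest.approx(
            r.psi - r.surrogate_mean["psi"]
        )

    def test_exact_report_has_no_surrogates(self):
        r = exact_eval(ParitySystemSpec(n=2, gamma=0.9, variant="example1"))
        assert r.n_surrogates == 0 and r.surrogate_mean == {}
        assert r.estimator == "exact"
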