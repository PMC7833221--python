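"""Redundancy lattice, PID/two-series atoms, synergy and unique-information
indices under the minimum-MI redundancy."""

import numpy as np
import pytest

from emergence.decomposition import (
    antichain_below,
    antichain_lattice,
    d_k,
    format_antichain,
    g_k,
    phiid_mmi,
    pid_mmi,
    syn_k,
    syn_k_lattice,
    un_feature_mmi,
    un_mmi,
)
from emergence.info import mutual_information
from emergence.prob import ArgumentError, ProbabilityTable
from emergence.toys import (
    ParitySystemSpec,
    binary_entropy,
    joint_with_feature,
    state_names,
)

from conftest import random_feature_table, random_kernel_table

TOP2 = frozenset({frozenset({1, 2})})
BOT2 = frozenset({frozenset({1}), frozenset({2})})
A1 = frozenset({frozenset({1})})
A2 = frozenset({frozenset({2})})


class TestLattice:
    def test_sizes(self):
        assert len(antichain_lattice(1)) == 1
        assert len(antichain_lattice(2)) == 4
        assert len(antichain_lattice(3)) == 18

    def test_n2_order(self):
        order = [format_antichain(a) for a in antichain_lattice(2)]
        assert order == ["{1}{2}", "{1}", "{2}", "{12}"]

    def test_topological(self):
        order = antichain_lattice(3)
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                assert not (antichain_below(b, a) and b != a)

    def test_resource_guard(self):
        with pytest.raises(MemoryError):
            antichain_lattice(4)


class TestPid:
    def test_xor_is_pure_synergy(self, xor_table):
        atoms = pid_mmi(xor_table, ["x1", "x2"], "y")
        assert atoms[TOP2] == pytest.approx(1.0, abs=1e-12)
        for key in (BOT2, A1, A2):
            assert atoms[key] == pytest.approx(0.0, abs=1e-12)
        assert atoms.check_conservation()

    def test_duplicated_source_is_pure_redundancy(self):
        m = np.zeros((2, 2, 2))
        m[0, 0, 0] = m[1, 1, 1] = 0.5
        t = ProbabilityTable(("x1", "x2", "y"), m)
        atoms = pid_mmi(t, ["x1", "x2"], "y")
        assert atoms[BOT2] == pytest.approx(1.0, abs=1e-12)
        assert atoms[TOP2] == pytest.approx(0.0, abs=1e-12)

    def test_independent_target_all_zero(self):
        rng = np.random.default_rng(0)
        xy = rng.dirichlet(np.ones(4)).reshape(2, 2)
        m = xy[:, :, None] * np.array([0.5, 0.5])[None, None, :]
        t = ProbabilityTable(("x1", "x2", "y"), m)
        atoms = pid_mmi(t, ["x1", "x2"], "y")
        for v in atoms.atoms.values():
            assert v == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_random_three_sources(self, seed):
        rng = np.random.default_rng(seed)
        masses = rng.dirichlet(np.ones(16)).reshape(2, 2, 2, 2)
        t = ProbabilityTable(("a", "b", "c", "y"), masses, check=False)
        atoms = pid_mmi(t, ["a", "b", "c"], "y")
        assert atoms.check_conservation()


class TestSynK:
    def test_example1_parity_target(self):
        g = 0.9
        j = joint_with_feature(ParitySystemSpec(n=3, gamma=g, variant="example1"))
        past, _ = state_names(3)
        assert syn_k(j, past, "v'", 1) == pytest.approx(
            1 - binary_entropy(g), abs=1e-10
        )

    def test_copy_system_no_single_bit_synergy_about_one_bit(self):
        """X' = X with independent bits: one future bit is fully carried by
        its own past bit, so synergy about it vanishes."""
        m = np.zeros((2, 2, 2))
        for a in range(2):
            for b in range(2):
                m[a, b, a] = 0.25
        t = ProbabilityTable(("x1", "x2", "y"), m)
        assert syn_k(t, ["x1", "x2"], "y", 1) == pytest.approx(0.0, abs=1e-12)

    def test_partition_bound(self, xor_table):
        total = mutual_information(xor_table, ("x1", "x2"), "y")
        assert syn_k(xor_table, ["x1", "x2"], "y", 1) <= total + 1e-12

    @pytest.mark.parametrize("seed", range(15))
    def test_closed_form_equals_lattice(self, seed):
        """The MMI shortcut I(X;Y) - max_{|a|=k} I(X^a;Y) equals the
        Moebius-summed atoms over the high-order antichains."""
        rng = np.random.default_rng(seed)
        n = 2 + seed % 2
        masses = rng.dirichlet(np.ones(2 ** (n + 1))).reshape((2,) * (n + 1))
        names = tuple(f"x{i}" for i in range(n)) + ("y",)
        t = ProbabilityTable(names, masses, check=False)
        for k in range(1, n):
            closed = syn_k(t, names[:-1], "y", k)
            lattice = syn_k_lattice(t, names[:-1], "y", k)
            assert closed == pytest.approx(lattice, abs=1e-9)

    def test_bad_k(self, xor_table):
        with pytest.raises(ArgumentError):
            syn_k(xor_table, ["x1", "x2"], "y", 2)


class TestUnMmi:
    def test_example1_parity_emergent(self):
        g = 0.99
        j = joint_with_feature(ParitySystemSpec(n=3, gamma=g, variant="example1"))
        past, future = state_names(3)
        assert un_mmi(j, "v", past, future, 1) == pytest.approx(
            1 - binary_entropy(g), abs=1e-10
        )

    def test_single_variable_feature_never_emergent(self):
        """A function of one part cannot beat the best single part."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = random_kernel_table(rng, 2)
            past, future = ("x1", "x2"), ("x1'", "x2'")
            # feature = x1 itself (the identity is the hardest case)
            val = (
                mutual_information(t, "x1", future)
                - max(
                    mutual_information(t, "x1", future),
                    mutual_information(t, "x2", future),
                )
            )
            assert val <= 1e-12

    def test_constant_feature(self):
        j = joint_with_feature(ParitySystemSpec(n=2, gamma=0.8, variant="example1"))
        past, future = state_names(2)
        # constant feature: use a fresh table where v is constant 0
        m = j.marginal(past + future).masses
        full = np.zeros((1,) + m.shape[:2] + (1,) + m.shape[2:])
        full[0, ..., 0, :, :] = m.reshape(full.shape[1:3] + full.shape[4:])
        t = ProbabilityTable(("v",) + past + ("v'",) + future, full, check=False)
        assert un_mmi(t, "v", past, future, 1) <= 0.0 + 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_corollary_bound_random_features(self, seed):
        """Unique information of any supervenient feature never exceeds the
        system's synergy capacity (both under MMI)."""
        rng = np.random.default_rng(100 + seed)
        n = 2 + seed % 2
        t = random_feature_table(rng, n)
        past = tuple(f"x{i + 1}" for i in range(n))
        future = tuple(f"x{i + 1}'" for i in range(n))
        un = un_mmi(t, "v", past, future, 1)
        syn = syn_k(t, past, future, 1)
        assert un <= syn + 1e-9

    def test_copy_system_counterexample_documented(self):
        """Known MMI limitation: in a pure copy system the parity feature
        has Psi = 1 bit while the X'-target unique-information closed form
        is 0 — a part's self-prediction masks the feature's distinct
        content.  The V'-target form keeps the bound."""
        from emergence.criteria import psi

        par = np.array([1, 0, 0, 1])
        fk = np.zeros((4, 2))
        fk[np.arange(4), par] = 1.0
        base = np.eye(4) / 4
        j4 = (
            base[None, :, None, :]
            * fk.T[:, :, None, None]
            * fk.T[None, None, :, :]
        ).reshape((2, 2, 2, 2, 2, 2), order="F")
        t = ProbabilityTable(("v", "x1", "x2", "v'", "x1'", "x2'"), j4,
                             check=False)
        past, future = ("x1", "x2"), ("x1'", "x2'")
        p = psi(t, feature_labels=("v", "v'"), system_labels=(past, future))
        assert p == pytest.approx(1.0, abs=1e-10)
        assert un_mmi(t, "v", past, future, 1) == pytest.approx(0.0, abs=1e-10)
        assert un_feature_mmi(t, "v", past, "v'", 1) >= p - 1e-9


class TestPhiid:
    def test_synergy_to_unique_atom(self):
        """X1' = X1 xor X2 with a fresh coin for X2': all information sits
        in the synergistic-cause / unique-effect atom."""
        m = np.zeros((2, 2, 2, 2))
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    m[a, b, a ^ b, c] = 0.125
        t = ProbabilityTable(("x1", "x2", "y1", "y2"), m)
        atoms = phiid_mmi(t, ["x1", "x2"], ["y1", "y2"])
        assert atoms[(TOP2, A1)] == pytest.approx(1.0, abs=1e-12)
        assert atoms.total == pytest.approx(1.0, abs=1e-12)
        assert atoms.check_conservation()

    def test_all_copies_is_double_redundancy(self):
        m = np.zeros((2, 2, 2, 2))
        m[0, 0, 0, 0] = m[1, 1, 1, 1] = 0.5
        t = ProbabilityTable(("x1", "x2", "y1", "y2"), m)
        atoms = phiid_mmi(t, ["x1", "x2"], ["y1", "y2"])
        assert atoms[(BOT2, BOT2)] == pytest.approx(1.0, abs=1e-12)
        others = sum(
            abs(v) for k, v in atoms.atoms.items() if k != (BOT2, BOT2)
        )
        assert others == pytest.approx(0.0, abs=1e-10)

    def test_independent_times_all_zero(self):
        rng = np.random.default_rng(1)
        a = rng.dirichlet(np.ones(4)).reshape(2, 2)
        b = rng.dirichlet(np.ones(4)).reshape(2, 2)
        t = ProbabilityTable(
            ("x1", "x2", "y1", "y2"), a[:, :, None, None] * b[None, None, :, :],
            check=False,
        )
        atoms = phiid_mmi(t, ["x1", "x2"], ["y1", "y2"])
        for v in atoms.atoms.values():
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_scope_error(self, xor_table):
        with pytest.raises(ArgumentError):
            phiid_mmi(xor_table, ["x1"], ["x2", "y"])


class TestDownwardDecouplingIndices:
    def test_example2_is_downward_causation(self):
        j = joint_with_feature(ParitySystemSpec(n=2, variant="example2"))
        past, future = state_names(2)
        atoms = phiid_mmi(j.marginal(past + future), past, future)
        assert d_k(atoms) == pytest.approx(1.0, abs=1e-9)
        assert g_k(atoms) == pytest.approx(0.0, abs=1e-9)

    def test_example1_is_causal_decoupling(self):
        g = 0.99
        j = joint_with_feature(ParitySystemSpec(n=2, gamma=g, variant="example1"))
        past, future = state_names(2)
        atoms = phiid_mmi(j.marginal(past + future), past, future)
        assert g_k(atoms) == pytest.approx(1 - binary_entropy(g), abs=1e-9)
        assert d_k(atoms) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_additivity(self, seed):
        """Syn(1) = D(1) + G(1) exactly, for random two-bit kernels."""
        rng = np.random.default_rng(200 + seed)
        t = random_kernel_table(rng, 2, concentration=rng.uniform(0.2, 3))
        atoms = phiid_mmi(t, ["x1", "x2"], ["x1'", "x2'"])
        syn = syn_k(t, ["x1", "x2"], ("x1'", "x2'"), 1)
        assert d_k(atoms) + g_k(atoms) == pytest.approx(syn, abs=1e-9)
        assert atoms.check_conservation()
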