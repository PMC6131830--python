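import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_joint
from neuroinfo.discretize import JointDistribution, LagVar, StateSeries, assemble_lagged
from neuroinfo.infocore import (
    conditional_entropy,
    conditional_mutual_information,
    entropy,
    i_min,
    information_gain,
    information_transmission,
    mutual_information,
    pid,
    transfer_entropy,
)


def or_gate_joint():
    """(C1, C2, C3 = C1 OR C2) with independent fair input coins."""
    p = np.zeros((2, 2, 2))
    for c1 in (0, 1):
        for c2 in (0, 1):
            p[c1, c2, c1 | c2] = 0.25
    return JointDistribution(p, names=["c1", "c2", "c3"])


def copy_chain_joint(copies=3):
    """n perfectly linked fair coins."""
    p = np.zeros((2,) * copies)
    p[(0,) * copies] = p[(1,) * copies] = 0.5
    return JointDistribution(p)


class TestEntropy:
    def test_fair_coin_one_bit(self):
        assert entropy(JointDistribution(np.array([0.5, 0.5]))).value == 1.0

    def test_certain_state_zero_bits(self):
        assert entropy(JointDistribution(np.array([1.0]))).value == 0.0

    def test_independent_fair_pair_two_bits(self):
        assert entropy(JointDistribution(np.full((2, 2), 0.25))).value == 2.0

    def test_linked_coins_joint_entropy(self, dependent_coins):
        expected = 0.8 * np.log2(1 / 0.4) + 0.2 * np.log2(1 / 0.1)
        assert entropy(dependent_coins).value == pytest.approx(expected, abs=1e-12)
        assert round(entropy(dependent_coins).value, 1) == 1.7

    def test_skewed_four_state_model(self):
        h = entropy(JointDistribution(np.array([0.95, 0.04, 0.009, 0.001]))).value
        assert round(h, 2) == 0.33

    def test_bounded_by_log_state_count(self, rng):
        for _ in range(20):
            joint = random_joint((4,), rng, sparsity=0.3)
            n_nonzero = int((joint.probabilities > 0).sum())
            assert 0.0 <= entropy(joint).value <= np.log2(n_nonzero) + 1e-12


class TestConditionalEntropy:
    def test_independent_coins(self):
        joint = JointDistribution(np.full((2, 2), 0.25))
        assert conditional_entropy(joint, [0], [1]).value == pytest.approx(1.0)

    def test_linked_coins(self, dependent_coins):
        expected = 0.8 * np.log2(1 / 0.8) + 0.2 * np.log2(1 / 0.2)
        assert conditional_entropy(dependent_coins, [0], [1]).value == pytest.approx(
            expected, abs=1e-12
        )

    def test_identical_variables_zero(self):
        assert conditional_entropy(copy_chain_joint(2), [0], [1]).value == 0.0

    def test_overlap_rejected(self, dependent_coins):
        with pytest.raises(ValueError, match="disjoint"):
            conditional_entropy(dependent_coins, [0], [0])


class TestMutualInformation:
    def test_product_distribution_zero(self):
        joint = JointDistribution(np.outer([0.3, 0.7], [0.6, 0.4]))
        assert mutual_information(joint, [0], [1]).value == pytest.approx(0.0, abs=1e-15)

    def test_identical_fair_coins_maximal(self):
        assert mutual_information(copy_chain_joint(2), [0], [1]).value == 1.0

    def test_strong_association_model(self):
        joint = JointDistribution(np.array([[0.45, 0.05], [0.05, 0.45]]))
        assert round(mutual_information(joint, [0], [1]).value, 2) == 0.53

    def test_vector_valued_side(self, quantity_pid_table):
        # both sources jointly determine the 4-state target exactly
        assert mutual_information(
            quantity_pid_table, [0, 1], [2]
        ).value == pytest.approx(2.0, abs=1e-12)


class TestConditionalMutualInformation:
    def test_three_copies_fully_explained(self):
        assert conditional_mutual_information(
            copy_chain_joint(3), [0], [1], [2]
        ).value == pytest.approx(0.0, abs=1e-12)

    def test_or_gate_induces_dependence(self):
        v = conditional_mutual_information(or_gate_joint(), [0], [1], [2]).value
        assert round(v, 2) == 0.19

    def test_irrelevant_conditioner_equals_plain_mi(self, rng):
        for _ in range(20):
            pxy = rng.dirichlet(np.ones(4)).reshape(2, 2)
            pz = rng.dirichlet(np.ones(2))
            joint = JointDistribution(pxy[:, :, None] * pz[None, None, :])
            cmi = conditional_mutual_information(joint, [0], [1], [2]).value
            mi = mutual_information(joint, [0], [1]).value
            assert cmi == pytest.approx(mi, abs=1e-12)


def _te_table(p_xyz):
    return JointDistribution(p_xyz, names=["Yfuture", "Xpast", "Ypast"])


class TestTransferEntropy:
    def test_independent_streams_zero(self):
        p = np.full((2, 2, 2), 0.125)
        assert transfer_entropy(_te_table(p)).value == pytest.approx(0.0, abs=1e-15)

    def test_source_determines_future_maximal(self):
        # Yfuture copies Xpast; Ypast independent fair
        p = np.zeros((2, 2, 2))
        for x in (0, 1):
            for yp in (0, 1):
                p[x, x, yp] = 0.25
        joint = _te_table(p)
        te = transfer_entropy(joint).value
        h_future = entropy(joint, ["Yfuture"]).value
        assert te == pytest.approx(h_future, abs=1e-12) == 1.0

    def test_self_predictable_receiver_zero(self):
        # Yfuture copies Ypast which also equals Xpast: X adds nothing
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        assert transfer_entropy(_te_table(p)).value == pytest.approx(0.0, abs=1e-12)

    def test_missing_roles_error(self):
        joint = JointDistribution(np.full((2, 2, 2), 0.125))
        with pytest.raises(ValueError, match="role"):
            transfer_entropy(joint)


class TestImin:
    def test_quantity_example_one_bit(self, quantity_pid_table):
        assert i_min(
            quantity_pid_table, [[0], [1]], [2]
        ).value == pytest.approx(1.0, abs=1e-12)

    def test_constant_source_zero(self):
        p = np.zeros((2, 1, 2))
        p[0, 0, 0] = p[1, 0, 1] = 0.5
        joint = JointDistribution(p)
        assert i_min(joint, [[0], [1]], [2]).value == pytest.approx(0.0, abs=1e-15)

    def test_redundant_copies_equal_single_mi(self):
        # X1 = X2 = Y: both sources carry identical information
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        joint = JointDistribution(p)
        imin = i_min(joint, [[0], [1]], [2]).value
        assert imin == pytest.approx(
            mutual_information(joint, [0], [2]).value, abs=1e-12
        )

    def test_three_sources_unsupported(self, rng):
        joint = random_joint((2, 2, 2, 2), rng)
        with pytest.raises(ValueError, match="two sources"):
            i_min(joint, [[0], [1], [2]], [3])

    def test_matches_specific_information_form(self, rng):
        # per-target-state term equals p(y) * KL(p(x|y) || p(x))
        for _ in range(30):
            joint = random_joint((3, 2, 3), rng, sparsity=0.2)
            imin = i_min(joint, [[0], [1]], [2]).value
            assert imin == pytest.approx(
                oracles.imin_oracle(joint.probabilities, [0], [1], [2]), abs=1e-12
            )


class TestPID:
    def test_quantity_example(self, quantity_pid_table):
        res = pid(quantity_pid_table, [[0], [1]], [2])
        assert res.redundancy == pytest.approx(1.0, abs=1e-12)
        assert res.synergy == pytest.approx(1.0, abs=1e-12)
        assert res.unique_1 == pytest.approx(0.0, abs=1e-12)
        assert res.unique_2 == pytest.approx(0.0, abs=1e-12)

    def test_xor_purely_synergistic(self):
        p = np.zeros((2, 2, 2))
        for x1 in (0, 1):
            for x2 in (0, 1):
                p[x1, x2, x1 ^ x2] = 0.25
        res = pid(JointDistribution(p), [[0], [1]], [2])
        assert res.synergy == pytest.approx(1.0, abs=1e-12)
        assert res.redundancy == res.unique_1 == res.unique_2 == 0.0

    def test_single_driver_purely_unique(self):
        # only X1 determines Y; X2 independent fair
        p = np.zeros((2, 2, 2))
        for x1 in (0, 1):
            for x2 in (0, 1):
                p[x1, x2, x1] = 0.25
        res = pid(JointDistribution(p), [[0], [1]], [2])
        assert res.unique_1 == pytest.approx(
            mutual_information(JointDistribution(p), [0], [2]).value, abs=1e-12
        )
        assert res.redundancy == pytest.approx(0.0, abs=1e-12)
        assert res.unique_2 == pytest.approx(0.0, abs=1e-12)
        assert res.synergy == pytest.approx(0.0, abs=1e-12)


def _role_table(p, names):
    return JointDistribution(p, names=names)


class TestInformationGainAndTransmission:
    def test_static_series_gains_nothing(self):
        # Yfuture identical to Ypast: nothing new is acquired
        p = np.zeros((2, 2, 2))  # X, Yfuture, Ypast
        for x in (0, 1):
            for y in (0, 1):
                p[x, y, y] = 0.25
        joint = _role_table(p, ["X", "Yfuture", "Ypast"])
        assert information_gain(joint).value == pytest.approx(0.0, abs=1e-12)

    def test_independent_other_gains_nothing(self, rng):
        px = rng.dirichlet([1, 1])
        pyy = rng.dirichlet(np.ones(4)).reshape(2, 2)
        p = px[:, None, None] * pyy[None, :, :]
        joint = _role_table(p, ["X", "Yfuture", "Ypast"])
        assert information_gain(joint).value == pytest.approx(0.0, abs=1e-12)

    def test_fresh_copy_gains_full_entropy(self):
        # Yfuture = X, Ypast independent: everything is newly gained
        p = np.zeros((2, 2, 2))
        for x in (0, 1):
            for yp in (0, 1):
                p[x, x, yp] = 0.25
        joint = _role_table(p, ["X", "Yfuture", "Ypast"])
        assert information_gain(joint).value == pytest.approx(1.0, abs=1e-12)

    def test_relay_transmits_full_entropy(self):
        # Zfuture = Ypast = X; Zpast independent fair
        p = np.zeros((2, 2, 2, 2))  # X, Ypast, Zfuture, Zpast
        for x in (0, 1):
            for zp in (0, 1):
                p[x, x, x, zp] = 0.25
        joint = _role_table(p, ["X", "Ypast", "Zfuture", "Zpast"])
        assert information_transmission(joint).value == pytest.approx(1.0, abs=1e-12)

    def test_unrelated_source_past_transmits_nothing(self, rng):
        # Ypast independent of everything else
        pxz = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
        py = rng.dirichlet([1, 1])
        p = pxz[:, None, :, :] * py[None, :, None, None]
        joint = _role_table(p, ["X", "Ypast", "Zfuture", "Zpast"])
        assert information_transmission(joint).value == pytest.approx(0.0, abs=1e-12)

    def test_works_from_assembled_series(self, rng):
        x = rng.integers(0, 2, 500)
        series = StateSeries.from_columns([x, np.roll(x, -1)], ["x", "y"])
        assembled = assemble_lagged(
            series,
            {"X": LagVar("x", 1), "Yfuture": LagVar("y", 0), "Ypast": LagVar("y", 1)},
        )
        assert information_gain(assembled).value >= 0.0


SHAPES = [(2, 2), (3, 2), (2, 2, 2), (3, 3, 3), (2, 3, 2, 2)]


class TestAlgebraicInvariants:
    """Identity suite on random tables, checked against brute-force sums."""

    @pytest.mark.parametrize("sparsity", [0.0, 0.3])
    def test_identities_on_random_tables(self, rng, sparsity):
        for shape in SHAPES:
            for _ in range(25):
                joint = random_joint(shape, rng, sparsity)
                p = joint.probabilities
                h = entropy(joint).value
                hx = entropy(joint, [0]).value
                hyz = entropy(joint, list(range(1, p.ndim))).value
                # chain rule
                rest = list(range(1, p.ndim))
                assert h == pytest.approx(
                    hx + conditional_entropy(joint, rest, [0]).value, abs=1e-12
                )
                # MI symmetry and entropy identity
                mi_ab = mutual_information(joint, [0], rest).value
                mi_ba = mutual_information(joint, rest, [0]).value
                assert mi_ab == mi_ba
                assert mi_ab == pytest.approx(hx + hyz - h, abs=1e-12)
                assert mi_ab >= 0.0 and h >= 0.0

    def test_additivity_for_products(self, rng):
        for _ in range(50):
            pa = rng.dirichlet(np.ones(3))
            pb = rng.dirichlet(np.ones(4))
            joint = JointDistribution(np.outer(pa, pb))
            assert entropy(joint).value == pytest.approx(
                entropy(JointDistribution(pa)).value
                + entropy(JointDistribution(pb)).value,
                abs=1e-12,
            )

    def test_pid_bookkeeping(self, rng):
        for _ in range(50):
            joint = random_joint((3, 2, 3), rng, sparsity=0.2)
            res = pid(joint, [[0], [1]], [2])
            assert res.total == pytest.approx(
                res.synergy + res.redundancy + res.unique_1 + res.unique_2, abs=1e-12
            )
            assert res.single_1 == pytest.approx(res.redundancy + res.unique_1, abs=1e-12)
            assert res.single_2 == pytest.approx(res.redundancy + res.unique_2, abs=1e-12)
            for v in (res.synergy, res.redundancy, res.unique_1, res.unique_2):
                assert v >= 0.0
            assert res.redundancy <= min(res.single_1, res.single_2) + 1e-12

    def test_estimators_match_bruteforce(self, rng):
        for _ in range(30):
            joint = random_joint((2, 3, 2, 2), rng, sparsity=0.25)
            p = joint.probabilities
            assert entropy(joint).value == pytest.approx(
                oracles.entropy_oracle(p), abs=1e-12
            )
            assert conditional_entropy(joint, [0, 1], [2, 3]).value == pytest.approx(
                oracles.conditional_entropy_oracle(p, [0, 1], [2, 3]), abs=1e-12
            )
            assert mutual_information(joint, [0, 2], [1, 3]).value == pytest.approx(
                oracles.mi_oracle(p, [0, 2], [1, 3]), abs=1e-12
            )
            assert conditional_mutual_information(
                joint, [0], [1], [2, 3]
            ).value == pytest.approx(oracles.cmi_oracle(p, [0], [1], [2, 3]), abs=1e-12)
            assert i_min(joint, [[0], [1, 3]], [2]).value == pytest.approx(
                oracles.imin_oracle(p, [0], [1, 3], [2]), abs=1e-12
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_hypothesis_random_tables(self, seed):
        r = np.random.default_rng(seed)
        joint = random_joint((2, 2, 2), r, sparsity=0.2)
        p = joint.probabilities
        assert mutual_information(joint, [0], [1]).value == pytest.approx(
            oracles.mi_oracle(p, [0], [1]), abs=1e-12
        )
        s, rr, u1, u2 = oracles.pid_oracle(p, [0], [1], [2])
        res = pid(joint, [[0], [1]], [2])
        assert res.synergy == pytest.approx(s, abs=1e-12)
        assert res.redundancy == pytest.approx(rr, abs=1e-12)


class TestInputValidation:
    def test_broken_distribution_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            JointDistribution(np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="non-negative"):
            JointDistribution(np.array([1.5, -0.5]))

    def test_accepts_state_series_directly(self, rng):
        states = StateSeries.from_columns(
            [rng.integers(0, 2, 100), rng.integers(0, 2, 100)]
        )
        assert mutual_information(states, [0], [1]).value >= 0.0
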