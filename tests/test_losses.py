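"""Mutual-learning loss components against hand/closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ofml import (
    ConfigurationError,
    DataError,
    assemble_bundle,
    branch_total,
    cross_entropy,
    global_total,
    kl_divergence,
    soften,
)
from ofml.autodiff import Tensor
from ofml.losses import LossBundle


class TestSoften:
    def test_equal_logits_are_uniform(self):
        for t in (0.5, 1.0, 4.0):
            np.testing.assert_allclose(soften(np.array([0.0, 0.0]), t).data, [0.5, 0.5], atol=1e-7)

    def test_closed_form_softmax(self):
        out = soften(np.array([math.log(2.0), 0.0]), 1.0).data
        np.testing.assert_allclose(out, [2 / 3, 1 / 3], atol=1e-6)

    def test_high_temperature_limit_is_uniform(self):
        out = soften(np.array([5.0, -5.0]), 1000.0).data
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-2)

    def test_temperature_softening_is_monotone_toward_uniform(self):
        """KL from uniform shrinks monotonically as T grows."""
        logits = np.array([2.0, 0.5, -1.0, 0.0])
        uniform = np.full(4, 0.25)
        divergences = [
            float(kl_divergence(soften(logits, t).data, uniform).data)
            for t in (1.0, 2.0, 4.0, 8.0, 16.0)
        ]
        assert all(a > b for a, b in zip(divergences, divergences[1:]))

    @pytest.mark.parametrize("t", [0.0, -1.0])
    def test_nonpositive_temperature_rejected(self, t):
        with pytest.raises(ConfigurationError):
            soften(np.zeros(3), t)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert float(cross_entropy(np.array([1.0, 0.0]), np.array([0])).data) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_log_m(self):
        loss = float(cross_entropy(np.full((1, 4), 0.25), np.array([2])).data)
        assert loss == pytest.approx(math.log(4), abs=1e-6)

    def test_soft_label_generalization(self):
        """-sum y log p on a two-class toy, by hand."""
        p = np.array([[0.8, 0.2]])
        y = np.array([[0.5, 0.5]])
        expected = -(0.5 * math.log(0.8) + 0.5 * math.log(0.2))
        assert float(cross_entropy(p, y).data) == pytest.approx(expected, abs=1e-6)

    def test_zero_probability_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            loss = float(cross_entropy(np.array([[0.0, 1.0]]), np.array([0])).data)
        assert np.isfinite(loss)
        assert loss > 20  # -log(1e-12)


class TestKL:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.3, 0.7])
        assert float(kl_divergence(p, p).data) == pytest.approx(0.0, abs=1e-7)

    def test_hand_computed_value(self):
        expected = 0.5 * math.log(2.0) + 0.5 * math.log(2.0 / 3.0)
        got = float(kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75])).data)
        assert got == pytest.approx(expected, abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_on_random_simplex_pairs(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(5))
        q = r.dirichlet(np.ones(5))
        assert float(kl_divergence(p, q).data) >= -1e-7

    def test_nan_input_is_data_error(self):
        with pytest.raises(DataError):
            kl_divergence(np.array([np.nan, 1.0]), np.array([0.5, 0.5]))


def _oracle_branch_total(logits_b, y, logits_f, T):
    """Float64 re-derivation of the per-branch loss triple."""

    def softmax(z, t):
        z = np.asarray(z, dtype=np.float64) / t
        e = np.exp(z - z.max())
        return e / e.sum()

    p1 = softmax(logits_b, 1.0)
    l_net = -math.log(p1[y])
    pT = softmax(logits_b, T)
    qT = softmax(logits_f, T)
    l_fpkt = float((pT * np.log(pT / qT)).sum())
    return l_net, l_fpkt, l_net + T * T * l_fpkt


class TestBranchTotal:
    def test_identical_branch_and_fusion_logits_have_zero_transfer(self):
        logits = Tensor(np.array([[1.0, -0.5]]))
        l_net, l_fpkt, total = branch_total(logits, np.array([0]), logits, 4.0)
        assert float(l_fpkt.data) == pytest.approx(0.0, abs=1e-7)
        assert float(total.data) == pytest.approx(float(l_net.data), abs=1e-6)

    def test_temperature_squared_multiplier(self):
        b = Tensor(np.array([[0.2, -0.1]]))
        f = Tensor(np.array([[1.0, 0.3]]))
        l_net, l_fpkt, total = branch_total(b, np.array([1]), f, 4.0)
        assert float(total.data) == pytest.approx(float(l_net.data) + 16.0 * float(l_fpkt.data), rel=1e-6)

    @pytest.mark.parametrize("y", [0, 1])
    def test_matches_float64_oracle(self, y):
        logits_b = np.array([0.7, -1.3])
        logits_f = np.array([-0.4, 0.9])
        l_net, l_fpkt, total = branch_total(
            Tensor(logits_b[None]), np.array([y]), Tensor(logits_f[None]), 4.0
        )
        exp_net, exp_fpkt, exp_total = _oracle_branch_total(logits_b, y, logits_f, 4.0)
        assert float(l_net.data) == pytest.approx(exp_net, abs=1e-6)
        assert float(l_fpkt.data) == pytest.approx(exp_fpkt, abs=1e-6)
        assert float(total.data) == pytest.approx(exp_total, abs=1e-5)

    def test_fusion_teacher_is_detached(self):
        """FPKT must not push gradients into the fusion classifier."""
        fusion = Tensor(np.array([[1.0, -1.0]]), requires_grad=True)
        branch = Tensor(np.array([[0.3, 0.2]]), requires_grad=True)
        _, l_fpkt, _ = branch_total(branch, np.array([0]), fusion, 4.0)
        l_fpkt.backward()
        assert fusion.grad is None
        assert branch.grad is not None


class TestGlobalTotal:
    def test_all_zero_components_sum_to_zero(self):
        zero = Tensor(np.zeros(()))
        bundle = LossBundle(L1=zero, L2=zero, L_ensemble=zero)
        assert float(global_total(bundle, 4.0).data) == 0.0

    def test_literal_three_term_total(self):
        bundle = LossBundle(
            L1=Tensor(np.array(1.0)),
            L2=Tensor(np.array(2.0)),
            L_ensemble=Tensor(np.array(0.5)),
            L_EPKT=Tensor(np.array(9.0)),
            L_fusion_ce=Tensor(np.array(9.0)),
        )
        total = global_total(bundle, 4.0, w_epkt=0.0, w_fusion_ce=0.0)
        assert float(total.data) == pytest.approx(1 + 2 + 16 * 0.5, rel=1e-6)

    def test_auxiliary_terms_enter_with_weights(self):
        bundle = LossBundle(
            L1=Tensor(np.array(1.0)),
            L2=Tensor(np.array(1.0)),
            L_ensemble=Tensor(np.array(0.0)),
            L_EPKT=Tensor(np.array(0.25)),
            L_fusion_ce=Tensor(np.array(0.5)),
        )
        total = global_total(bundle, 2.0, w_epkt=2.0, w_fusion_ce=1.0)
        assert float(total.data) == pytest.approx(1 + 1 + 0 + 0.5 + 0.5, rel=1e-6)


class TestAssembleBundle:
    def test_all_components_present_for_full_heads(self, rng):
        out = assemble_bundle(
            np.array([0, 1]),
            4.0,
            logits1=Tensor(rng.normal(size=(2, 3)).astype(np.float32)),
            logits2=Tensor(rng.normal(size=(2, 3)).astype(np.float32)),
            fusion_logits=Tensor(rng.normal(size=(2, 3)).astype(np.float32)),
            ensemble=Tensor(rng.normal(size=(2, 3)).astype(np.float32)),
        )
        values = out.to_floats()
        expected_keys = {
            "L_net1", "L_FPKT1", "L1", "L_net2", "L_FPKT2", "L2",
            "L_ensemble", "L_EPKT", "L_fusion_ce", "L_f",
        }
        assert set(values) == expected_keys
        assert all(v >= -1e-7 for v in values.values())

    def test_total_decomposition_identity(self, rng):
        """L1 = L_net1 + T^2 L_FPKT1 and the global sum both hold exactly."""
        T = 4.0
        out = assemble_bundle(
            np.array([1]),
            T,
            logits1=Tensor(rng.normal(size=(1, 4)).astype(np.float32)),
            logits2=Tensor(rng.normal(size=(1, 4)).astype(np.float32)),
            fusion_logits=Tensor(rng.normal(size=(1, 4)).astype(np.float32)),
            ensemble=Tensor(rng.normal(size=(1, 4)).astype(np.float32)),
        )
        v = out.to_floats()
        assert v["L1"] == pytest.approx(v["L_net1"] + T**2 * v["L_FPKT1"], rel=1e-5)
        assert v["L2"] == pytest.approx(v["L_net2"] + T**2 * v["L_FPKT2"], rel=1e-5)
        assert v["L_f"] == pytest.approx(
            v["L1"] + v["L2"] + T**2 * v["L_ensemble"] + v["L_EPKT"] + v["L_fusion_ce"], rel=1e-5
        )

    def test_branch_only_bundle_is_plain_cross_entropy(self, rng):
        logits = Tensor(rng.normal(size=(2, 3)).astype(np.float32))
        out = assemble_bundle(np.array([0, 2]), 4.0, logits1=logits)
        v = out.to_floats()
        assert set(v) == {"L_net1", "L1", "L_f"}
        assert v["L1"] == pytest.approx(v["L_net1"])
        assert v["L_f"] == pytest.approx(v["L1"])

    def test_gradient_reaches_all_heads_through_total(self, rng):
        l1 = Tensor(rng.normal(size=(1, 3)).astype(np.float32), requires_grad=True)
        l2 = Tensor(rng.normal(size=(1, 3)).astype(np.float32), requires_grad=True)
        lf = Tensor(rng.normal(size=(1, 3)).astype(np.float32), requires_grad=True)
        from ofml import ensemble_logits

        bundle = assemble_bundle(
            np.array([1]), 4.0, logits1=l1, logits2=l2,
            fusion_logits=lf, ensemble=ensemble_logits(l1, l2),
        )
        bundle.L_f.backward()
        for name, t in {"branch1": l1, "branch2": l2, "fusion": lf}.items():
            assert t.grad is not None and np.abs(t.grad).sum() > 0, name
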