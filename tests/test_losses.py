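"""Loss family: analytic spot values, oracle agreement, geometric invariances."""

import numpy as np
import pytest

from drmargin import (
    MarginConfig,
    angular_margin_loss,
    combined_loss,
    cross_entropy_loss,
    make_pairing,
    normalize_rows,
    oracle_angular_margin_loss,
    oracle_self_supervised_loss,
    oracle_supcon_loss,
    pairwise_angles,
    partition_anchors,
    self_supervised_loss,
    supcon_loss,
)
from conftest import random_double_view_batch


class TestNormalizeRows:
    def test_three_four_five(self):
        out = normalize_rows(np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(out, [[0.6, 0.8]])

    def test_unit_row_unchanged(self):
        row = np.array([[0.0, 1.0, 0.0]])
        np.testing.assert_allclose(normalize_rows(row), row)

    def test_zero_row_reports_index(self):
        with pytest.raises(ValueError, match="index 1"):
            normalize_rows(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestPartitionAnchors:
    def test_mixed_labels_example(self):
        # 2N=6, pairing i <-> i+3, labels (0,0,1,0,0,1)
        labels = np.array([0, 0, 1, 0, 0, 1])
        part = partition_anchors(make_pairing(3), labels)
        assert set(part.U(0)) == {3}
        assert set(part.V(0)) == {1, 4}
        assert len(part.P(0)) == 3
        assert all(len(part.U(i)) + len(part.V(i)) == len(part.P(i)) for i in range(6))
        assert all(len(part.A(i)) == 5 for i in range(6))

    def test_distinct_labels_degenerate_to_sibling_only(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        part = partition_anchors(make_pairing(3), labels)
        for i in range(6):
            assert part.V(i).size == 0
            assert set(part.P(i)) == {int(part.pairing[i])}

    def test_all_same_label_counts(self):
        part = partition_anchors(make_pairing(2), np.zeros(4, int))
        for i in range(4):
            assert len(part.P(i)) == 3 and len(part.V(i)) == 2

    def test_label_mismatch_within_pair_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            partition_anchors(make_pairing(2), np.array([0, 1, 1, 1]))

    def test_non_involution_rejected(self):
        with pytest.raises(ValueError, match="involution"):
            partition_anchors(np.array([1, 2, 3, 0]), np.zeros(4, int))


class TestPairwiseAngles:
    def test_known_angles(self):
        z = np.array([[1, 0], [0, 1], [0.5, np.sqrt(3) / 2]])
        theta = pairwise_angles(z)
        assert theta[0, 0] == 0.0
        np.testing.assert_allclose(theta[0, 1], np.pi / 2, atol=1e-6)
        np.testing.assert_allclose(theta[0, 2], np.pi / 3, atol=1e-6)
        np.testing.assert_allclose(theta, theta.T)

    def test_non_unit_rows_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            pairwise_angles(np.array([[2.0, 0.0], [0.0, 1.0]]))


class TestSpotValues:
    """Closed-form values for the all-identical 2N=4 batch and a hand case."""

    def test_identical_batch_gives_log3(self, margin_cfg):
        z = normalize_rows(np.ones((4, 8)))
        labels = np.zeros(4, int)
        pair = make_pairing(2)
        assert self_supervised_loss(z, pair, 0.7).total == pytest.approx(np.log(3), abs=1e-9)
        assert supcon_loss(z, pair, labels, 0.05).total == pytest.approx(np.log(3), abs=1e-9)

    def test_identical_batch_angular_margin_closed_form(self, margin_cfg):
        z = normalize_rows(np.ones((4, 8)))
        loss = angular_margin_loss(z, make_pairing(2), np.zeros(4, int), margin_cfg)
        delta = (np.cos(0.1) - np.cos(0.2)) / 0.05
        expected = (np.log(1 + 2 * np.exp(delta)) + 2 * np.log(2 + np.exp(-delta))) / 3
        # the arccos clamp moves theta from 0 to ~4.5e-4 rad; effect ~6e-5
        assert loss.total == pytest.approx(expected, abs=1e-4)
        assert loss.total == pytest.approx(1.1082, abs=5e-4)

    def test_single_positive_two_antipodal_negatives(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        pairing = np.array([1, 0, 3, 2])
        loss = self_supervised_loss(z, pairing, 1.0)
        # positives at angle ~0, negatives at ~pi: -log(e / (e + 2/e))
        assert loss.per_anchor[0] == pytest.approx(np.log(1 + 2 * np.exp(-2)), abs=1e-5)


class TestOracleAgreement:
    def test_vectorized_equals_oracles_on_random_batches(self, margin_cfg):
        rng = np.random.default_rng(42)
        for _ in range(50):
            z, labels, pairing = random_double_view_batch(rng)
            tau = float(rng.uniform(0.05, 1.0))
            cfg = MarginConfig(m_u=0.2, m_v=0.1, tau=tau)
            assert self_supervised_loss(z, pairing, tau).total == pytest.approx(
                oracle_self_supervised_loss(z, pairing, tau).total, abs=1e-5
            )
            assert supcon_loss(z, pairing, labels, tau).total == pytest.approx(
                oracle_supcon_loss(z, pairing, labels, tau).total, abs=1e-5
            )
            assert angular_margin_loss(z, pairing, labels, cfg).total == pytest.approx(
                oracle_angular_margin_loss(z, pairing, labels, cfg).total, abs=1e-5
            )

    def test_zero_margins_reduce_to_supcon(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            z, labels, pairing = random_double_view_batch(rng)
            cfg = MarginConfig(m_u=0.0, m_v=0.0, tau=0.1)
            am = angular_margin_loss(z, pairing, labels, cfg)
            sc = supcon_loss(z, pairing, labels, 0.1)
            assert am.total == pytest.approx(sc.total, abs=1e-6)

    def test_distinct_labels_reduce_supcon_to_self(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            z, _, pairing = random_double_view_batch(rng, n_sources=n)
            labels = np.concatenate([np.arange(n)] * 2)
            sc = supcon_loss(z, pairing, labels, 0.2)
            ss = self_supervised_loss(z, pairing, 0.2)
            np.testing.assert_allclose(sc.per_anchor, ss.per_anchor, atol=1e-10)


class TestInvariances:
    def test_per_anchor_terms_nonnegative_and_finite(self, margin_cfg):
        rng = np.random.default_rng(3)
        for _ in range(30):
            z, labels, pairing = random_double_view_batch(rng)
            for lb in (
                self_supervised_loss(z, pairing, 0.1),
                supcon_loss(z, pairing, labels, 0.1),
                angular_margin_loss(z, pairing, labels, margin_cfg),
            ):
                assert np.all(np.isfinite(lb.per_anchor))
                assert np.all(lb.per_anchor >= -1e-12)
                assert lb.total == pytest.approx(np.mean(lb.per_anchor))

    def test_permutation_invariance(self, margin_cfg):
        rng = np.random.default_rng(11)
        for _ in range(10):
            z, labels, pairing = random_double_view_batch(rng)
            perm = rng.permutation(len(labels))
            inv = np.argsort(perm)
            z2, labels2 = z[inv], labels[inv]
            pairing2 = np.empty_like(pairing)
            pairing2[perm] = perm[pairing]  # conjugated involution
            before = angular_margin_loss(z, pairing, labels, margin_cfg).total
            after = angular_margin_loss(z2, pairing2, labels2, margin_cfg).total
            assert after == pytest.approx(before, abs=1e-6)

    def test_rotation_invariance(self, margin_cfg):
        rng = np.random.default_rng(12)
        for _ in range(10):
            z, labels, pairing = random_double_view_batch(rng, dim=8)
            q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
            zr = z @ q
            assert self_supervised_loss(zr, pairing, 0.3).total == pytest.approx(
                self_supervised_loss(z, pairing, 0.3).total, abs=1e-6
            )
            assert supcon_loss(zr, pairing, labels, 0.3).total == pytest.approx(
                supcon_loss(z, pairing, labels, 0.3).total, abs=1e-6
            )
            assert angular_margin_loss(zr, pairing, labels, margin_cfg).total == pytest.approx(
                angular_margin_loss(z, pairing, labels, margin_cfg).total, abs=1e-6
            )

    def test_margin_monotonicity_single_positive(self):
        # anchors in a tight cone: all pairwise angles well below pi - 0.5
        rng = np.random.default_rng(13)
        n = 4
        base = np.zeros((2 * n, 6))
        base[:, 0] = 1.0
        z = normalize_rows(base + 0.3 * rng.normal(size=base.shape))
        assert pairwise_angles(z).max() < np.pi - 0.5
        labels = np.concatenate([np.arange(n)] * 2)  # only positive is j(i)
        pairing = make_pairing(n)
        totals = [
            angular_margin_loss(z, pairing, labels, MarginConfig(m_u=m, m_v=0.0, tau=0.1)).total
            for m in np.arange(0.0, 0.51, 0.1)
        ]
        assert np.all(np.diff(totals) > 0)


class TestCrossEntropyAndCombination:
    def test_binary_values(self):
        assert cross_entropy_loss(np.array([1.0]), np.array([1])).total == 0.0
        assert cross_entropy_loss(np.array([0.5]), np.array([1])).total == pytest.approx(np.log(2))

    def test_multiclass_uniform(self):
        probs = np.full((3, 5), 0.2)
        labels = np.array([0, 2, 4])
        assert cross_entropy_loss(probs, labels).total == pytest.approx(np.log(5))

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cross_entropy_loss(np.array([1.2]), np.array([1]))
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy_loss(np.array([[0.5, 0.2]]), np.array([0]))

    @pytest.mark.parametrize(
        "lam, ce, am, expected", [(0.0, 0.5, 1.0, 0.5), (1.0, 0.5, 1.0, 1.5), (2.0, 0.25, 0.5, 1.25)]
    )
    def test_combined_arithmetic(self, lam, ce, am, expected):
        from drmargin.losses import LossBreakdown

        ce_b = LossBreakdown(ce, np.array([ce]), "cross_entropy")
        am_b = LossBreakdown(am, np.array([am]), "angular_margin")
        assert combined_loss(ce_b, am_b, lam).total == pytest.approx(expected)

    def test_negative_weight_rejected(self):
        from drmargin.losses import LossBreakdown

        b = LossBreakdown(1.0, np.array([1.0]), "cross_entropy")
        with pytest.raises(ValueError):
            combined_loss(b, b, -0.5)


class TestValidation:
    def test_nonpositive_temperature_rejected(self):
        z = normalize_rows(np.ones((4, 3)))
        with pytest.raises(ValueError, match="temperature"):
            self_supervised_loss(z, make_pairing(2), 0.0)
        with pytest.raises(ValueError, match="temperature"):
            MarginConfig(tau=-1.0)

    def test_negative_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            MarginConfig(m_u=-0.1)
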