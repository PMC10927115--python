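import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stdomain import (
    DilatedConvNet,
    TrainConfig,
    continuity_loss,
    high_conf_ce,
    kl_loss,
    lattice_pairs,
    pretrain,
    soft_assign,
    stop_check,
    target_distribution,
    total_loss,
    train,
)
from stdomain.training import init_centroids


class TestSoftAssign:
    def test_equidistant_row_is_uniform(self):
        E = np.array([[0.0, 0.0]])
        mu = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(soft_assign(E, mu), 1.0 / 3.0)

    def test_hand_value(self):
        # spot at centroid 1, centroid 2 at distance 3:
        # q = (1 / (1 + 1/10)) = 10/11
        E = np.array([[0.0, 0.0]])
        mu = np.array([[0.0, 0.0], [3.0, 0.0]])
        Q = soft_assign(E, mu)
        assert Q[0, 0] == pytest.approx(10.0 / 11.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        arrays(np.float64, (6, 3), elements=st.floats(-5, 5)),
        arrays(np.float64, (4, 3), elements=st.floats(-5, 5)),
    )
    def test_rows_sum_to_one(self, E, mu):
        Q = soft_assign(E, mu)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(Q >= 0)


class TestTargetDistribution:
    def test_uniform_stays_uniform(self):
        Q = np.full((5, 4), 0.25)
        np.testing.assert_allclose(target_distribution(Q), 0.25)

    def test_one_hot_fixed_point(self):
        Q = np.eye(3)
        np.testing.assert_allclose(target_distribution(Q), Q)

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(2), size=3)
        P = target_distribution(Q)
        for i in range(3):
            denom = sum(
                Q[i, jp] ** 2 / Q[:, jp].sum() for jp in range(2)
            )
            for j in range(2):
                expected = (Q[i, j] ** 2 / Q[:, j].sum()) / denom
                assert P[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_mass_cluster_errors(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            target_distribution(Q)


class TestKlLoss:
    def test_equal_distributions_give_zero(self):
        P = np.random.default_rng(1).dirichlet(np.ones(4), size=6)
        assert kl_loss(P, P) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_ln2(self):
        P = np.array([[1.0, 0.0]])
        Q = np.array([[0.5, 0.5]])
        assert kl_loss(P, Q) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            P = rng.dirichlet(np.ones(5), size=7)
            Q = rng.dirichlet(np.ones(5), size=7)
            assert kl_loss(P, Q) >= -1e-12


class TestHighConfCe:
    def test_one_hot_gives_zero(self):
        Q = np.eye(4)
        assert high_conf_ce(Q, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_above_cut(self):
        Q = np.array([[0.6, 0.4]])
        assert high_conf_ce(Q, 0.5) == pytest.approx(-np.log(0.6), abs=1e-9)

    def test_cut_zero_includes_every_spot(self):
        Q = np.array([[0.6, 0.4], [0.3, 0.7], [0.45, 0.55]])
        expected = -np.mean(np.log(Q.max(axis=1)))
        assert high_conf_ce(Q, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_no_qualifying_spot_returns_zero(self):
        Q = np.full((3, 4), 0.25)
        assert high_conf_ce(Q, 0.5) == 0.0


class TestContinuityLoss:
    def test_constant_embeddings_give_zero(self):
        spot_index = np.array([[0, 0], [0, 2], [1, 1]])
        po, pd = lattice_pairs(spot_index, "visium")
        E = np.ones((3, 4))
        assert continuity_loss(E, po, pd) == pytest.approx(0.0, abs=1e-5)

    def test_single_diagonal_pair_hand_value(self):
        spot_index = np.array([[0, 0], [1, 1]])
        po, pd = lattice_pairs(spot_index, "visium")
        assert po.shape[0] == 0 and pd.shape[0] == 1  # one undirected pair
        E = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert continuity_loss(E, po, pd, 0.62, 0.58) == pytest.approx(
            0.58 * 2.0, abs=1e-5
        )

    def test_stereo_diagonal_weight_zero(self):
        spot_index = np.array([[0, 0], [1, 1]])
        po, pd = lattice_pairs(spot_index, "stereo")
        E = np.array([[0.0, 0.0], [5.0, 0.0]])
        assert continuity_loss(E, po, pd, 0.62, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_visium_orthogonal_offsets_are_two_apart(self):
        spot_index = np.array([[0, 0], [0, 2], [2, 0]])
        po, _ = lattice_pairs(spot_index, "visium")
        assert po.shape[0] == 2  # (0, 1) along the row, (0, 2) down the column


def test_total_loss_weighted_sum():
    assert total_loss(1.0, 1.0, 1.0) == pytest.approx(2.49)
    assert total_loss(0.0, 0.0, 0.0) == 0.0


class TestStopCheck:
    def test_fewer_unique_labels(self):
        labels = np.array([0, 1, 1, 0, 2, 2])
        assert stop_check(labels, None, n=4) == "fewer_unique_labels_than_n"

    def test_cluster_below_min_fraction(self):
        labels = np.concatenate([np.zeros(991, int), np.ones(9, int)])
        assert stop_check(labels, None, n=2) == "cluster_below_min_fraction"

    def test_label_change_only_on_target_refresh(self):
        labels = np.zeros(2000, int)
        labels[:1000] = 1
        prev = labels.copy()
        prev[0] = 0  # change ratio 1/2000 = 0.0005 < 0.001
        assert stop_check(labels, prev, n=2, p_updated=False) is None
        assert (
            stop_check(labels, prev, n=2, p_updated=True)
            == "label_change_below_tolerance"
        )

    def test_healthy_state_continues(self):
        labels = np.repeat([0, 1, 2], 100)
        prev = np.roll(labels, 30)
        assert stop_check(labels, prev, n=3, p_updated=True) is None


class TestPretrain:
    def test_zero_iterations_leave_params_unchanged(self, small_visium_image):
        img = small_visium_image["img"]
        net = DilatedConvNet("visium", 3, seed=0)
        before = [np.array(l["w"]) for b in net.params for l in b]
        pretrain(net, img, small_visium_image["labels"], max_iter=0)
        after = [np.array(l["w"]) for b in net.params for l in b]
        for x, y in zip(before, after):
            np.testing.assert_array_equal(x, y)

    def test_overfits_easy_pseudo_labels(self, stripe_image, stripe_preprocessed):
        labels = stripe_preprocessed["labels"]
        net = DilatedConvNet("visium", 3, seed=0)
        pretrain(net, stripe_image, labels, max_iter=150)
        E = net.feature_image(stripe_image).E
        assert (np.argmax(E, axis=1) == labels).mean() >= 0.95

    def test_degenerate_labels_stop_early(self, small_visium_image):
        # on a 32-spot image the untrained argmax labels are degenerate,
        # so one of the label-structure rules fires within a few steps
        img = small_visium_image["img"]
        labels = small_visium_image["labels"]
        net = DilatedConvNet("visium", 3, seed=0)
        hist = pretrain(net, img, labels, max_iter=50, min_frac=0.6)
        assert hist["stop_reason"] in (
            "cluster_below_min_fraction",
            "fewer_unique_labels_than_n",
        )
        assert hist["iterations"] < 50

    def test_wrong_label_length_errors(self, small_visium_image):
        net = DilatedConvNet("visium", 3, seed=0)
        with pytest.raises(ValueError):
            pretrain(net, small_visium_image["img"], np.zeros(3, int))


class TestTrain:
    def test_zero_loss_weights_freeze_labels(self, small_visium_image):
        img = small_visium_image["img"]
        labels = small_visium_image["labels"]
        net = DilatedConvNet("visium", 3, seed=0)
        pretrain(net, img, labels, max_iter=60)
        E0 = net.feature_image(img).E
        mu0 = init_centroids(E0, labels, 3)
        expected = np.argmax(np.asarray(soft_assign(E0, mu0)), axis=1)
        cfg = TrainConfig(platform="visium", w_kl=0.0, w_ce=0.0, w_cont=0.0)
        state = train(net, img, labels, cfg)
        np.testing.assert_array_equal(state.C, expected)

    def test_distributions_row_stochastic_and_losses_finite(self, small_visium_image):
        img = small_visium_image["img"]
        labels = small_visium_image["labels"]
        net = DilatedConvNet("visium", 3, seed=1)
        pretrain(net, img, labels, max_iter=60)
        cfg = TrainConfig(platform="visium", max_train=12, label_change_tol=0.0)
        state = train(net, img, labels, cfg)
        np.testing.assert_allclose(state.Q.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(state.P.sum(axis=1), 1.0, atol=1e-6)
        for key in ("L1", "L2", "L3", "Lt"):
            assert np.all(np.isfinite(state.loss_trace[key]))

    def test_kl_term_minimized_when_assignment_matches_target(self):
        # one spot, two centroids: the KL objective in one embedding row is
        # minimized where the soft assignment reproduces the target row
        from scipy.optimize import minimize_scalar

        mu = np.array([[0.0], [3.0]])
        P = np.array([[0.7, 0.3]])

        def objective(e):
            return kl_loss(P, np.asarray(soft_assign(np.array([[e]]), mu)))

        res = minimize_scalar(objective, bounds=(0.0, 3.0), method="bounded")
        Q_star = np.asarray(soft_assign(np.array([[res.x]]), mu))
        np.testing.assert_allclose(Q_star, P, atol=1e-4)
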