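"""Saliency mapping: gradient correctness, input-layer identity, equivariance,
group aggregation, top-percentile extraction, robustness and composition."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_brain_graph, random_graph
from ginfc.gin import GinConfig, GINNetwork
from ginfc.graphs import BrainGraph, one_hot_features
from ginfc.saliency import (
    RobustnessReport,
    SalientRegionSet,
    SaliencyMap,
    cam_baseline,
    grad_cam_input,
    grad_cam_layer,
    group_saliency,
    network_hemisphere_summary,
    robustness_match_ratio,
    top_percentile_regions,
)
from ginfc.synthetic import generate_parcellation


class TestGradCam:
    def test_alpha_matches_finite_differences_all_layers(self, tiny_network, rng):
        """Central finite differences of the target logit w.r.t. the input
        reproduce the analytic channel weights at every layer."""
        g = make_brain_graph(rng, n=6)
        target = 1
        # finite differences are only directly available at the input layer
        step = 1e-4
        n = 6
        num = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                xp, xm = np.eye(n), np.eye(n)
                xp[i, j] += step
                xm[i, j] -= step
                lp, *_ = tiny_network.forward(g.adjacency[None], xp[None])
                lm, *_ = tiny_network.forward(g.adjacency[None], xm[None])
                num[i, j] = (lp.data[0, target] - lm.data[0, target]) / (2 * step)
        analytic = grad_cam_input(tiny_network, g, target).values
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(num.sum(axis=0) - analytic).max() / scale < 1e-4
        # interior layers: saliency well-defined and finite for every k
        for k in range(tiny_network.config.n_layers + 1):
            m = grad_cam_layer(tiny_network, g, k, target)
            assert np.all(np.isfinite(m.values)) and m.values.shape == (n,)

    def test_input_map_equals_layer_zero(self, tiny_network, rng):
        for _ in range(5):
            g = make_brain_graph(rng, n=6)
            for target in (0, 1):
                m0 = grad_cam_input(tiny_network, g, target)
                mk = grad_cam_layer(tiny_network, g, 0, target)
                np.testing.assert_array_equal(m0.values, mk.values)

    def test_zero_head_gives_zero_map(self, rng):
        net = GINNetwork(GinConfig(n_layers=2, hidden_units=4), 5, 5, seed=2)
        net.head_w.data[:] = 0.0
        m = grad_cam_input(net, make_brain_graph(rng, n=5), 0)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_map_linear_in_logit_scale(self, tiny_network, rng):
        g = make_brain_graph(rng, n=6)
        base = grad_cam_input(tiny_network, g, 1).values
        saved = tiny_network.head_w.data.copy()
        try:
            tiny_network.head_w.data = saved * 3.0
            scaled = grad_cam_input(tiny_network, g, 1).values
        finally:
            tiny_network.head_w.data = saved
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-10)

    def test_permutation_equivariance(self, tiny_network, rng):
        n = 6
        a = random_graph(rng, n)
        g = BrainGraph(adjacency=a, node_features=one_hot_features(n), label=1)
        base = grad_cam_layer(tiny_network, g, 0, 1).values
        for _ in range(5):
            perm = rng.permutation(n)
            p = np.eye(n)[perm]
            gp = BrainGraph(adjacency=p @ a @ p.T, node_features=p, label=1)
            permuted = grad_cam_layer(tiny_network, gp, 0, 1).values
            np.testing.assert_allclose(permuted, p @ base, atol=1e-9)

    def test_non_one_hot_rejected_by_input_form(self, tiny_network, rng):
        g = BrainGraph(adjacency=random_graph(rng, 6),
                       node_features=np.ones((6, 6)), label=0)
        with pytest.raises(ValueError, match="one-hot"):
            grad_cam_input(tiny_network, g, 0)

    def test_layer_out_of_range(self, tiny_network, rng):
        with pytest.raises(ValueError):
            grad_cam_layer(tiny_network, make_brain_graph(rng, n=6), 7, 0)


@pytest.fixture(scope="module")
def cam_network():
    return GINNetwork(
        GinConfig(n_layers=2, hidden_units=8, readout_mode="mean_last",
                  dropout_rate=0.0),
        in_features=6, n_nodes=6, seed=4,
    )


class TestCamBaseline:
    def test_requires_mean_pooling_head(self, tiny_network, rng):
        with pytest.raises(ValueError, match="mean_last"):
            cam_baseline(tiny_network, make_brain_graph(rng, n=6), 0)

    def test_zero_head_zero_map(self, cam_network, rng):
        cam_network.head_w.data[:] = 0.0
        m = cam_baseline(cam_network, make_brain_graph(rng, n=6), 1)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_matches_hand_evaluation(self, cam_network, rng):
        prng = np.random.default_rng(10)
        cam_network.head_w.data = prng.standard_normal(cam_network.head_w.data.shape)
        g = make_brain_graph(rng, n=6)
        _, feats, _ = cam_network.forward(g.adjacency[None], g.node_features[None])
        last = feats[-1].data[0]
        expected = last @ cam_network.head_w.data[:, 1]
        np.testing.assert_allclose(cam_baseline(cam_network, g, 1).values, expected)


class TestGroupSaliency:
    def test_single_map_normalized_to_unit_range(self):
        m = SaliencyMap(np.array([2.0, -1.0, 4.0]), 0, 1)
        gm = group_saliency([m])
        assert gm.values.min() == 0.0 and gm.values.max() == 1.0
        assert gm.normalized

    def test_two_identical_maps(self):
        m = SaliencyMap(np.array([0.0, 1.0, 3.0]), 0, 0)
        gm = group_saliency([m, m])
        np.testing.assert_allclose(gm.values, [0.0, 1.0 / 3.0, 1.0])

    def test_listed_four_vectors_direct_arithmetic(self):
        m1 = SaliencyMap(np.array([1.0, 3.0, 5.0, 7.0]), 0, 1)
        m2 = SaliencyMap(np.array([3.0, 1.0, 7.0, 5.0]), 0, 1)
        gm = group_saliency([m1, m2])
        # means: [2,2,6,6] → normalized [0,0,1,1]
        np.testing.assert_allclose(gm.values, [0.0, 0.0, 1.0, 1.0])

    def test_class_filter(self):
        m0 = SaliencyMap(np.array([0.0, 1.0]), 0, 0)
        m1 = SaliencyMap(np.array([1.0, 0.0]), 0, 1)
        gm = group_saliency([m0, m1], class_filter=1)
        np.testing.assert_allclose(gm.values, [1.0, 0.0])

    def test_constant_map_normalizes_to_zeros_with_warning(self):
        m = SaliencyMap(np.full(4, 2.5), 0, 0)
        with pytest.warns(UserWarning, match="constant"):
            gm = group_saliency([m])
        np.testing.assert_array_equal(gm.values, 0.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            group_saliency([], class_filter=0)


class TestTopPercentile:
    def test_400_regions_at_5th_percentile_gives_20(self):
        gm = SaliencyMap(np.linspace(0, 1, 400), 0, 0, normalized=True)
        rs = top_percentile_regions(gm, percentile=5.0)
        assert len(rs.region_indices) == 20

    def test_20_regions_gives_1(self):
        gm = SaliencyMap(np.arange(20.0), 0, 0)
        rs = top_percentile_regions(gm, percentile=5.0)
        assert len(rs.region_indices) == 1
        assert rs.region_indices[0] == 19

    def test_tie_break_by_region_index(self):
        values = np.array([0.5, 0.9, 0.9, 0.9, 0.1, 0.9])
        gm = SaliencyMap(values, 0, 0)
        rs = top_percentile_regions(gm, percentile=50.0)  # floor(0.5*6)=3
        # four regions tie at 0.9; lowest indices win
        np.testing.assert_array_equal(sorted(rs.region_indices), [1, 2, 3])

    def test_metadata_join(self):
        parc = generate_parcellation(10, seed=0)
        gm = SaliencyMap(np.arange(10.0), 0, 0)
        rs = top_percentile_regions(gm, parc, percentile=20.0)
        assert list(rs.table["label"]) == list(parc.iloc[[9, 8]]["label"])


class TestRobustness:
    def _set(self, idx):
        idx = np.asarray(idx)
        return SalientRegionSet(idx, np.zeros(len(idx)), 5.0)

    def test_identical_sets_100(self):
        full = self._set(range(20))
        rep = robustness_match_ratio(full, [self._set(range(20))])
        assert rep.mean == 100.0

    def test_disjoint_sets_0(self):
        rep = robustness_match_ratio(self._set(range(20)),
                                     [self._set(range(20, 40))])
        assert rep.mean == 0.0

    def test_13_of_20_overlap(self):
        full = self._set(range(20))
        sub = self._set(list(range(13)) + list(range(100, 107)))
        rep = robustness_match_ratio(full, [sub])
        assert rep.mean == pytest.approx(65.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            robustness_match_ratio(self._set(range(20)), [self._set(range(10))])


class TestNetworkHemisphereSummary:
    def test_all_left(self):
        parc = generate_parcellation(20, seed=1)
        rs = SalientRegionSet(np.arange(5), np.zeros(5), 5.0)  # first half is L
        frac = network_hemisphere_summary(rs, parc)
        assert frac["hemisphere"] == {"L": 1.0}

    def test_13_7_hemisphere_split(self):
        parc = generate_parcellation(40, seed=1)  # 20 L then 20 R
        idx = np.concatenate([np.arange(13), 20 + np.arange(7)])
        rs = SalientRegionSet(idx, np.zeros(20), 5.0)
        frac = network_hemisphere_summary(rs, parc)
        assert frac["hemisphere"]["L"] == pytest.approx(0.65)
        assert frac["hemisphere"]["R"] == pytest.approx(0.35)

    def test_network_fractions_by_counting(self):
        parc = pd.DataFrame({
            "label": [f"r{i}" for i in range(4)],
            "hemisphere": ["L", "L", "R", "R"],
            "network": ["DMN", "DMN", "SMN", "VN"],
            "R": 0.0, "A": 0.0, "S": 0.0,
        }, index=pd.Index(range(4), name="region_id"))
        rs = SalientRegionSet(np.arange(4), np.zeros(4), 100.0)
        frac = network_hemisphere_summary(rs, parc)
        assert frac["network"] == {"DMN": 0.5, "SMN": 0.25, "VN": 0.25}
        assert sum(frac["network"].values()) == pytest.approx(1.0)
        assert sum(frac["hemisphere"].values()) == pytest.approx(1.0)

    def test_unknown_region_rejected(self):
        parc = generate_parcellation(5, seed=0)
        rs = SalientRegionSet(np.array([99]), np.zeros(1), 5.0)
        with pytest.raises(ValueError):
            network_hemisphere_summary(rs, parc)
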