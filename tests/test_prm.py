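"""Peak stimulation and random-walk back-propagation against explicit
transition-matrix oracles."""

import numpy as np
import pytest

from plaqseg3d import prm as P
from plaqseg3d.nn import tape
from plaqseg3d.nn.functional import conv_out_shape
from plaqseg3d.nn.tape import Parameter, Tensor


class TestFindPeaks:
    def test_constant_map_has_no_strict_maxima(self):
        assert P.find_peaks(np.full((5, 5, 5), 0.7), min_score=0.0) == []

    def test_single_spike(self):
        m = np.zeros((5, 5, 5))
        m[2, 3, 1] = 1.0
        peaks = P.find_peaks(m, min_score=0.5)
        assert len(peaks) == 1 and peaks[0].location == (2, 3, 1)

    def test_equal_spikes_sorted_lexicographically(self):
        m = np.zeros((7, 7, 7))
        m[5, 5, 5] = 0.9
        m[1, 2, 3] = 0.9
        peaks = P.find_peaks(m, min_score=0.5)
        assert [p.location for p in peaks] == [(1, 2, 3), (5, 5, 5)]

    def test_min_score_filters(self):
        m = np.zeros((5, 5, 5))
        m[1, 1, 1] = 0.4
        m[3, 3, 3] = 0.8
        peaks = P.find_peaks(m, min_score=0.5)
        assert [p.location for p in peaks] == [(3, 3, 3)]

    def test_channelled_map_reports_channel(self):
        m = np.zeros((2, 5, 5, 5))
        m[1, 2, 2, 2] = 1.0
        peaks = P.find_peaks(m, min_score=0.5)
        assert peaks[0].channel == 1


class TestTransitionProbabilities:
    def test_single_tap_identity(self):
        layer = P.TransitionKernel(weights=np.ones((1,)), activations=np.ones((1,)))
        assert P.transition_probabilities(layer, (0,)) == {(0,): 1.0}

    def test_hand_evaluated_1d_filter(self):
        # W = (-1, 2, 2) over activations (1, 1, 3): products (0, 2, 6),
        # normaliser 1/8 -> probabilities (0, 0.25, 0.75)
        layer = P.TransitionKernel(weights=np.array([-1.0, 2.0, 2.0]),
                                   activations=np.array([1.0, 1.0, 3.0]))
        probs = P.transition_probabilities(layer, (0,))
        assert probs[(1,)] == pytest.approx(0.25)
        assert probs[(2,)] == pytest.approx(0.75)
        assert (0,) not in probs

    def test_all_negative_weights_absorb(self):
        layer = P.TransitionKernel(weights=-np.ones((3,)),
                                   activations=np.ones((3,)))
        assert P.transition_probabilities(layer, (0,)) == {}

    def test_probabilities_sum_to_one(self, rng):
        layer = P.TransitionKernel(weights=rng.normal(size=(3, 3, 3)),
                                   activations=rng.random((6, 6, 6)),
                                   stride=1, pad=1)
        probs = P.transition_probabilities(layer, (2, 3, 4))
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


def transition_matrix_oracle(xdata, W, stride, pad):
    """Explicit (outputs x inputs) transition matrix, naive loops."""
    co, ci, k = W.shape[0], W.shape[1], W.shape[2]
    xs = xdata.shape[1:]
    os_ = conv_out_shape(xs, k, stride, pad)
    T = np.zeros((co * int(np.prod(os_)), ci * int(np.prod(xs))))
    Wp = np.maximum(W.astype(np.float64), 0)
    xp = np.maximum(xdata.astype(np.float64), 0)
    for oc in range(co):
        for oz in range(os_[0]):
            for oy in range(os_[1]):
                for ox in range(os_[2]):
                    probs = {}
                    for ic in range(ci):
                        for dz in range(k):
                            for dy in range(k):
                                for dx in range(k):
                                    iz = oz * stride - pad + dz
                                    iy = oy * stride - pad + dy
                                    ix = ox * stride - pad + dx
                                    if not (0 <= iz < xs[0] and 0 <= iy < xs[1]
                                            and 0 <= ix < xs[2]):
                                        continue
                                    p = xp[ic, iz, iy, ix] * Wp[oc, ic, dz, dy, dx]
                                    if p > 0:
                                        key = (ic, iz, iy, ix)
                                        probs[key] = probs.get(key, 0.0) + p
                    tot = sum(probs.values())
                    if tot <= 0:
                        continue
                    row = ((oc * os_[0] + oz) * os_[1] + oy) * os_[2] + ox
                    for (ic, iz, iy, ix), p in probs.items():
                        col = ((ic * xs[0] + iz) * xs[1] + iy) * xs[2] + ix
                        T[row, col] = p / tot
    return T


def _toy_net(rng, xs=(4, 5, 4), chans=(1, 2, 2), strides=(1, 1), pads=(1, 1)):
    x = Tensor(rng.random((chans[0], *xs)).astype(np.float32))
    tensors = [x]
    Ws = []
    h = x
    for i in range(len(chans) - 1):
        W = Parameter(rng.normal(size=(chans[i + 1], chans[i], 3, 3, 3))
                      .astype(np.float32))
        Ws.append(W)
        h = tape.conv3d(h, W, None, strides[i], pads[i])
        tensors.append(h)
        if i < len(chans) - 2:
            h = tape.relu(h)
    return x, h, tensors, Ws


class TestBackpropagatePeak:
    def test_identity_conv_gives_delta(self):
        x = Tensor(np.ones((1, 3, 3, 3), np.float32))
        W = Parameter(np.ones((1, 1, 1, 1, 1), np.float32))
        y = tape.conv3d(x, W)
        m = P.backpropagate_peak(y, P.Peak((1, 2, 0), 0, 1.0))
        expect = np.zeros((3, 3, 3))
        expect[1, 2, 0] = 1.0
        np.testing.assert_allclose(m.prob, expect, atol=1e-12)
        assert m.total_mass == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_transition_matrix_product(self, seed):
        rng = np.random.default_rng(seed)
        x, y, tensors, Ws = _toy_net(rng)
        T1 = transition_matrix_oracle(tensors[0].data, Ws[0].data, 1, 1)
        mid = np.maximum(tensors[1].data, 0)  # post-ReLU activations
        T2 = transition_matrix_oracle(mid, Ws[1].data, 1, 1)
        peaks = P.find_peaks(y.data, min_score=-np.inf)[:3]
        for pk in peaks:
            got = P.backpropagate_peak(y, pk)
            n2 = T2.shape[0]
            ind = np.zeros(n2)
            sh = y.data.shape
            ind[((pk.channel * sh[1] + pk.location[0]) * sh[2]
                 + pk.location[1]) * sh[3] + pk.location[2]] = 1.0
            oracle = (ind @ T2) @ T1
            oracle = oracle.reshape(tensors[0].data.shape).sum(axis=0)
            assert np.abs(got.prob - oracle).max() <= 1e-9

    def test_mass_conservation_or_accounted_absorption(self, rng):
        x, y, _, _ = _toy_net(rng, xs=(5, 5, 5), chans=(1, 3, 2))
        for pk in P.find_peaks(y.data, min_score=-np.inf)[:5]:
            m = P.backpropagate_peak(y, pk)
            assert m.prob.min() >= 0
            assert m.total_mass + m.absorbed_mass == pytest.approx(1.0, abs=1e-9)

    def test_support_contained_in_receptive_field(self, rng):
        x, y, _, _ = _toy_net(rng, xs=(8, 8, 8), chans=(1, 2, 1),
                              strides=(2, 1), pads=(1, 1))
        pk = P.find_peaks(y.data, min_score=-np.inf)[0]
        m = P.backpropagate_peak(y, pk)
        rf = tape.receptive_field(y, x, pk.location)
        support = np.argwhere(m.prob > 0)
        if len(support):
            for ax in range(3):
                assert support[:, ax].min() >= rf[ax][0]
                assert support[:, ax].max() <= rf[ax][1]

    def test_mass_splits_proportionally_across_skip_sum(self):
        # y = a + b with positive contributions 1 and 3: mass splits 1/4, 3/4
        a = Tensor(np.full((1, 1, 1, 1), 1.0, np.float32))
        b = Tensor(np.full((1, 1, 1, 1), 3.0, np.float32))
        y = tape.add(a, b)
        leaves, absorbed = P._walk(y, np.ones((1, 1, 1, 1, 1)))
        assert leaves[id(a)][0, 0, 0, 0, 0] == pytest.approx(0.25)
        assert leaves[id(b)][0, 0, 0, 0, 0] == pytest.approx(0.75)
        assert absorbed[0] == 0.0

    def test_batched_walk_equals_individual_walks(self, rng):
        x, y, _, _ = _toy_net(rng, xs=(6, 6, 6), chans=(1, 2, 2))
        peaks = P.find_peaks(y.data, min_score=-np.inf)[:5]
        batched = P.backpropagate_peaks(y, peaks, chunk=3)
        for pk, bm in zip(peaks, batched):
            single = P.backpropagate_peak(y, pk)
            np.testing.assert_allclose(bm.prob, single.prob, atol=1e-12)


class TestPrmForBlock:
    def _trained_stub(self):
        from plaqseg3d.detect3d import DetectorModel, detect
        from plaqseg3d.hrnet3d import HRNetConfig

        model = DetectorModel(HRNetConfig(n_branches=2, base_channels=4,
                                          n_stages=1), seed=0)
        return model, detect

    def test_no_peaks_warns_and_returns_zero_map(self):
        model, detect = self._trained_stub()
        block = np.zeros((16, 16, 16), np.float32)
        _, rpn = detect(model, block, score_thresh=0.9)
        with pytest.warns(UserWarning):
            agg, maps = P.prm_for_block(model, block, rpn, score_thresh=0.99)
        assert agg.shape == block.shape and agg.max() == 0.0 and maps == []

    def test_aggregate_is_scaled_max_over_peaks(self, rng):
        model, detect = self._trained_stub()
        block = rng.random((16, 16, 16)).astype(np.float32)
        _, rpn = detect(model, block, score_thresh=0.9)
        agg, maps = P.prm_for_block(model, block, rpn, score_thresh=0.0)
        if maps:
            stacked = np.max(np.stack([m.prob for m in maps]), axis=0)
            np.testing.assert_allclose(agg, stacked / stacked.max(), atol=1e-12)
            assert 0 <= agg.min() and agg.max() == pytest.approx(1.0)
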