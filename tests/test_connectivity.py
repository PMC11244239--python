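import numpy as np
import pytest

from strokeeg.connectivity import (
    CorrelationWeights,
    PliMatrix,
    apply_weights,
    correlation_weights,
    instantaneous_phase,
    pli,
    pli_matrix,
    wrap_phase,
)
from strokeeg.errors import DegeneratePhaseWarning, ParameterError

from .oracles import pli_oracle

FS = 256
T = np.arange(FS) / FS


class TestInstantaneousPhase:
    def test_pure_tone_phase_slope(self):
        x = np.cos(2 * np.pi * 8 * T)
        phase = np.unwrap(instantaneous_phase(x))
        mid = slice(64, 192)
        slope = np.polyfit(T[mid], phase[mid], 1)[0]
        assert abs(slope - 2 * np.pi * 8) / (2 * np.pi * 8) < 0.01

    def test_quadrature_pair(self):
        x = np.cos(2 * np.pi * 8 * T)
        y = np.sin(2 * np.pi * 8 * T)
        d = wrap_phase(instantaneous_phase(x) - instantaneous_phase(y))
        assert np.allclose(d[64:192], np.pi / 2, atol=1e-6)

    def test_negation_shifts_phase_by_pi(self):
        x = np.cos(2 * np.pi * 8 * T)
        d = wrap_phase(instantaneous_phase(-x) - instantaneous_phase(x))
        assert np.allclose(np.abs(d[64:192]), np.pi, atol=1e-6)

    def test_constant_signal_warns(self):
        with pytest.warns(DegeneratePhaseWarning):
            instantaneous_phase(np.ones(64))

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            instantaneous_phase(np.arange(4.0))


class TestPli:
    def test_constant_lag_gives_one(self):
        # 8 Hz fills exactly 8 periods in 1 s, so the discrete analytic
        # signal is exact and the phase difference is exactly pi/4
        x = np.cos(2 * np.pi * 8 * T)
        y = np.cos(2 * np.pi * 8 * T - np.pi / 4)
        assert pli(x, y) == 1.0

    def test_identical_signals_give_zero(self, rng):
        x = rng.normal(size=FS)
        assert pli(x, x) == 0.0

    def test_independent_noise_is_low(self, rng):
        vals = [pli(rng.normal(size=FS), rng.normal(size=FS)) for _ in range(100)]
        assert np.mean(vals) < 0.15

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(size=FS)
            y = rng.normal(size=FS)
            assert abs(pli(x, y) - pli_oracle(x, y)) <= 1e-12

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            pli(rng.normal(size=FS), rng.normal(size=FS - 1))

    def test_edge_exclusion_switch(self, rng):
        x = np.cos(2 * np.pi * 8 * T)
        y = np.cos(2 * np.pi * 8 * T - np.pi / 4)
        assert pli(x, y, exclude_edge_fraction=0.05) == 1.0
        a, b = rng.normal(size=FS), rng.normal(size=FS)
        trimmed = pli(a, b, exclude_edge_fraction=0.05)
        assert 0.0 <= trimmed <= 1.0
        with pytest.raises(ParameterError):
            pli(a, b, exclude_edge_fraction=0.6)


class TestPliMatrix:
    def test_two_channels_reduce_to_pairwise(self, rng):
        epoch = rng.normal(size=(2, FS))
        m = pli_matrix(epoch).values
        assert m[0, 1] == pli(epoch[0], epoch[1])
        assert m[0, 0] == 0.0 and m[1, 1] == 0.0

    def test_symmetric_zero_diagonal(self, rng):
        m = pli_matrix(rng.normal(size=(7, FS))).values
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_fully_coupled_cohort_high_everywhere(self, coupled_epochs):
        m = pli_matrix(coupled_epochs.epochs[3]).values
        off = ~np.eye(m.shape[0], dtype=bool)
        assert m[off].min() >= 0.9


class TestCorrelationWeights:
    def _mats(self, values):
        return [PliMatrix(values=v, channel_names=["a", "b"]) for v in values]

    def test_unanimous_direction_gives_one(self):
        lo = np.array([[0.0, 0.2], [0.2, 0.0]])
        hi = np.array([[0.0, 0.8], [0.8, 0.0]])
        w = correlation_weights(self._mats([lo, lo]), self._mats([hi, hi]))
        assert w.values[0, 1] == 1.0  # |0 - 4| / 4
        assert w.n_stroke == 2 and w.n_control == 2

    def test_balanced_comparisons_give_zero(self):
        lo = np.array([[0.0, 0.2], [0.2, 0.0]])
        hi = np.array([[0.0, 0.8], [0.8, 0.0]])
        w = correlation_weights(self._mats([lo, hi]), self._mats([lo, hi]))
        # n_greater = n_smaller = 1 (one tie pair each way contributes none)
        assert w.values[0, 1] == 0.0

    def test_comparison_count_matches_group_sizes(self, rng):
        stroke = [rng.uniform(size=(19, 19)) for _ in range(20)]
        control = [rng.uniform(size=(19, 19)) for _ in range(19)]
        w = correlation_weights(stroke, control)
        assert w.n_stroke * w.n_control == 380

    def test_weights_symmetric_in_unit_interval(self, rng):
        def sym(a):
            a = rng.uniform(size=(5, 5))
            return (a + a.T) / 2
        w = correlation_weights([sym(None) for _ in range(4)],
                                [sym(None) for _ in range(3)]).values
        assert np.array_equal(w, w.T)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            correlation_weights([], self._mats([np.zeros((2, 2))]))


class TestApplyWeights:
    def test_identity_and_zero_weights(self, rng):
        p = rng.uniform(size=(6, 6))
        p = (p + p.T) / 2
        names = [f"c{i}" for i in range(6)]
        pm = PliMatrix(values=p, channel_names=names)
        ones = CorrelationWeights(values=np.ones((6, 6)), channel_names=names)
        zeros = CorrelationWeights(values=np.zeros((6, 6)), channel_names=names)
        assert np.array_equal(apply_weights(pm, ones).values, p)
        assert np.all(apply_weights(pm, zeros).values == 0.0)

    def test_matches_elementwise_loop(self, rng):
        p = rng.uniform(size=(5, 5))
        w = rng.uniform(size=(5, 5))
        names = [f"c{i}" for i in range(5)]
        out = apply_weights(PliMatrix(values=p, channel_names=names),
                            CorrelationWeights(values=w, channel_names=names)).values
        for i in range(5):
            for j in range(5):
                assert out[i, j] == p[i, j] * w[i, j]
        assert np.all(out <= p + 1e-15)  # cwPLI never exceeds PLI

    def test_channel_mismatch_rejected(self, rng):
        pm = PliMatrix(values=np.zeros((4, 4)), channel_names=list("abcd"))
        w = CorrelationWeights(values=np.zeros((5, 5)), channel_names=list("abcde"))
        with pytest.raises(ParameterError):
            apply_weights(pm, w)
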