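import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from cfcausal import (
    SymbolSequence,
    dpli,
    dste_scan,
    envelope_xcorr_lag,
    pac,
    ste,
    symbolize,
    wrap_phase,
)

FS = 256.0


class TestDpli:
    def test_leader_with_constant_positive_offset(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        b = wrap_phase(a - np.pi / 4)
        assert dpli(a, b) == pytest.approx(1.0)

    def test_identical_series_half(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        assert dpli(a, a) == pytest.approx(0.5)

    def test_follower_with_constant_negative_offset(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        b = wrap_phase(a + np.pi / 4)
        assert dpli(a, b) == pytest.approx(0.0)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            dpli(rng.uniform(size=10), rng.uniform(size=9))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 200)
        b = r.uniform(-np.pi, np.pi, 200)
        assert dpli(a, b) + dpli(b, a) == pytest.approx(1.0, abs=1e-12)


class TestPac:
    def test_constructed_modulation_detected(self, rng):
        # frequency-jittered slow phase: a near-periodic phase would defeat
        # time-shift surrogates (shifting a periodic signal only adds a
        # constant phase offset, which the PLV ignores)
        n = int(6 * FS)
        freqs = 5.5 + 1.0 * rng.standard_normal(n)
        lf_phase = wrap_phase(np.cumsum(2 * np.pi * freqs / FS))
        env = 1.0 + 0.9 * np.cos(lf_phase)
        res = pac(lf_phase, env, FS, n_surrogates=199, rng=np.random.default_rng(1))
        assert res.value > 0.9
        assert res.p_value < 0.01

    def test_constant_envelope_not_significant(self, rng):
        n = int(6 * FS)
        freqs = 5.5 + 1.0 * rng.standard_normal(n)
        lf_phase = wrap_phase(np.cumsum(2 * np.pi * freqs / FS))
        env = np.ones(n) + 1e-6 * rng.standard_normal(n)
        res = pac(lf_phase, env, FS, n_surrogates=30, rng=np.random.default_rng(2))
        assert res.p_value > 0.05

    def test_modulation_outside_band_rejected(self):
        # envelope modulated at 2 Hz, far below the 5-6 Hz filter band:
        # the modulation phase is rejected, so significance stays at chance
        n = int(5 * FS)
        t = np.arange(n) / FS
        hits = 0
        reps = 100
        for i in range(reps):
            r = np.random.default_rng(3000 + i)
            lf_phase = wrap_phase(
                np.cumsum(2 * np.pi * (5.5 + r.standard_normal(n)) / FS)
            )
            mod_phase = np.cumsum(2 * np.pi * (1.5 + 0.25 * r.standard_normal(n)) / FS)
            env = 1.0 + 0.8 * np.cos(mod_phase) + 0.05 * r.standard_normal(n)
            res = pac(lf_phase, env, FS, n_surrogates=30, rng=np.random.default_rng(i))
            hits += res.p_value <= 0.05
        assert (reps - hits) / reps >= 0.95


class TestSymbolize:
    def test_ordinal_ascending_series_single_symbol(self):
        s = symbolize(np.arange(50.0), "ordinal", m=3)
        assert len(np.unique(s.symbols)) == 1
        assert s.n_symbols == math.factorial(3)

    def test_ordinal_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(300)
        a = symbolize(x, "ordinal", m=3)
        b = symbolize(np.exp(2 * x + 1), "ordinal", m=3)
        np.testing.assert_array_equal(a.symbols, b.symbols)

    def test_neural_gas_partitions_plateaus(self, rng):
        # alternating well-separated plateaus -> the two prototypes split
        # them exactly like a 2-means solution on the embedded cloud
        levels = np.repeat(np.tile([0.0, 10.0], 20), 25)
        x = levels + 0.01 * rng.standard_normal(levels.size)
        s = symbolize(x, "neural_gas", m=3, n_symbols=2,
                      rng=np.random.default_rng(0))
        emb_level = levels[: len(s.symbols)]
        interior = np.abs(np.diff(emb_level)) == 0  # skip transition vectors
        interior = np.concatenate([interior, [True]])
        lab0 = s.symbols[(emb_level == 0) & interior]
        lab10 = s.symbols[(emb_level == 10) & interior]
        assert len(np.unique(lab0)) == 1
        assert len(np.unique(lab10)) == 1
        assert lab0[0] != lab10[0]

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            symbolize(np.arange(3.0), "ordinal", m=4, tau=2)

    def test_too_few_symbols_raises(self, rng):
        with pytest.raises(ValueError, match="symbols"):
            symbolize(rng.standard_normal(100), "neural_gas", n_symbols=1)


class TestSte:
    def seq(self, arr, K):
        return SymbolSequence(np.asarray(arr), K, "ordinal", 3, 1)

    def test_independent_sequences_near_zero(self, rng):
        x = self.seq(rng.integers(0, 4, 10_000), 4)
        y = self.seq(rng.integers(0, 4, 10_000), 4)
        assert ste(x, y, 5) < 0.02

    def test_deterministic_copy_transfers_full_entropy(self, rng):
        xs = rng.integers(0, 4, 5000)
        delta = 7
        ys = np.roll((xs + 1) % 4, delta)  # y_{t+delta} = f(x_t)
        x = self.seq(xs, 4)
        y = self.seq(ys, 4)
        # y is an iid sequence whose future is fully determined by x_t
        p = np.bincount(ys, minlength=4) / len(ys)
        h_y = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert ste(x, y, delta) == pytest.approx(h_y, rel=0.05)
        assert ste(x, y, delta) > 0

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        x = self.seq(r.integers(0, 3, 500), 3)
        y = self.seq(r.integers(0, 3, 500), 3)
        assert ste(x, y, int(r.integers(1, 50))) >= 0.0

    def test_delta_validation(self, rng):
        x = self.seq(rng.integers(0, 3, 100), 3)
        with pytest.raises(ValueError):
            ste(x, x, 100)
        with pytest.raises(ValueError):
            ste(x, x, 0)


class TestDsteScan:
    def test_delayed_copy_recovered(self, rng):
        n = 2000
        delay = 10
        x = signal.filtfilt(signal.firwin(65, 40, fs=FS), [1.0],
                            rng.standard_normal(n))
        y = np.roll(x, delay) + 0.1 * rng.standard_normal(n)
        est = dste_scan(x, y, FS, max_delay_ms=100.0,
                        rng=np.random.default_rng(0))
        assert abs(est.delay_samples - delay) <= 1
        assert est.net_direction == 1

    def test_swap_reverses_asymmetry(self, rng):
        n = 1500
        x = signal.filtfilt(signal.firwin(65, 40, fs=FS), [1.0],
                            rng.standard_normal(n))
        y = np.roll(x, 12) + 0.2 * rng.standard_normal(n)
        fwd = dste_scan(x, y, FS, max_delay_ms=80.0, scheme="ordinal")
        rev = dste_scan(y, x, FS, max_delay_ms=80.0, scheme="ordinal")
        # the forward curve of one orientation is the reverse of the other
        np.testing.assert_allclose(fwd.te_forward, rev.te_reverse, atol=1e-12)
        np.testing.assert_allclose(fwd.te_reverse, rev.te_forward, atol=1e-12)
        assert np.sign(fwd.te_forward[5] - fwd.te_reverse[5]) == -np.sign(
            rev.te_forward[5] - rev.te_reverse[5]
        )

    def test_independent_series_rarely_significant(self):
        hits = 0
        reps = 100
        for i in range(reps):
            r = np.random.default_rng(i)
            x = r.standard_normal(1000)
            y = r.standard_normal(1000)
            est = dste_scan(x, y, FS, max_delay_ms=40.0, delay_step=2,
                            scheme="ordinal", n_surrogates=30,
                            rng=np.random.default_rng(5000 + i))
            hits += est.p_value <= 0.05
        assert (reps - hits) / reps >= 0.94

    def test_empty_grid_rejected(self, rng):
        x = rng.standard_normal(500)
        from cfcausal.causal import dste_scan_symbols

        sx = symbolize(x, "ordinal")
        with pytest.raises(ValueError, match="empty"):
            dste_scan_symbols(sx, sx, FS, np.array([], dtype=int))


class TestEnvelopeXcorr:
    def test_shifted_copy_recovers_exact_lag(self, rng):
        base = signal.filtfilt(signal.firwin(129, 4, fs=FS), [1.0],
                               rng.standard_normal(2200))
        L = 17
        n = 2000
        x = base[L: L + n]
        y = base[:n]  # y(t) = x(t - L): x precedes y
        lag_ms = envelope_xcorr_lag(x, y, FS, max_lag_ms=200.0)
        assert round(lag_ms / 1000 * FS) == L

    def test_identical_envelopes_zero_lag(self, rng):
        env = np.abs(signal.filtfilt(signal.firwin(129, 4, fs=FS), [1.0],
                                     rng.standard_normal(1500)))
        assert envelope_xcorr_lag(env, env, FS) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            envelope_xcorr_lag(np.ones(500), np.ones(500), FS)

    def test_independent_envelopes_below_shift_null(self, rng):
        # peak correlation of independent smoothed-noise envelopes stays
        # below the 95th percentile of a circular-shift null
        b = signal.firwin(129, 3, fs=FS)
        hits = 0
        reps = 60
        for i in range(reps):
            r = np.random.default_rng(i)
            # crop interiors: aligned filter-edge transients would otherwise
            # inflate the near-zero-lag correlation of independent envelopes
            ax = np.abs(signal.filtfilt(b, [1.0], r.standard_normal(2100)))[300:1800]
            ay = np.abs(signal.filtfilt(b, [1.0], r.standard_normal(2100)))[300:1800]
            axm = ax - ax.mean()
            aym = ay - ay.mean()
            cc = signal.correlate(aym, axm, "full")
            lags = signal.correlation_lags(len(aym), len(axm), "full")
            sel = np.abs(lags) <= 64
            peak = np.max(np.abs(cc[sel]))
            null = []
            for s in r.integers(300, 1200, 19):
                ccs = signal.correlate(aym, np.roll(axm, int(s)), "full")
                null.append(np.max(np.abs(ccs[sel])))
            hits += peak > np.quantile(null, 0.95)
        assert hits / reps < 0.25


def test_lag_recovery_on_synthetic_pair(small_config):
    """Light version of the full parameter-recovery check (one lag)."""
    import dataclasses

    from cfcausal import generate_trial
    from cfcausal.causal import causal_series

    cfg = dataclasses.replace(small_config, duration_base_ms=6000.0,
                              duration_step_ms=0.0)
    rng = np.random.default_rng(3)
    errs = []
    for i in range(10):
        trial, gt = generate_trial(cfg, 3, "correct", rng)
        x = causal_series(trial.samples[0], cfg.fs)
        y = causal_series(trial.samples[cfg.montage.index("O2")], cfg.fs)
        est = dste_scan(x, y, cfg.fs, rng=np.random.default_rng(i))
        errs.append(abs(est.delay_samples - gt.pair_lag_samples("O2")))
    assert np.median(errs) <= 1
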