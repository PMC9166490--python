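"""Signal generator and overwrite-store telemeter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from modbci.simulator import (
    ConfigError,
    DeviceUnavailable,
    EcogPacket,
    MOVE,
    REST,
    SimClock,
    SimConfig,
    Telemeter,
    estimate_erd_ratio,
    packetize,
    synthesize_signal,
)


def _welch_band_power(x, fs, band):
    f, p = sps.welch(x, fs=fs, nperseg=min(1024, len(x)))
    m = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[m], f[m])


class TestSynthesize:
    def test_seeded_determinism_is_bitwise(self):
        sched = [(REST, 4.0), (MOVE, 4.0)]
        a = synthesize_signal(SimConfig(seed=42), sched)
        b = synthesize_signal(SimConfig(seed=42), sched)
        assert np.array_equal(a.ch1, b.ch1)
        assert np.array_equal(a.ch4_power, b.ch4_power)
        c = synthesize_signal(SimConfig(seed=43), sched)
        assert not np.array_equal(a.ch1, c.ch1)

    def test_no_erd_means_equal_beta_power(self):
        sig = synthesize_signal(
            SimConfig(erd_depth=0.0, seed=1),
            [(REST, 120.0), (MOVE, 120.0)] * 2,
        )
        move = sig.state_lagged
        p_rest = _welch_band_power(sig.ch1[~move], 200, (12, 25))
        p_move = _welch_band_power(sig.ch1[move], 200, (12, 25))
        assert abs(p_move - p_rest) / p_rest < 0.05

    def test_erd_suppresses_move_beta_power(self):
        # one-sided comparison over >= 100 windows per state
        sig = synthesize_signal(
            SimConfig(erd_depth=0.8, seed=3), [(REST, 60.0), (MOVE, 60.0)]
        )
        fs = 200
        half = len(sig.ch1) // 2
        win = fs  # 1 s windows -> 60 per state... use 0.5 s for >=100
        win = fs // 2
        rest_w = sig.ch1[:half].reshape(-1, win)
        move_w = sig.ch1[half + 200:].reshape(-1, win)  # skip lag region
        bp = lambda W: [_welch_band_power(w, fs, (12, 25)) for w in W]
        assert len(rest_w) >= 100
        assert np.mean(bp(move_w)) < np.mean(bp(rest_w))

    def test_erd_ratio_recovers_generative_amplitude_ratio(self):
        # MOVE/REST beta power converges to (1-d)^2 for a >=5 min session
        for d in (0.5, 0.8):
            cfg = SimConfig(erd_depth=d, seed=9)
            sig = synthesize_signal(cfg, [(REST, 30.0), (MOVE, 30.0)] * 5)
            ratio = estimate_erd_ratio(sig)
            assert ratio == pytest.approx((1 - d) ** 2, rel=0.10)

    def test_pure_tone_psd_peaks_at_tone_frequency(self):
        cfg = SimConfig(
            pink_noise_scale=0.0, white_noise_scale=0.0, beta_amplitude=0.0, seed=0
        )
        sig = synthesize_signal(cfg, [(REST, 10.0)])
        tone = np.sin(2 * np.pi * 18.0 * np.arange(len(sig.ch1)) / 200)
        f, p = sps.welch(sig.ch1 + tone, fs=200, nperseg=512)
        assert f[np.argmax(p)] == pytest.approx(18.0, abs=f[1] - f[0])

    def test_power_channels_track_time_channel_band_power(self):
        # per-packet correlation of emitted power channel vs Welch band power
        cfg = SimConfig(seed=5)
        sig = synthesize_signal(cfg, [(REST, 150.0), (MOVE, 150.0)])
        packets, _ = packetize(sig)
        onboard = np.array([p.ch2_power.mean() for p in packets])
        welch = np.array(
            [_welch_band_power(p.ch1, 200, (4, 36)) for p in packets]
        )
        rho = np.corrcoef(onboard, welch)[0, 1]
        assert rho > 0.8

    def test_neuromotor_lag_delays_state_change_in_signal(self):
        cfg = SimConfig(neuromotor_lag=0.3, seed=0)
        sig = synthesize_signal(cfg, [(REST, 2.0), (MOVE, 2.0)])
        change_prompt = np.flatnonzero(np.diff(sig.state.astype(int)))[0] + 1
        change_signal = np.flatnonzero(np.diff(sig.state_lagged.astype(int)))[0] + 1
        assert change_signal - change_prompt == int(0.3 * 200)

    def test_invalid_erd_depth_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(erd_depth=1.5)
        with pytest.raises(ConfigError):
            SimConfig(erd_depth=-0.1)

    def test_empty_or_nonpositive_schedule_rejected(self):
        with pytest.raises(ConfigError):
            synthesize_signal(SimConfig(), [])
        with pytest.raises(ConfigError):
            synthesize_signal(SimConfig(), [(REST, -1.0)])


class TestPacketize:
    def test_five_minute_signal_gives_750_packets_and_60000_samples(self):
        sig = synthesize_signal(SimConfig(seed=1), [(REST, 300.0)])
        packets, discarded = packetize(sig)
        assert len(packets) == 750
        assert discarded == 0
        assert sum(len(p.ch1) for p in packets) == 60_000
        assert all(len(p.ch1) == 80 and len(p.ch3) == 80 for p in packets)
        assert all(len(p.ch2_power) == 2 and len(p.ch4_power) == 2 for p in packets)

    def test_trailing_partial_frame_is_dropped_and_counted(self):
        sig = synthesize_signal(SimConfig(seed=1), [(REST, 0.79)])
        packets, discarded = packetize(sig)
        assert len(packets) == 1
        assert discarded == 1

    def test_packet_indices_and_times_are_consecutive(self):
        sig = synthesize_signal(SimConfig(seed=1), [(REST, 4.0), (MOVE, 4.0)])
        packets, _ = packetize(sig)
        assert [p.packet_index for p in packets] == list(range(20))
        assert np.allclose([p.t_start for p in packets], np.arange(20) * 0.4)

    def test_true_state_follows_prompt_schedule(self):
        sig = synthesize_signal(SimConfig(seed=1), [(REST, 4.0), (MOVE, 4.0)])
        packets, _ = packetize(sig)
        assert [p.true_state for p in packets] == [REST] * 10 + [MOVE] * 10


def _loss_oracle(poll_intervals, period=0.4):
    """Independent discrete-event simulation of the single-slot store.

    Tracks real time; the store holds the latest completed frame.  Returns
    (returned_indices, total_lost).
    """
    t = 0.0
    last = -1
    returned, lost = [], 0
    for dt in poll_intervals:
        t += dt
        latest_done = int(np.floor(t / period + 1e-9)) - 1
        want = last + 1
        if latest_done <= want:
            t = max(t, (want + 1) * period)  # block until completion
            got = want
        else:
            got = latest_done
            lost += got - want
        returned.append(got)
        last = got
    return returned, lost


class TestTelemeter:
    def _make(self, n=2000, clock=None):
        sig = synthesize_signal(SimConfig(seed=0), [(REST, n * 0.4)])
        packets, _ = packetize(sig)
        return Telemeter(packets, clock or SimClock())

    def test_nominal_polls_lose_nothing(self):
        tm = self._make(20)
        idx = [tm.read_packet().packet_index for _ in range(10)]
        assert idx == list(range(10))
        assert tm.n_lost == 0

    def test_blocking_returns_next_frame_never_a_duplicate(self):
        tm = self._make(20)
        a = tm.read_packet()
        b = tm.read_packet(tm.clock.now())  # immediate re-poll within the window
        assert b.packet_index == a.packet_index + 1

    def test_900ms_delay_loses_exactly_one_frame(self):
        tm = self._make(20)
        tm.read_packet()
        t = tm.clock.now()
        p = tm.read_packet(t + 0.9)
        assert tm.n_lost == 1
        assert len(tm.loss_events) == 1
        # index gap of 2 relative to the previous read
        assert p.packet_index == 2

    @pytest.mark.parametrize("interval", [0.401, 0.55, 0.9, 1.3])
    def test_cumulative_losses_match_discrete_event_oracle(self, interval):
        n_polls = 300
        tm = self._make(2000)
        got = []
        t = 0.0
        for _ in range(n_polls):
            t = tm.clock.now() + interval if got else interval
            got.append(tm.read_packet(t).packet_index)
        # oracle polls at the same relative cadence
        exp_idx, exp_lost = _loss_oracle([interval] * n_polls)
        assert got == exp_idx
        assert tm.n_lost == exp_lost

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=2.5, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_arbitrary_poll_schedules_match_oracle(self, intervals):
        tm = self._make(600)
        got = []
        for dt in intervals:
            got.append(tm.read_packet(tm.clock.now() + dt).packet_index)
        exp_idx, exp_lost = _loss_oracle(intervals)
        assert got == exp_idx
        assert tm.n_lost == exp_lost

    def test_disconnected_telemeter_raises(self):
        tm = self._make(10)
        tm.connected = False
        with pytest.raises(DeviceUnavailable):
            tm.read_packet()
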