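"""Synthetic ECoG telemetry: signal generation, packetization and the
overwrite-store telemeter.

The simulated implant emulates a four-channel sensing neurostimulator:
channels 1 and 3 stream raw field potentials at 200 Hz, channels 2 and 4
stream an on-board average band-power estimate (4-36 Hz) at 5 Hz.  Data
leave the device in 400 ms frames (2.5 Hz) through a single-slot on-board
store that is overwritten every frame, so a reader that polls late loses
the frames it skipped.

Signal model
------------
Each time channel is the sum of three components:

* a pink (1/f) background, the dominant broadband feature of cortical
  field potentials;
* a band-limited beta oscillation (12-25 Hz by default) whose amplitude
  is ``A_rest`` during REST and ``(1 - d) * A_rest`` during motor imagery
  (MOVE), modelling event-related desynchronization of depth ``d``;
* white sensor noise.

The two time channels share the state-dependent beta amplitude envelope
(they overlie the same cortical region) but carry independent noise and
independent narrow-band carriers.  State changes reach the signal after a
configurable neuromotor lag emulating reaction time.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps

MOVE = "MOVE"
REST = "REST"
UNLABELED = "UNLABELED"

#: schema identifier embedded in persisted session files
SESSION_SCHEMA = "modbci-session-v1"


class ConfigError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Device constants and generative parameters of the simulated implant.

    Parameters
    ----------
    fs_time : float
        Sampling rate of the raw time channels, samples/s.
    fs_power : float
        Sampling rate of the on-board band-power channels, samples/s.
    packet_period : float
        Telemetry frame length in seconds (the overwrite period).
    beta_band : tuple of float
        Band of the state-modulated oscillation, Hz.
    power_band : tuple of float
        Band integrated by the on-board power estimator, Hz.
    erd_depth : float
        Desynchronization depth ``d`` in [0, 1]: beta amplitude during
        MOVE is ``(1 - d)`` times the REST amplitude.
    beta_amplitude : float
        REST-state standard deviation of the beta component (a.u.).
    pink_noise_scale, white_noise_scale : float
        Standard deviations of the background components (a.u.).
    neuromotor_lag : float
        Delay in seconds between a prompt change and the corresponding
        change in the signal.
    seed : int
        Seed for the generator; identical configs and schedules produce
        bit-identical signals.
    """

    fs_time: float = 200.0
    fs_power: float = 5.0
    packet_period: float = 0.4
    beta_band: tuple[float, float] = (12.0, 25.0)
    power_band: tuple[float, float] = (4.0, 36.0)
    erd_depth: float = 0.8
    beta_amplitude: float = 2.0
    pink_noise_scale: float = 1.0
    white_noise_scale: float = 0.2
    neuromotor_lag: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigError(
                f"erd_depth must be in [0, 1], got {self.erd_depth}"
            )
        spp = self.fs_time * self.packet_period
        if abs(spp - round(spp)) > 1e-9 or round(spp) < 1:
            raise ConfigError("fs_time * packet_period must be a whole number of samples")
        ppp = self.fs_power * self.packet_period
        if abs(ppp - round(ppp)) > 1e-9 or round(ppp) < 1:
            raise ConfigError("fs_power * packet_period must be a whole number of samples")
        if not 0 < self.beta_band[0] < self.beta_band[1] < self.fs_time / 2:
            raise ConfigError(f"invalid beta band {self.beta_band}")

    @property
    def samples_per_packet(self) -> int:
        return int(round(self.fs_time * self.packet_period))

    @property
    def power_samples_per_packet(self) -> int:
        return int(round(self.fs_power * self.packet_period))


@dataclasses.dataclass
class EcogPacket:
    """One 400 ms telemetry frame."""

    packet_index: int
    t_start: float
    ch1: np.ndarray        # raw time channel, samples_per_packet floats
    ch3: np.ndarray        # raw time channel
    ch2_power: np.ndarray  # on-board band power, power_samples_per_packet floats
    ch4_power: np.ndarray
    true_state: str        # simulator ground truth, hidden from the decoder

    def __post_init__(self) -> None:
        if len(self.ch1) != len(self.ch3):
            raise ValueError("time channels differ in length")
        if len(self.ch2_power) != len(self.ch4_power):
            raise ValueError("power channels differ in length")


@dataclasses.dataclass
class SimulatedSignal:
    """A continuous realization before packetization."""

    config: SimConfig
    ch1: np.ndarray
    ch3: np.ndarray
    ch2_power: np.ndarray
    ch4_power: np.ndarray
    state: np.ndarray       # prompt-aligned state per time sample (no lag)
    state_lagged: np.ndarray  # state actually driving the signal

    @property
    def n_samples(self) -> int:
        return len(self.ch1)

    @property
    def duration(self) -> float:
        return self.n_samples / self.config.fs_time


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    nf = n // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros(nf)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_limited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _states_from_schedule(
    schedule: Sequence[tuple[str, float]], fs: float
) -> np.ndarray:
    """Expand (state, duration-seconds) pairs to a per-sample state array."""
    if not schedule:
        raise ConfigError("state schedule must be nonempty")
    chunks = []
    for state, duration in schedule:
        if state not in (MOVE, REST):
            raise ConfigError(f"unknown state {state!r}")
        if duration <= 0:
            raise ConfigError("schedule durations must be positive")
        chunks.append(np.full(int(round(duration * fs)), state == MOVE))
    return np.concatenate(chunks)


def synthesize_signal(
    config: SimConfig, state_schedule: Sequence[tuple[str, float]]
) -> SimulatedSignal:
    """Generate a continuous two-channel realization for a prompt schedule.

    Parameters
    ----------
    config : SimConfig
    state_schedule : sequence of (state, duration_seconds)

    Returns
    -------
    SimulatedSignal
        Time channels, on-board power traces, and ground-truth state arrays.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs_time
    is_move = _states_from_schedule(state_schedule, fs)
    n = len(is_move)

    lag = int(round(config.neuromotor_lag * fs))
    lagged = np.empty_like(is_move)
    lagged[:lag] = is_move[0] if lag else False
    if lag:
        lagged[lag:] = is_move[:-lag] if lag < n else is_move[0]
    else:
        lagged[:] = is_move

    amp = config.beta_amplitude * np.where(lagged, 1.0 - config.erd_depth, 1.0)

    channels = []
    for _ in range(2):
        beta = _band_limited_noise(n, fs, config.beta_band, rng)
        pink = _pink_noise(n, fs, rng)
        white = rng.standard_normal(n)
        channels.append(
            amp * beta
            + config.pink_noise_scale * pink
            + config.white_noise_scale * white
        )
    ch1, ch3 = channels

    ch2_power = _onboard_band_power(ch1, config)
    ch4_power = _onboard_band_power(ch3, config)
    return SimulatedSignal(config, ch1, ch3, ch2_power, ch4_power, is_move, lagged)


def _onboard_band_power(x: np.ndarray, config: SimConfig) -> np.ndarray:
    """Emulate the implant's power channels: trailing-window mean band power.

    The signal is band-passed to ``power_band``, squared, and averaged over
    a trailing window of one power-sample period; one value is emitted per
    1/fs_power seconds, aligned to the end of each window.
    """
    sos = sps.butter(4, config.power_band, btype="bandpass", fs=config.fs_time, output="sos")
    inst = sps.sosfilt(sos, x) ** 2
    step = int(round(config.fs_time / config.fs_power))
    n_out = len(x) // step
    csum = np.concatenate([[0.0], np.cumsum(inst)])
    ends = (np.arange(1, n_out + 1) * step)
    return (csum[ends] - csum[ends - step]) / step


def packetize(signal: SimulatedSignal) -> tuple[list[EcogPacket], int]:
    """Cut a realization into consecutive non-overlapping telemetry frames.

    A trailing partial frame is dropped and counted.  ``true_state`` of a
    packet is the prompt-aligned state at the packet's first sample.

    Returns
    -------
    (packets, discarded) : list of EcogPacket, int
    """
    cfg = signal.config
    spp = cfg.samples_per_packet
    ppp = cfg.power_samples_per_packet
    n_packets = signal.n_samples // spp
    if n_packets < 1:
        raise ValueError("signal shorter than one packet")
    discarded = int(signal.n_samples % spp > 0)
    packets = []
    for k in range(n_packets):
        sl = slice(k * spp, (k + 1) * spp)
        pl = slice(k * ppp, (k + 1) * ppp)
        packets.append(
            EcogPacket(
                packet_index=k,
                t_start=k * cfg.packet_period,
                ch1=signal.ch1[sl].copy(),
                ch3=signal.ch3[sl].copy(),
                ch2_power=signal.ch2_power[pl].copy(),
                ch4_power=signal.ch4_power[pl].copy(),
                true_state=MOVE if signal.state[k * spp] else REST,
            )
        )
    return packets, discarded


class SimClock:
    """A shared monotonic simulated clock (seconds)."""

    def __init__(self, t0: float = 0.0) -> None:
        self._t = float(t0)

    def now(self) -> float:
        return self._t

    def advance_to(self, t: float) -> None:
        if t < self._t:
            raise ValueError("clock cannot move backwards")
        self._t = t

    def advance(self, dt: float) -> None:
        self.advance_to(self._t + dt)


@dataclasses.dataclass
class LossEvent:
    """Frames lost to a late poll of the overwrite store."""

    poll_time: float
    first_lost_index: int
    n_lost: int


class Telemeter:
    """The overwrite-store reader for a packetized realization.

    The implant completes frame ``k`` at ``(k + 1) * packet_period`` and
    immediately overwrites the single-slot store with it.  ``read_packet``
    blocks (advancing the simulated clock) until the next unread frame
    completes; a caller that polls more than one frame late finds the
    intervening frames already overwritten and receives only the latest,
    with the gap recorded as a :class:`LossEvent`.
    """

    def __init__(self, packets: Sequence[EcogPacket], clock: SimClock | None = None):
        self._packets = list(packets)
        if not self._packets:
            raise ValueError("telemeter needs at least one packet")
        self.clock = clock if clock is not None else SimClock()
        self._period = _packet_period_of(packets)
        self._last_index: int = -1
        self.loss_events: list[LossEvent] = []
        self.connected = True

    @property
    def n_lost(self) -> int:
        return sum(e.n_lost for e in self.loss_events)

    def exhausted(self) -> bool:
        return self._last_index >= len(self._packets) - 1

    def read_packet(self, poll_time: float | None = None) -> EcogPacket:
        """Return the next available frame, blocking on the simulated clock.

        Parameters
        ----------
        poll_time : float, optional
            Time of the poll; defaults to the clock's current time.  The
            clock is advanced to the poll time and then to the completion
            of the returned frame when it has to block.
        """
        if not self.connected:
            raise DeviceUnavailable("telemeter disconnected")
        if self.exhausted():
            raise StopIteration("telemetry stream exhausted")
        t = self.clock.now() if poll_time is None else poll_time
        if t > self.clock.now():
            self.clock.advance_to(t)
        t = self.clock.now()
        desired = self._last_index + 1
        # latest frame whose completion time (k+1)*period is <= t
        latest_done = int(np.floor(t / self._period + 1e-9)) - 1
        latest_done = min(latest_done, len(self._packets) - 1)
        if latest_done <= desired:
            # store still holds (or will next hold) the desired frame: block
            completion = (desired + 1) * self._period
            if completion > t:
                self.clock.advance_to(completion)
            self._last_index = desired
            return self._packets[desired]
        # late poll: frames desired .. latest_done-1 were overwritten
        n_lost = latest_done - desired
        self.loss_events.append(LossEvent(t, desired, n_lost))
        self._last_index = latest_done
        return self._packets[latest_done]


def _packet_period_of(packets: Sequence[EcogPacket]) -> float:
    if len(packets) >= 2:
        return packets[1].t_start - packets[0].t_start
    return 0.4


class DeviceUnavailable(RuntimeError):
    """A selected device is disconnected or otherwise unreachable."""


# ---------------------------------------------------------------------------
# Spectral ground-truth estimation used by recovery checks and reports.

def band_power_above_background(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (12.0, 25.0),
    flanks: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 9.0), (31.0, 38.0)),
    nperseg: int = 1024,
) -> float:
    """Integrated band power above the 1/f background.

    The background under ``band`` is estimated by a log-log linear fit of
    the Welch spectrum over the two flanking bands and subtracted before
    integrating, so a narrow-band oscillation can be quantified on top of
    pink noise.
    """
    f, p = sps.welch(x, fs=fs, nperseg=min(nperseg, len(x)))
    fl = ((f >= flanks[0][0]) & (f <= flanks[0][1])) | (
        (f >= flanks[1][0]) & (f <= flanks[1][1])
    )
    coef = np.polyfit(np.log(f[fl]), np.log(p[fl]), 1)
    inband = (f >= band[0]) & (f <= band[1])
    background = np.exp(np.polyval(coef, np.log(f[inband])))
    df = f[1] - f[0]
    return float(np.clip(p[inband] - background, 0.0, None).sum() * df)


def estimate_erd_ratio(signal: SimulatedSignal, margin: float = 0.5) -> float:
    """Estimate the MOVE/REST beta-power ratio from a realization.

    Splits each time channel into MOVE and REST segments (excluding
    ``margin`` seconds around every state change to avoid lag contamination),
    measures beta power above the pink background in each state, and returns
    the MOVE/REST power ratio averaged over the two channels.  For the
    generative model the expected value is ``(1 - d)**2``.
    """
    cfg = signal.config
    fs = cfg.fs_time
    lagged = signal.state_lagged
    edges = np.flatnonzero(np.diff(lagged.astype(int))) + 1
    keep = np.ones(len(lagged), bool)
    m = int(round(margin * fs))
    for e in edges:
        keep[max(0, e - m): e + m] = False
    ratios = []
    for ch in (signal.ch1, signal.ch3):
        p_move = band_power_above_background(ch[keep & lagged], fs, cfg.beta_band)
        p_rest = band_power_above_background(ch[keep & ~lagged], fs, cfg.beta_band)
        ratios.append(p_move / p_rest)
    return float(np.mean(ratios))
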