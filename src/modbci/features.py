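"""Packet-to-feature transformation.

Each 400 ms telemetry frame becomes a 644-dimensional feature vector:

* the two raw time channels are high-pass filtered at 1 Hz (FIR), then a
  Hann-windowed periodogram of each 80-sample packet, zero-padded to 640
  points, yields 321 spectral bins per channel at a resolution of
  200/640 = 0.3125 Hz;
* the two on-board band-power samples per power channel are averaged to
  one value per channel.

Layout: ``[psd(ch1) | psd(ch3) | mean(ch2_power) | mean(ch4_power)]``,
i.e. 2 x 321 + 2 = 644 values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .simulator import EcogPacket, UNLABELED

N_PSD_BINS = 321
N_FEATURES = 2 * N_PSD_BINS + 2
_NFFT = 640  # the only zero-pad length giving 640/2 + 1 = 321 bins
_SAMPLES_PER_PACKET = 80
_FS = 200.0


class FilterSpecError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """High-pass FIR filter applied to the time channels.

    A windowed-sinc (Hamming) design realized by spectral inversion of the
    complementary low-pass, which nulls the DC gain exactly.  The default
    301 taps (1.5 s at 200 Hz) is the shortest Hamming design whose
    passband above 2 Hz stays within +/-0.05 of unity; ``causal-online``
    mode streams with carried filter state (group delay (n_taps-1)/2
    samples), while ``zero-phase-offline`` applies forward-backward
    filtering to a whole session.
    """

    cutoff: float = 1.0
    n_taps: int = 301
    window: str = "hamming"
    mode: str = "zero-phase-offline"  # or "causal-online"

    def __post_init__(self) -> None:
        if self.n_taps % 2 == 0 or self.n_taps < 3:
            raise FilterSpecError("n_taps must be odd and >= 3")
        if self.mode not in ("causal-online", "zero-phase-offline"):
            raise FilterSpecError(f"unknown filter mode {self.mode!r}")
        if not 0 < self.cutoff < _FS / 2:
            raise FilterSpecError("cutoff outside (0, Nyquist)")

    def taps(self, fs: float = _FS) -> np.ndarray:
        lp = sps.firwin(self.n_taps, self.cutoff, window=self.window, fs=fs)
        hp = -lp
        hp[(self.n_taps - 1) // 2] += 1.0  # spectral inversion: exact DC null
        return hp

    @property
    def group_delay_samples(self) -> int:
        return (self.n_taps - 1) // 2


def highpass(
    samples: np.ndarray,
    spec: FilterSpec,
    filter_state: np.ndarray | None = None,
    fs: float = _FS,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Filter one block of a time channel.

    In causal-online mode the returned filter state must be carried into
    the next call so that streaming block-by-block filtering equals batch
    filtering of the concatenated signal.  Zero-phase mode ignores and
    returns no state (it is a whole-session operation).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        return samples, filter_state
    taps = spec.taps(fs)
    if spec.mode == "zero-phase-offline":
        padlen = min(3 * len(taps), samples.size - 1)
        return sps.filtfilt(taps, [1.0], samples, padlen=padlen), None
    if filter_state is None:
        filter_state = np.zeros(len(taps) - 1)
    y, zf = sps.lfilter(taps, [1.0], samples, zi=filter_state)
    return y, zf


def packet_psd(filtered_samples: np.ndarray) -> np.ndarray:
    """321-bin Hann periodogram of one 80-sample packet.

    Bin ``k`` maps to frequency ``k * (200 / 640)`` Hz.  Density scaling
    (power per Hz); absolute scale cancels downstream in standardization.
    """
    x = np.asarray(filtered_samples, dtype=float)
    if x.shape != (_SAMPLES_PER_PACKET,):
        raise ValueError(
            f"packet_psd expects exactly {_SAMPLES_PER_PACKET} samples, got {x.shape}"
        )
    _, p = sps.periodogram(
        x, fs=_FS, window="hann", nfft=_NFFT, detrend=False, scaling="density"
    )
    return p


def psd_bin_frequencies() -> np.ndarray:
    """Frequencies (Hz) of the 321 spectral bins."""
    return np.arange(N_PSD_BINS) * (_FS / _NFFT)


@dataclasses.dataclass
class FeatureVector:
    """One packet's 644 features with its (possibly absent) prompt label."""

    values: np.ndarray
    packet_index: int
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(f"feature vector must have {N_FEATURES} values")


def build_feature_vector(
    packet: EcogPacket,
    filter_spec: FilterSpec | None = None,
    filter_states: tuple | None = None,
) -> tuple[FeatureVector, tuple | None]:
    """Turn one packet into a feature vector (single-packet convenience).

    For whole sessions prefer :class:`PacketFeaturizer`, which filters the
    concatenated stream so FIR state flows across packet boundaries.
    """
    spec = filter_spec or FilterSpec(mode="causal-online")
    st1, st3 = filter_states if filter_states is not None else (None, None)
    f1, st1 = highpass(packet.ch1, spec, st1)
    f3, st3 = highpass(packet.ch3, spec, st3)
    values = np.concatenate(
        [
            packet_psd(f1),
            packet_psd(f3),
            [float(np.mean(packet.ch2_power))],
            [float(np.mean(packet.ch4_power))],
        ]
    )
    fv = FeatureVector(values, packet.packet_index, packet.true_state)
    return fv, (st1, st3)


class PacketFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from packet streams to feature matrices.

    ``transform`` accepts a sequence of :class:`EcogPacket` and returns an
    ``(n_packets, 644)`` array.  The time channels of the whole sequence
    are filtered as one continuous stream (consecutive packets are assumed
    contiguous in time), then split back into packets for the per-packet
    periodogram.

    Parameters
    ----------
    cutoff, n_taps, window, mode
        High-pass filter design, see :class:`FilterSpec`.
    """

    def __init__(
        self,
        cutoff: float = 1.0,
        n_taps: int = 301,
        window: str = "hamming",
        mode: str = "zero-phase-offline",
    ) -> None:
        self.cutoff = cutoff
        self.n_taps = n_taps
        self.window = window
        self.mode = mode

    def _spec(self) -> FilterSpec:
        return FilterSpec(self.cutoff, self.n_taps, self.window, self.mode)

    def fit(self, X: Sequence[EcogPacket], y=None) -> "PacketFeaturizer":
        self._spec()  # validate parameters
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: Sequence[EcogPacket]) -> np.ndarray:
        packets = list(X)
        if not packets:
            return np.empty((0, N_FEATURES))
        spec = self._spec()
        spp = len(packets[0].ch1)
        ch1 = np.concatenate([p.ch1 for p in packets])
        ch3 = np.concatenate([p.ch3 for p in packets])
        f1, _ = highpass(ch1, spec)
        f3, _ = highpass(ch3, spec)
        out = np.empty((len(packets), N_FEATURES))
        for k, p in enumerate(packets):
            sl = slice(k * spp, (k + 1) * spp)
            out[k, :N_PSD_BINS] = packet_psd(f1[sl])
            out[k, N_PSD_BINS: 2 * N_PSD_BINS] = packet_psd(f3[sl])
            out[k, -2] = np.mean(p.ch2_power)
            out[k, -1] = np.mean(p.ch4_power)
        return out

    def feature_names(self) -> list[str]:
        """Machine-readable manifest of the 644 columns."""
        freqs = psd_bin_frequencies()
        names = [f"ch1_psd_{f:.4f}Hz" for f in freqs]
        names += [f"ch3_psd_{f:.4f}Hz" for f in freqs]
        names += ["ch2_power_mean", "ch4_power_mean"]
        return names


def featurize_session(
    packets: Sequence[EcogPacket],
    labels: Sequence[str] | None = None,
    featurizer: PacketFeaturizer | None = None,
) -> list[FeatureVector]:
    """Featurize a packet stream, attaching per-packet labels if given."""
    fz = featurizer or PacketFeaturizer()
    X = fz.fit(packets).transform(packets)
    out = []
    for row, p in zip(X, packets):
        lab = labels[p.packet_index] if labels is not None else p.true_state
        out.append(FeatureVector(row, p.packet_index, lab))
    return out
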