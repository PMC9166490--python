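"""Calibration protocol: prompt scheduling, label alignment, sessions.

A calibration session alternates MOVE and REST prompts at random
intervals of 6-10 s (15-25 telemetry packets), starting with REST as the
baseline.  Packets between consecutive prompt displays inherit the active
label; a latency guard marks the first packet of any prompt whose
delay-to-screen exceeded one packet period as UNLABELED, and an optional
transition-exclusion window drops the packets immediately after every
prompt change to absorb reaction time.

Sessions persist to Parquet with one row per packet and an embedded,
versioned schema string.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import simulator as sim
from .features import PacketFeaturizer
from .simulator import (
    MOVE,
    REST,
    UNLABELED,
    EcogPacket,
    LossEvent,
    SESSION_SCHEMA,
    SimConfig,
)

CALIBRATION_OPEN_LOOP = "calibration-open-loop"
CLOSED_LOOP = "closed-loop"

INTERVAL_PACKETS = (15, 25)   # inclusive bounds, i.e. 6-10 s at 2.5 packets/s
SESSION_DURATION = 300.0      # default 5-minute session -> 750 packets


@dataclasses.dataclass
class PromptEvent:
    """One textual MOVE/REST prompt."""

    label: str
    scheduled_packet_index: int
    sent_ts: float = float("nan")
    displayed_ts: float = float("nan")


@dataclasses.dataclass
class SessionRecord:
    """Everything recorded during one session."""

    mode: str
    packets: list[EcogPacket]
    prompts: list[PromptEvent]
    decoded: list[tuple[str, float]] | None   # per-packet (command, probability)
    loss_events: list[LossEvent]
    discarded: int
    config: SimConfig
    seed: int
    partial: bool = False

    @property
    def labels(self) -> list[str]:
        return label_packets(self.packets, self.prompts)


def schedule_prompts(
    duration: float,
    seed: int | np.random.Generator = 0,
    first_label: str = REST,
    interval_packets: tuple[int, int] = INTERVAL_PACKETS,
    packet_period: float = 0.4,
) -> list[PromptEvent]:
    """Randomized alternating MOVE/REST prompt schedule.

    Interval lengths are drawn uniformly from the integer packet counts
    ``interval_packets[0] .. interval_packets[1]`` inclusive (discrete in
    packets so labels stay frame-aligned); the final interval is truncated
    at the session end.
    """
    lo, hi = interval_packets
    total_packets = int(round(duration / packet_period))
    if total_packets < lo:
        raise ValueError("session shorter than one prompt interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prompts, idx, label = [], 0, first_label
    while idx < total_packets:
        prompts.append(PromptEvent(label, idx))
        idx += int(rng.integers(lo, hi + 1))
        label = MOVE if label == REST else REST
    return prompts


def prompts_to_schedule(
    prompts: Sequence[PromptEvent], duration: float, packet_period: float = 0.4
) -> list[tuple[str, float]]:
    """Convert a prompt list into (state, duration-seconds) pairs."""
    total_packets = int(round(duration / packet_period))
    out = []
    for i, p in enumerate(prompts):
        end = (
            prompts[i + 1].scheduled_packet_index
            if i + 1 < len(prompts)
            else total_packets
        )
        out.append((p.label, (end - p.scheduled_packet_index) * packet_period))
    return out


def label_packets(
    packets: Sequence[EcogPacket],
    prompts: Sequence[PromptEvent],
    max_display_delay: float = 0.4,
    transition_exclusion: int = 0,
) -> list[str]:
    """Assign prompt labels to packets with a delay-to-screen guard.

    Packets from a prompt's ``scheduled_packet_index`` up to the next
    prompt receive that prompt's label.  If the prompt's display delay
    (``displayed_ts - sent_ts``) exceeded ``max_display_delay``, its first
    packet is marked UNLABELED (the on-screen instruction cannot reliably
    be matched to that frame).  ``transition_exclusion`` additionally
    marks that many packets after every prompt change UNLABELED.
    """
    idxs = [p.scheduled_packet_index for p in prompts]
    if idxs != sorted(idxs):
        raise ValueError("prompts must be sorted by scheduled_packet_index")
    labels = [UNLABELED] * len(packets)
    for i, p in enumerate(prompts):
        start = p.scheduled_packet_index
        stop = prompts[i + 1].scheduled_packet_index if i + 1 < len(prompts) else len(packets)
        for k in range(start, min(stop, len(packets))):
            labels[k] = p.label
        delay = p.displayed_ts - p.sent_ts
        late = np.isfinite(delay) and delay > max_display_delay
        n_guard = max(1 if late else 0, transition_exclusion if i > 0 else 0)
        for k in range(start, min(start + n_guard, len(packets))):
            labels[k] = UNLABELED
    return labels


def run_calibration_session(
    config: SimConfig,
    duration: float = SESSION_DURATION,
    seed: int = 0,
    mode: str = CALIBRATION_OPEN_LOOP,
    decoder=None,
    output_device=None,
    display_latency: float | Callable[[int], float] = 0.023,
    first_label: str = REST,
    verbose: bool = False,
) -> SessionRecord:
    """Run one simulated prompt-driven data-collection session.

    The prompt schedule drives the signal generator; prompt send and
    display timestamps are stamped against the session clock, with the
    client's delay-to-screen given by ``display_latency`` (a constant or a
    per-prompt callable).  In closed-loop mode a trained ``decoder``
    classifies every packet and the command is forwarded to
    ``output_device``; in open-loop mode decoded values (if a decoder is
    given) are recorded but not forwarded.
    """
    ss = np.random.SeedSequence([seed, config.seed])
    sched_seed, sig_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    prompts = schedule_prompts(duration, sched_seed, first_label=first_label)
    schedule = prompts_to_schedule(prompts, duration, config.packet_period)
    cfg = dataclasses.replace(config, seed=sig_seed)
    signal = sim.synthesize_signal(cfg, schedule)
    packets, discarded = sim.packetize(signal)

    lat = display_latency if callable(display_latency) else (lambda i: display_latency)
    for i, p in enumerate(prompts):
        p.sent_ts = p.scheduled_packet_index * cfg.packet_period
        p.displayed_ts = p.sent_ts + float(lat(i))

    decoded = None
    partial = False
    if decoder is not None:
        decoded = []
        state = None
        fz = PacketFeaturizer(mode="causal-online")
        X = fz.fit(packets).transform(packets)
        for row in X:
            cmd, prob, state = decoder.decode_step(row, state)
            decoded.append((cmd, prob))
            if mode == CLOSED_LOOP and output_device is not None:
                try:
                    output_device.send_output(cmd)
                except sim.DeviceUnavailable:
                    partial = True

    record = SessionRecord(
        mode=mode,
        packets=packets,
        prompts=prompts,
        decoded=decoded,
        loss_events=[],
        discarded=discarded,
        config=cfg,
        seed=seed,
        partial=partial,
    )
    if verbose:
        labels = record.labels
        n_move = labels.count(MOVE)
        n_rest = labels.count(REST)
        print(
            f"session: {len(packets)} packets, {record.discarded} discarded, "
            f"0 lost, labels MOVE={n_move} REST={n_rest} "
            f"UNLABELED={labels.count(UNLABELED)}"
        )
    return record


def featurize_record(
    record: SessionRecord,
    featurizer: PacketFeaturizer | None = None,
    max_display_delay: float = 0.4,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix and aligned labels for a session."""
    fz = featurizer or PacketFeaturizer()
    X = fz.fit(record.packets).transform(record.packets)
    labels = label_packets(record.packets, record.prompts, max_display_delay)
    return X, labels


# ---------------------------------------------------------------------------
# persistence

def save_session(record: SessionRecord, path: str | Path) -> None:
    rows = []
    labels = record.labels
    for p, lab in zip(record.packets, labels):
        rows.append(
            {
                "packet_index": p.packet_index,
                "t_start": p.t_start,
                "ch1": p.ch1.tolist(),
                "ch3": p.ch3.tolist(),
                "ch2_power": p.ch2_power.tolist(),
                "ch4_power": p.ch4_power.tolist(),
                "true_state": p.true_state,
                "prompt_label": lab,
            }
        )
    df = pd.DataFrame(rows)
    meta = {
        "schema": SESSION_SCHEMA,
        "mode": record.mode,
        "seed": record.seed,
        "discarded": record.discarded,
        "partial": record.partial,
        "config": dataclasses.asdict(record.config),
        "prompts": [dataclasses.asdict(p) for p in record.prompts],
        "decoded": record.decoded,
    }
    df.attrs["modbci"] = meta
    import pyarrow as pa
    import pyarrow.parquet as pq

    table = pa.Table.from_pandas(df, preserve_index=False)
    table = table.replace_schema_metadata(
        {**(table.schema.metadata or {}), b"modbci": json.dumps(meta).encode()}
    )
    pq.write_table(table, path)


def load_session(path: str | Path) -> SessionRecord:
    import pyarrow.parquet as pq

    table = pq.read_table(path)
    meta = json.loads(table.schema.metadata[b"modbci"].decode())
    if meta["schema"] != SESSION_SCHEMA:
        raise ValueError(f"unknown session schema {meta['schema']!r}")
    df = table.to_pandas()
    packets = [
        EcogPacket(
            packet_index=int(r.packet_index),
            t_start=float(r.t_start),
            ch1=np.asarray(r.ch1),
            ch3=np.asarray(r.ch3),
            ch2_power=np.asarray(r.ch2_power),
            ch4_power=np.asarray(r.ch4_power),
            true_state=r.true_state,
        )
        for r in df.itertuples()
    ]
    prompts = [PromptEvent(**p) for p in meta["prompts"]]
    cfg_d = meta["config"]
    for key in ("beta_band", "power_band"):
        cfg_d[key] = tuple(cfg_d[key])
    return SessionRecord(
        mode=meta["mode"],
        packets=packets,
        prompts=prompts,
        decoded=[tuple(d) for d in meta["decoded"]] if meta["decoded"] else None,
        loss_events=[],
        discarded=meta["discarded"],
        config=SimConfig(**cfg_d),
        seed=meta["seed"],
        partial=meta["partial"],
    )


# ---------------------------------------------------------------------------
# benchmark

@dataclasses.dataclass
class BenchmarkReport:
    """Held-out decoding performance over a multi-session benchmark."""

    train_accuracies: list[float]
    test_accuracies: list[float]
    n_train_sessions: int
    n_test_sessions: int
    training_minutes: float

    @property
    def median_test_accuracy(self) -> float:
        return float(np.median(self.test_accuracies))

    def __str__(self) -> str:
        return (
            f"benchmark: {self.n_train_sessions} training + {self.n_test_sessions} "
            f"held-out sessions ({self.training_minutes:.0f} min training data); "
            f"median held-out windowed accuracy "
            f"{100 * self.median_test_accuracy:.2f}%"
        )


def run_benchmark(
    config: SimConfig | None = None,
    n_train: int = 33,
    n_test: int = 17,
    duration: float = SESSION_DURATION,
    seed: int = 0,
    decoder=None,
    transition_exclusion: int = 1,
    noise_factors: Sequence[float] | None = None,
) -> tuple["MotorImageryDecoder", BenchmarkReport]:
    """Train on ``n_train`` sessions and evaluate on ``n_test`` held out.

    ``noise_factors``, if given, scales the background-noise amplitudes of
    test session ``i`` by ``noise_factors[i]`` (slow noise-floor drift
    across months of use).
    """
    from .decoder import MotorImageryDecoder, evaluate

    cfg = config or SimConfig()
    Xs, ys, lens = [], [], []
    for i in range(n_train):
        rec = run_calibration_session(cfg, duration, seed=seed * 10_000 + i)
        X, labels = featurize_record(rec)
        Xs.append(X)
        ys.append(labels)
        lens.append(len(X))
    model = decoder or MotorImageryDecoder()
    model.fit(np.vstack(Xs), np.concatenate(ys), sequence_lengths=lens)
    train_acc = [
        evaluate(model, X, y, transition_exclusion).accuracy
        for X, y in zip(Xs, ys)
    ]

    test_acc = []
    for i in range(n_test):
        tc = cfg
        if noise_factors is not None:
            f = float(noise_factors[i])
            tc = dataclasses.replace(
                cfg,
                pink_noise_scale=cfg.pink_noise_scale * f,
                white_noise_scale=cfg.white_noise_scale * f,
            )
        rec = run_calibration_session(tc, duration, seed=seed * 10_000 + 5_000 + i)
        X, labels = featurize_record(rec)
        test_acc.append(evaluate(model, X, labels, transition_exclusion).accuracy)

    report = BenchmarkReport(
        train_accuracies=train_acc,
        test_accuracies=test_acc,
        n_train_sessions=n_train,
        n_test_sessions=n_test,
        training_minutes=n_train * duration / 60.0,
    )
    return model, report
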