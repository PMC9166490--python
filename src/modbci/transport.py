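"""GATT-style chunked message transport.

Three logical characteristics (settings, status, calibration) carry
framed messages between the controller and the client.  Each transfer is
capped at a 512-byte MTU, so messages are split into chunks with a fixed
12-byte little-endian header (message_id, chunk_index, total_chunks; 4
bytes each) and reassembled in order on the far side.  Exactly one
message may be in flight per characteristic at a time; concurrency comes
from multiplexing across characteristics.

The default link is an in-process duplex queue pair with deterministic
delivery; "notify" is modeled as a server-push callback on a
characteristic.  A :class:`DelayMonitor` aggregates prompt delay-to-screen
measurements (sent timestamp vs client display acknowledgment).
"""

from __future__ import annotations

import dataclasses
import enum
import struct
from collections import deque
from typing import Callable, Sequence

MTU = 512
_HEADER = struct.Struct("<III")  # message_id, chunk_index, total_chunks
HEADER_SIZE = _HEADER.size       # 12 bytes


class Characteristic(enum.Enum):
    SETTINGS = "settings"
    STATUS = "status"
    CALIBRATION = "calibration"


class ProtocolError(RuntimeError):
    pass


class ReassemblyTimeout(ProtocolError):
    pass


@dataclasses.dataclass
class TransportMessage:
    characteristic: Characteristic
    message_id: int
    payload: bytes


@dataclasses.dataclass
class Chunk:
    message_id: int
    chunk_index: int
    total_chunks: int
    body: bytes

    def __post_init__(self) -> None:
        if not 0 <= self.chunk_index < self.total_chunks:
            raise ProtocolError("chunk_index must be < total_chunks")
        if len(self.body) > MTU - HEADER_SIZE:
            raise ProtocolError(f"chunk body exceeds MTU-{HEADER_SIZE} bytes")

    def to_bytes(self) -> bytes:
        return _HEADER.pack(self.message_id, self.chunk_index, self.total_chunks) + self.body

    @classmethod
    def from_bytes(cls, raw: bytes) -> "Chunk":
        if len(raw) < HEADER_SIZE or len(raw) > MTU:
            raise ProtocolError("chunk size outside [header, MTU]")
        mid, idx, total = _HEADER.unpack_from(raw)
        return cls(mid, idx, total, raw[HEADER_SIZE:])


def chunk_message(msg: TransportMessage, mtu: int = MTU) -> list[Chunk]:
    """Split a message payload into MTU-bounded chunks.

    An empty payload still produces one header-only chunk so the receiver
    sees the message.
    """
    body_size = mtu - HEADER_SIZE
    if body_size <= 0:
        raise ProtocolError(f"mtu must exceed the {HEADER_SIZE}-byte header")
    payload = msg.payload
    total = max(1, -(-len(payload) // body_size))  # ceil, min 1
    return [
        Chunk(msg.message_id, i, total, payload[i * body_size: (i + 1) * body_size])
        for i in range(total)
    ]


def reassemble(
    chunks: Sequence[Chunk], characteristic: Characteristic = Characteristic.SETTINGS
) -> TransportMessage:
    """Exact inverse of :func:`chunk_message` for in-order chunks."""
    if not chunks:
        raise ReassemblyTimeout("no chunks received")
    mid = chunks[0].message_id
    total = chunks[0].total_chunks
    for c in chunks:
        if c.message_id != mid:
            raise ProtocolError(
                f"interleaved message_ids {mid} and {c.message_id} on one characteristic"
            )
        if c.total_chunks != total:
            raise ProtocolError(f"inconsistent total_chunks in message {mid}")
    indices = [c.chunk_index for c in chunks]
    if indices != list(range(total)):
        missing = sorted(set(range(total)) - set(indices))
        if missing:
            raise ReassemblyTimeout(
                f"timeout waiting for chunks {missing} of message {mid}"
            )
        raise ProtocolError(f"out-of-order chunks in message {mid}")
    return TransportMessage(characteristic, mid, b"".join(c.body for c in chunks))


class _Endpoint:
    """One side of the duplex link."""

    def __init__(self) -> None:
        self.queues: dict[Characteristic, deque[list[Chunk]]] = {
            c: deque() for c in Characteristic
        }
        self.notify_callbacks: dict[Characteristic, Callable] = {}
        self.peer: "_Endpoint | None" = None
        self._next_message_id = 0

    def send(self, characteristic: Characteristic, payload: bytes) -> int:
        """Chunk a payload and deliver it in order to the peer.

        Returns the message id.  If the peer registered a notify callback
        on the characteristic the reassembled message is pushed
        synchronously; otherwise it queues for a later ``receive``.
        """
        mid = self._next_message_id
        self._next_message_id += 1
        msg = TransportMessage(characteristic, mid, bytes(payload))
        chunks = chunk_message(msg)
        # wire round-trip: serialize/parse each chunk as on a real link
        wire = [Chunk.from_bytes(c.to_bytes()) for c in chunks]
        cb = self.peer.notify_callbacks.get(characteristic)
        if cb is not None:
            cb(reassemble(wire, characteristic))
        else:
            self.peer.queues[characteristic].append(wire)
        return mid

    def receive(self, characteristic: Characteristic) -> TransportMessage | None:
        q = self.queues[characteristic]
        if not q:
            return None
        return reassemble(q.popleft(), characteristic)

    def pending(self, characteristic: Characteristic) -> int:
        return len(self.queues[characteristic])

    def on_notify(self, characteristic: Characteristic, callback: Callable) -> None:
        self.notify_callbacks[characteristic] = callback


class BleLink:
    """An in-process duplex queue pair standing in for a BLE connection."""

    def __init__(self) -> None:
        self.server = _Endpoint()
        self.client = _Endpoint()
        self.server.peer = self.client
        self.client.peer = self.server


@dataclasses.dataclass
class DelayStats:
    mean: float
    max: float
    count: int
    over_threshold: int


class DelayMonitor:
    """Aggregates prompt delay-to-screen measurements for one session."""

    def __init__(self, threshold: float = 0.4) -> None:
        self.threshold = threshold
        self.delays: list[float] = []

    def record(self, sent_ts: float, displayed_ts: float) -> float:
        delay = displayed_ts - sent_ts
        if delay < 0:
            raise ProtocolError(
                f"clock contract violated: displayed_ts {displayed_ts} < sent_ts {sent_ts}"
            )
        self.delays.append(delay)
        return delay

    def stats(self) -> DelayStats:
        if not self.delays:
            return DelayStats(0.0, 0.0, 0, 0)
        return DelayStats(
            mean=sum(self.delays) / len(self.delays),
            max=max(self.delays),
            count=len(self.delays),
            over_threshold=sum(d > self.threshold for d in self.delays),
        )


def measure_display_delay(sent_ts: float, displayed_ts: float) -> float:
    """Delay-to-screen of one prompt; negative deltas violate the clock contract."""
    if displayed_ts < sent_ts:
        raise ProtocolError("displayed_ts precedes sent_ts")
    return displayed_ts - sent_ts
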