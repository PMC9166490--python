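"""The controller main loop.

Mirrors the two cooperating event loops of the platform: one path
iteratively pulls decoded samples from the selected input device and
forwards the command to the selected output device; the other services
client requests arriving over the transport (device enumeration, setting
reads/writes, calibration control).  Requests are serviced at packet
boundaries, so a pending settings read never delays the decode path
across a frame, and the decode path never starves the request handler.

Every loop iteration is logged with timestamps partitioning it into an
acquire+decode span and a send span, the structure used for latency
profiling.  Device failures surface on the status characteristic and idle
the affected path; they never terminate the loop.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

from .devices import DeviceRegistry, SettingError, RegistrationError
from .simulator import DeviceUnavailable, SimClock
from .transport import BleLink, Characteristic, DelayMonitor


@dataclasses.dataclass
class IterationLog:
    """Per-iteration profiling record."""

    packet_number: int
    acquire_start: float
    decode_done: float
    send_done: float
    command: str | None

    @property
    def acquire_decode_span(self) -> float:
        return self.decode_done - self.acquire_start

    @property
    def send_span(self) -> float:
        return self.send_done - self.decode_done


class Controller:
    """Runs the decode path and the transport request handler cooperatively."""

    def __init__(
        self,
        registry: DeviceRegistry,
        link: BleLink | None = None,
        clock: SimClock | None = None,
    ) -> None:
        self.registry = registry
        self.link = link or BleLink()
        self.clock = clock or SimClock()
        self.delay_monitor = DelayMonitor()
        self.iteration_log: list[IterationLog] = []
        self.status_log: list[dict] = []
        self.closed_loop = True

    # -- status ----------------------------------------------------------

    def _publish_status(self, **fields: Any) -> None:
        record = {"t": self.clock.now(), **fields}
        self.status_log.append(record)
        self.link.server.send(
            Characteristic.STATUS, json.dumps(record).encode()
        )

    # -- request handling -------------------------------------------------

    def service_requests(self, limit: int | None = None) -> int:
        """Handle pending settings-characteristic requests; returns count."""
        handled = 0
        while limit is None or handled < limit:
            msg = self.link.server.receive(Characteristic.SETTINGS)
            if msg is None:
                break
            try:
                reply = self._handle(json.loads(msg.payload.decode()))
            except (SettingError, RegistrationError, DeviceUnavailable, ValueError) as e:
                reply = {"ok": False, "error": str(e), "request_id": msg.message_id}
            self.link.server.send(
                Characteristic.SETTINGS, json.dumps(reply).encode()
            )
            handled += 1
        return handled

    def _handle(self, req: dict) -> dict:
        op = req.get("op")
        if op == "list_devices":
            devices = [
                {
                    "device_id": d.device_id,
                    "kind": d.kind,
                    "display_name": d.display_name,
                    "connected": d.connected,
                }
                for d in self.registry.enumerate()
            ]
            return {"ok": True, "devices": devices}
        if op == "get_settings":
            dev = self.registry.get(req["device_id"])
            return {
                "ok": True,
                "render_commands": [
                    json.loads(s.render().to_json()) for s in dev.settings.values()
                ],
            }
        if op == "set_setting":
            dev = self.registry.get(req["device_id"])
            s = dev.apply_setting(req["name"], req["value"])
            return {"ok": True, "render_command": json.loads(s.render().to_json())}
        if op == "select_device":
            self.registry.select(req["device_id"])
            return {"ok": True}
        raise ValueError(f"unknown request op {op!r}")

    # -- decode path -------------------------------------------------------

    def run(self, n_packets: int) -> list[IterationLog]:
        """Run the decode loop for ``n_packets`` iterations.

        Each iteration: block for the next decoded input sample, forward
        the command to the output device (when closed-loop and selected),
        then drain pending transport requests before the next frame.
        """
        logs = []
        for k in range(n_packets):
            t0 = self.clock.now()
            inp = self.registry.input_device()
            command = None
            if inp is None or not inp.connected:
                self._publish_status(event="input-unavailable")
                self.clock.advance(0.4)  # idle one frame, keep serving requests
                t1 = t2 = self.clock.now()
            else:
                try:
                    sample = inp.get_input()
                    command = sample.command
                    t1 = self.clock.now()
                    out = self.registry.output_device()
                    if command is not None and self.closed_loop and out is not None:
                        try:
                            out.send_output(command)
                        except DeviceUnavailable:
                            self._publish_status(
                                event="output-unavailable",
                                device=getattr(out, "device_id", None),
                            )
                    t2 = self.clock.now()
                except StopIteration:
                    self._publish_status(event="input-exhausted")
                    break
                except DeviceUnavailable:
                    self._publish_status(event="input-unavailable")
                    self.clock.advance(0.4)
                    t1 = t2 = self.clock.now()
            log = IterationLog(k, t0, t1, t2, command)
            logs.append(log)
            self.iteration_log.append(log)
            # cooperative slice for the BLE side: zero-cost at frame boundary
            self.service_requests()
        return logs

    # -- calibration -------------------------------------------------------

    def push_prompt(self, label: str) -> float:
        """Send a prompt text over the calibration characteristic.

        Returns the send timestamp; the client acks with its display
        timestamp via :meth:`ack_prompt`.
        """
        sent_ts = self.clock.now()
        self.link.server.send(
            Characteristic.CALIBRATION,
            json.dumps({"prompt": label, "sent_ts": sent_ts}).encode(),
        )
        return sent_ts

    def ack_prompt(self, sent_ts: float, displayed_ts: float) -> float:
        return self.delay_monitor.record(sent_ts, displayed_ts)
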