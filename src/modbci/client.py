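"""Headless client: a scripted stand-in for the mobile application.

Talks to the controller exclusively over the transport's three
characteristics: settings requests/replies on the settings
characteristic, server-pushed status records on the status
characteristic, and prompt texts on the calibration characteristic,
which it acknowledges with a display timestamp after a configurable
simulated latency.
"""

from __future__ import annotations

import json

from .controller import Controller
from .transport import BleLink, Characteristic


class ClientError(RuntimeError):
    pass


class HeadlessClient:
    """Scripted client over one end of a :class:`BleLink`."""

    def __init__(
        self,
        link: BleLink,
        controller: Controller | None = None,
        display_latency: float = 0.023,
    ) -> None:
        self.link = link
        self.controller = controller
        self.display_latency = display_latency
        self.prompts_seen: list[str] = []
        self.status_seen: list[dict] = []
        self.link.client.on_notify(Characteristic.STATUS, self._on_status)
        self.link.client.on_notify(Characteristic.CALIBRATION, self._on_prompt)

    # -- notify handlers ---------------------------------------------------

    def _on_status(self, msg) -> None:
        self.status_seen.append(json.loads(msg.payload.decode()))

    def _on_prompt(self, msg) -> None:
        body = json.loads(msg.payload.decode())
        self.prompts_seen.append(body["prompt"])
        if self.controller is not None:
            self.controller.ack_prompt(
                body["sent_ts"], body["sent_ts"] + self.display_latency
            )

    # -- request/response --------------------------------------------------

    def _request(self, req: dict) -> dict:
        mid = self.link.client.send(Characteristic.SETTINGS, json.dumps(req).encode())
        if self.controller is not None:
            self.controller.service_requests()
        reply = self.link.client.receive(Characteristic.SETTINGS)
        if reply is None:
            raise ClientError(f"no reply to request (message_id {mid})")
        body = json.loads(reply.payload.decode())
        if not body.get("ok", False):
            raise ClientError(
                f"request failed (message_id {mid}): {body.get('error')}"
            )
        return body

    def list_devices(self) -> list[dict]:
        return self._request({"op": "list_devices"})["devices"]

    def get_settings(self, device_id: str) -> list[dict]:
        return self._request({"op": "get_settings", "device_id": device_id})[
            "render_commands"
        ]

    def set_setting(self, device_id: str, name: str, value) -> dict:
        return self._request(
            {"op": "set_setting", "device_id": device_id, "name": name, "value": value}
        )["render_command"]

    def select_device(self, device_id: str) -> None:
        self._request({"op": "select_device", "device_id": device_id})
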