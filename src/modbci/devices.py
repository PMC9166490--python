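"""Plug-in device framework.

Every piece of hardware the platform talks to is wrapped in a class
implementing the abstract device contract: input devices expose
``get_input`` (collect one telemetry frame, decode it, return a command),
output devices expose ``send_output`` (actuate on a command).  Devices
declare user-adjustable settings as :class:`DeviceSetting` objects, which
the framework turns into :class:`RenderCommand` widgets for the remote
client.  A :class:`DeviceRegistry` discovers device classes from plug-in
files at startup, so the controller never branches on a concrete device
type.
"""

from __future__ import annotations

import dataclasses
import importlib.util
import json
import sys
from pathlib import Path
from typing import Any, Sequence

from .decoder import MotorImageryDecoder
from .features import PacketFeaturizer
from .simulator import DeviceUnavailable, MOVE, REST, Telemeter

INPUT = "input"
OUTPUT = "output"


class RegistrationError(ValueError):
    pass


class ContractError(TypeError):
    pass


class SettingError(ValueError):
    pass


@dataclasses.dataclass
class DeviceSetting:
    """One user-adjustable device property.

    ``bounds_or_choices`` is a (lo, hi) numeric range for ``number``
    settings, ignored for ``boolean``, and a finite sequence for
    ``choice``.  ``current`` is validated on construction and on every
    mutation; immutable settings reject mutation.
    """

    name: str
    value_type: str  # number | boolean | choice
    current: Any
    bounds_or_choices: Any = None
    mutable: bool = True

    def __post_init__(self) -> None:
        if self.value_type not in ("number", "boolean", "choice"):
            raise SettingError(f"unknown value_type {self.value_type!r}")
        self._validate(self.current)

    def _validate(self, value: Any) -> Any:
        if self.value_type == "number":
            lo, hi = self.bounds_or_choices
            value = float(value)
            if not lo <= value <= hi:
                raise SettingError(
                    f"{self.name}={value} outside bounds [{lo}, {hi}]"
                )
        elif self.value_type == "boolean":
            if not isinstance(value, bool):
                raise SettingError(f"{self.name} expects a boolean")
        else:
            if value not in tuple(self.bounds_or_choices):
                raise SettingError(
                    f"{self.name}={value!r} not in choices {tuple(self.bounds_or_choices)}"
                )
        return value

    def set(self, value: Any) -> "DeviceSetting":
        if not self.mutable:
            raise SettingError(f"setting {self.name!r} is immutable")
        self.current = self._validate(value)
        return self

    # -- client rendering ------------------------------------------------

    _WIDGETS = {"number": "slider", "boolean": "toggle", "choice": "dropdown"}

    def render(self) -> "RenderCommand":
        payload = {
            "current": self.current,
            "mutable": self.mutable,
            "value_type": self.value_type,
        }
        if self.value_type == "number":
            payload["bounds"] = list(self.bounds_or_choices)
        elif self.value_type == "choice":
            payload["choices"] = list(self.bounds_or_choices)
        return RenderCommand(self.name, self._WIDGETS[self.value_type], payload)


@dataclasses.dataclass
class RenderCommand:
    """A widget description sent to the client for one setting."""

    target_setting: str
    widget_hint: str  # slider | toggle | dropdown | button
    payload: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RenderCommand":
        return cls(**json.loads(s))


@dataclasses.dataclass
class DeviceDescriptor:
    """Registry-facing metadata for one device."""

    device_id: str
    kind: str  # input | output
    display_name: str
    settings: list[DeviceSetting]
    connected: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (INPUT, OUTPUT):
            raise RegistrationError(f"kind must be input or output, got {self.kind!r}")


@dataclasses.dataclass
class DecodedSample:
    """One decoded command returned by an input device."""

    command: str
    probability: float
    timestamp: float


class Device:
    """Abstract device contract.

    Subclasses define ``device_id``, ``kind`` and ``display_name``, may
    populate ``settings``, and implement ``get_input`` (input devices) or
    ``send_output`` (output devices).  ``on_setting_changed`` is invoked
    after a successful mutation so behavior reflects the new value on the
    next cycle.
    """

    device_id: str = ""
    kind: str = ""
    display_name: str = ""

    def __init__(self) -> None:
        self.settings: dict[str, DeviceSetting] = {}
        self.connected = True

    def descriptor(self) -> DeviceDescriptor:
        return DeviceDescriptor(
            self.device_id,
            self.kind,
            self.display_name,
            list(self.settings.values()),
            self.connected,
        )

    def add_setting(self, setting: DeviceSetting) -> None:
        self.settings[setting.name] = setting

    def apply_setting(self, name: str, value: Any) -> DeviceSetting:
        if name not in self.settings:
            raise SettingError(f"unknown setting {name!r}")
        s = self.settings[name].set(value)
        self.on_setting_changed(name, s.current)
        return s

    def on_setting_changed(self, name: str, value: Any) -> None:
        pass

    def connect(self) -> None:
        self.connected = True

    def disconnect(self) -> None:
        self.connected = False

    def _require_connected(self) -> None:
        if not self.connected:
            raise DeviceUnavailable(f"device {self.device_id!r} is disconnected")


def _check_contract(device: Device) -> None:
    for attr in ("device_id", "kind", "display_name"):
        if not getattr(device, attr, ""):
            raise ContractError(f"device missing required attribute {attr!r}")
    if device.kind == INPUT and not callable(getattr(device, "get_input", None)):
        raise ContractError("input device must define get_input")
    if device.kind == OUTPUT and not callable(getattr(device, "send_output", None)):
        raise ContractError("output device must define send_output")
    if device.kind not in (INPUT, OUTPUT):
        raise ContractError(f"unknown device kind {device.kind!r}")


class DeviceRegistry:
    """Holds registered devices; enumeration covers connected ones only."""

    def __init__(self) -> None:
        self._devices: dict[str, Device] = {}
        self.selected_input: str | None = None
        self.selected_output: str | None = None

    def register(self, device: Device) -> Device:
        _check_contract(device)
        if device.device_id in self._devices:
            raise RegistrationError(f"duplicate device_id {device.device_id!r}")
        self._devices[device.device_id] = device
        return device

    def get(self, device_id: str) -> Device:
        try:
            return self._devices[device_id]
        except KeyError:
            raise RegistrationError(f"no such device {device_id!r}") from None

    def enumerate(self, kind: str | None = None) -> list[DeviceDescriptor]:
        return [
            d.descriptor()
            for d in self._devices.values()
            if d.connected and (kind is None or d.kind == kind)
        ]

    def select(self, device_id: str) -> Device:
        d = self.get(device_id)
        if not d.connected:
            raise DeviceUnavailable(f"device {device_id!r} is disconnected")
        if d.kind == INPUT:
            self.selected_input = device_id
        else:
            self.selected_output = device_id
        return d

    def input_device(self) -> Device | None:
        return self._devices.get(self.selected_input) if self.selected_input else None

    def output_device(self) -> Device | None:
        return self._devices.get(self.selected_output) if self.selected_output else None

    def discover(self, plugin_dir: str | Path, context: dict | None = None) -> list[Device]:
        """Scan a plug-in directory and register the devices it declares.

        Each ``*.py`` file in the directory is imported and must define a
        module-level ``create_devices(context) -> list[Device]`` factory.
        """
        registered = []
        for path in sorted(Path(plugin_dir).glob("*.py")):
            name = f"modbci_plugin_{path.stem}"
            spec = importlib.util.spec_from_file_location(name, path)
            mod = importlib.util.module_from_spec(spec)
            sys.modules[name] = mod
            spec.loader.exec_module(mod)
            factory = getattr(mod, "create_devices", None)
            if factory is None:
                raise ContractError(f"plugin {path.name} defines no create_devices")
            for dev in factory(context or {}):
                registered.append(self.register(dev))
        return registered


# ---------------------------------------------------------------------------
# concrete devices

class TelemeterInputDevice(Device):
    """The simulated implanted telemeter wrapped as an input device.

    ``get_input`` blocks on the simulated clock until the next telemetry
    frame completes, featurizes it with carried FIR state, advances the
    decoder's forward recursion one step, and returns the decoded command
    with its movement probability and the frame completion time.  The
    decoder threshold is exposed as a mutable device setting.
    """

    kind = INPUT

    def __init__(
        self,
        telemeter: Telemeter,
        decoder: MotorImageryDecoder | None = None,
        device_id: str = "sim-telemeter",
        display_name: str = "Simulated ECoG telemeter",
    ) -> None:
        super().__init__()
        self.device_id = device_id
        self.display_name = display_name
        self.telemeter = telemeter
        self.decoder = decoder
        self._decode_state = None
        self._featurizer = PacketFeaturizer(mode="causal-online")
        self._filter_states: tuple | None = None
        if decoder is not None:
            self.add_setting(
                DeviceSetting("threshold", "number", decoder.threshold, (0.0, 1.0))
            )

    def on_setting_changed(self, name: str, value: Any) -> None:
        if name == "threshold" and self.decoder is not None:
            self.decoder.threshold = value

    def get_input(self) -> DecodedSample:
        self._require_connected()
        if not self.telemeter.connected:
            raise DeviceUnavailable("telemeter stream unavailable")
        packet = self.telemeter.read_packet()
        from .features import build_feature_vector, FilterSpec

        fv, self._filter_states = build_feature_vector(
            packet, FilterSpec(mode="causal-online"), self._filter_states
        )
        if self.decoder is None:
            return DecodedSample(REST, 0.0, self.telemeter.clock.now())
        cmd, prob, self._decode_state = self.decoder.decode_step(fv, self._decode_state)
        return DecodedSample(cmd, prob, self.telemeter.clock.now())

    def disconnect(self) -> None:
        super().disconnect()
        self.telemeter.connected = False

    def connect(self) -> None:
        super().connect()
        self.telemeter.connected = True


class ReplayInputDevice(Device):
    """Input device replaying pre-decoded samples (e.g. from a session file).

    Exists so contract tests can swap the live simulator for a replayed
    stream without the controller noticing.
    """

    kind = INPUT

    def __init__(self, samples: Sequence[DecodedSample], device_id: str = "replay"):
        super().__init__()
        self.device_id = device_id
        self.display_name = "Session replay"
        self._samples = list(samples)
        self._i = 0

    def get_input(self) -> DecodedSample:
        self._require_connected()
        if self._i >= len(self._samples):
            raise StopIteration("replay exhausted")
        s = self._samples[self._i]
        self._i += 1
        return s


GLOVE_OPEN = "open"
GLOVE_GRASPING = "grasping"


class SimulatedGloveDevice(Device):
    """A motorized grasp-assist glove: MOVE closes, REST opens.

    Repeated identical commands are idempotent (one physical transition,
    one acknowledgment per command).
    """

    kind = OUTPUT

    def __init__(self, device_id: str = "sim-glove") -> None:
        super().__init__()
        self.device_id = device_id
        self.display_name = "Simulated prosthetic glove"
        self.state = GLOVE_OPEN
        self.transitions = 0
        self.add_setting(
            DeviceSetting("actuation_speed", "choice", "medium", ("slow", "medium", "fast"))
        )

    def send_output(self, command: str) -> dict:
        self._require_connected()
        if command not in (MOVE, REST):
            raise ValueError(f"unknown command {command!r}")
        target = GLOVE_GRASPING if command == MOVE else GLOVE_OPEN
        changed = target != self.state
        if changed:
            self.state = target
            self.transitions += 1
        return {"ack": True, "state": self.state, "changed": changed}
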