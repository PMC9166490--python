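# modbci

A modular, hardware-free at-home brain–computer interface (BCI) platform.
`modbci` reproduces, entirely in software, the architecture of a take-home
ECoG motor-imagery BCI: an implanted sensing device streams packetized
neural telemetry to a bedside controller, a trained decoder turns each
packet into a MOVE/REST command, and the command actuates a prosthetic
grasp-assist glove — with a mobile client attached over a low-energy
chunked transport for calibration and settings.

Every hardware component is replaced by a faithful simulator, so the whole
closed loop — signal generation, telemetry with overwrite loss, feature
extraction, decoding, actuation, and client communication — is testable
and reproducible on one machine. It is aimed at BCI researchers and
engineers who want to prototype decoder chains, device plug-ins, or
protocol changes without an implanted subject.

## What it contains

- **ECoG simulator** (`modbci.simulator`): two 200 Hz time channels
  (pink 1/f background + band-limited 12–25 Hz beta oscillation + white
  noise) and two 5 Hz band-power channels (4–36 Hz). Motor imagery
  (MOVE) attenuates the beta amplitude by a factor `1 − d`
  (event-related desynchronization, default `d = 0.8`). Telemetry is cut
  into 400 ms packets (80 samples/channel, 2 power samples/channel) read
  through a single-slot overwrite store: polling more than one frame late
  loses the skipped frames.
- **Feature pipeline** (`modbci.features`): 1 Hz high-pass FIR filtering,
  then per-packet Hann periodograms zero-padded to 640 points — 321
  spectral bins per time channel — concatenated with the per-packet mean
  of each power channel: a 644-dimensional feature vector per packet.
- **Decoder** (`modbci.decoder`): `MotorImageryDecoder`, a scikit-learn
  style classifier implementing the chain

  `x ∈ ℝ⁶⁴⁴ → log/standardize → LDA score s = wᵀx + b →`
  `2-state HMM forward posterior P(MOVE | s₁..sₜ) → logistic regression →`
  `command = MOVE iff P ≥ threshold`

  trained fully supervised (label-counted transitions with add-one
  smoothing, Gaussian emission MLE on the LDA score) and therefore
  deterministic.
- **Device framework** (`modbci.devices`): an abstract device contract
  (`get_input` / `send_output`), a registry with plug-in directory
  discovery, and user-adjustable `DeviceSetting` objects rendered to the
  client as widgets.
- **Calibration protocol** (`modbci.protocol`): alternating MOVE/REST
  prompts at random 6–10 s (15–25 packet) intervals, 5-minute sessions of
  750 packets, prompt-to-packet label alignment with a 400 ms
  delay-to-screen guard, Parquet session persistence, and the
  33-training + 17-held-out session benchmark.
- **Transport & client** (`modbci.transport`, `modbci.controller`,
  `modbci.client`): three GATT-style characteristics (settings, status,
  calibration), 512-byte-MTU chunked framing with a 12-byte header,
  a controller loop that interleaves decoding with request handling
  without losing telemetry, and a headless scripted client.

## Worked example

```
$ modbci calibrate --minutes 5 --seed 1 --out s1.parquet
session: 750 packets, 0 discarded, 0 lost, labels MOVE=371 REST=379 UNLABELED=0
session written to s1.parquet
$ modbci calibrate --minutes 5 --seed 2 --out s2.parquet
$ modbci calibrate --minutes 5 --seed 3 --out s3.parquet
$ modbci train s1.parquet s2.parquet --model-out model.json
model trained on 2 sessions (1500 packets, 10.0 min) -> model.json
$ modbci evaluate s3.parquet --model model.json
windowed accuracy 0.9789 over 712 packets (38 excluded; per-class REST: 0.970, MOVE: 0.988)
$ modbci run --seconds 60 --seed 4 --model model.json --closed-loop
150 packets processed; glove state open (8 transitions)
```

Each 5-minute calibration session delivers 750 packets (60,000 samples
per time channel) with roughly balanced MOVE/REST labels. Training on two
sessions (10 min of data) already decodes a held-out session at 97.9%
windowed accuracy — the fraction of labeled packets classified correctly
after excluding one packet following each prompt change (reaction-time
guard, the 38 excluded packets). The closed-loop run decodes 150 packets
in 60 s and actuates the simulated glove (8 open/close transitions,
finishing open). With the full default benchmark (33 training + 17
held-out sessions, `modbci benchmark`), median held-out accuracy is
essentially at ceiling under the default simulator conditions.

The same flow is available as a library:

```python
from modbci import SimConfig, run_benchmark
model, report = run_benchmark(SimConfig(), n_train=33, n_test=17, seed=1)
print(report)          # median held-out windowed accuracy ...
model.save("model.json")
```

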