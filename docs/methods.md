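# Methods

## The problem

A motor-imagery BCI decodes intent (here: imagined rapid hand
open/close vs rest) from sensorimotor cortical activity and turns it into
an actuation command for an end effector. The physiological signature
exploited is event-related desynchronization (ERD): a drop in
band-limited beta power (12–25 Hz) over motor cortex during movement or
motor imagery. `modbci` implements the full platform around that
signature with simulated hardware, so the statistical and systems
behavior of the chain can be studied and regression-tested without a
subject.

## Signal model (simulator)

Each of the two time channels is

```
x(t) = A(t)·β(t) + σ_pink·p(t) + σ_white·w(t)
```

where `β(t)` is unit-variance Gaussian noise band-passed to 12–25 Hz
(4th-order Butterworth) — a narrow-band stochastic oscillation rather
than a sinusoid, giving realistic spectra — `p(t)` is unit-variance 1/f
(pink) noise generated by spectral shaping, and `w(t)` is white noise.
The amplitude envelope is state-dependent:

```
A(t) = A_rest          in REST
A(t) = (1 − d)·A_rest  in MOVE        (ERD depth d ∈ [0, 1])
```

so the generative MOVE/REST beta power ratio is `(1 − d)²`. The two
channels share the envelope (they model a bipolar pair over the same
cortical region) but have independent carriers and noise. State changes
reach the signal after a neuromotor lag (default 300 ms) emulating
reaction time.

Defaults: `A_rest = 2.0`, `σ_pink = 1.0`, `σ_white = 0.2`, `d = 0.8`,
200 Hz sampling. These values put roughly 4 units of in-band beta power
over ~0.13 units of in-band background in REST — a clearly separable,
favorable regime chosen to represent a well-placed subdural electrode
pair. Amplitudes are in arbitrary units: the decoder standardizes
features, so absolute calibration is irrelevant.

The on-board power channels (5 Hz) are emulated as trailing 200 ms mean
squared amplitude of the 4–36 Hz band-passed signal. The actual estimator
of the real implanted device is undisclosed; ours is a plausible stand-in
computed from the same realization, so feature-consistency checks are
exact.

**Telemetry.** The signal is cut into 400 ms frames (80 samples/channel,
2 power samples/channel). The telemeter models a single-slot store
overwritten at 2.5 Hz: a read blocks until the next unread frame
completes; a reader arriving more than one full frame late receives only
the latest completed frame and the gap is recorded as a loss event. With
inter-poll interval Δ ≥ 400 ms, the number of lost frames is
`floor(Δ/0.4) − 1`.

**ERD recovery.** `estimate_erd_ratio` measures beta power *above the
pink background* (log–log linear fit over 5–9 Hz and 31–38 Hz flanking
bands, interpolated under 12–25 Hz and subtracted) separately in MOVE and
REST segments, excluding 0.5 s around state changes. This
background-subtracted ratio converges to `(1 − d)²` (within ~2–3% at 5
minutes per state under defaults); the raw in-band ratio would be biased
upward by the noise floor.

## Feature extraction

1. **High-pass filter**: 1 Hz FIR, Hamming windowed-sinc realized by
   spectral inversion of the complementary low-pass, 301 taps (1.5 s).
   Spectral inversion nulls DC exactly; 301 taps is the shortest Hamming
   design whose passband above 2 Hz stays within ±0.05 of unity while
   attenuating 0.1 Hz by >20 dB. Offline (training) mode uses zero-phase
   forward–backward filtering of the whole session; online mode streams
   causally with carried state (group delay 150 samples ≈ 0.75 s, under
   two packets, absorbed by the transition-exclusion window).
2. **Per-packet spectrum**: Hann-windowed periodogram of the 80-sample
   packet, zero-padded to nfft = 640 — the only length for which
   `640/2 + 1 = 321` bins per channel arise from per-packet computation.
   Bin `k` maps to `k·0.3125` Hz; density scaling (scale cancels in
   standardization). An alternative interpretation (a sliding 3.2 s
   buffer of 640 raw samples) would also give 321 bins but is not
   per-packet; the periodogram choice is the default and the buffer
   variant was deliberately not implemented to keep one documented code
   path.
3. **Assembly**: `[psd(ch1) ‖ psd(ch3) ‖ mean(ch2_power) ‖
   mean(ch4_power)]` → 644 features. The two 5 Hz power samples per
   packet are averaged to one value per channel, the only arity
   consistent with `644 = 2×321 + 2`.

Whether the original device chain computed spectra on raw or on filtered
signals is ambiguous; we filter first and note the choice here.

## Decoder

Per packet, with `x` the 644-vector:

1. `log(x + 1e−12)`, then z-scoring with training mean/σ (zero-variance
   features dropped with a warning). The log transform stabilizes the
   heavily skewed periodogram bins (each ~ χ²₂); it is a standard
   spectral-decoding step and an extrapolation beyond the minimal chain
   description, controllable via `log_features=False`.
2. **LDA**: the binary problem admits one discriminant; the scalar score
   is `s = wᵀx̃ + b` (scikit-learn SVD solver, deterministic).
3. **2-state HMM** (REST = 0, MOVE = 1), Gaussian emissions
   `N(μ_state, σ_state)` on `s`. Estimation is *supervised*: start and
   transition probabilities from label counts with add-one (Laplace)
   smoothing — labels exist, so Baum–Welch would only add
   nondeterminism — and emission MLE per state. Online inference is the
   forward (filtered) recursion, renormalized each step; we filter rather
   than Viterbi-decode because the chain maps *state probabilities*, not
   state identities, to commands.
4. **Logistic regression** on the single feature `P(MOVE | s₁..sₜ)`,
   fit against the training labels using the forward posteriors of the
   training sequences.
5. **Threshold**: command = MOVE iff the logistic output ≥ threshold
   (tie goes to MOVE); default 0.5, exposed as a mutable device setting
   in (0, 1).

Whether the original system fed smoothed posteriors, raw forward
probabilities, or Viterbi indicators to its logistic stage is not
recoverable; we use raw forward posteriors and make no fidelity claim for
that detail. Non-finite feature vectors reject the decode step (state
unchanged, warning logged). Models serialize to a single versioned JSON
file; decoding is bitwise identical across a save/load round trip.

**Evaluation** is windowed accuracy: correctly classified packets over
labeled packets, excluding a configurable window (default 1 packet =
400 ms) after every prompt change, matching the neuromotor lag.

## Calibration protocol

Prompts alternate REST/MOVE starting with REST (a known baseline start
helps the HMM initial distribution), at intervals drawn uniformly from
{15, …, 25} packets (6–10 s). Intervals are discrete in packets so labels
stay frame-aligned; whether the original protocol drew continuous seconds
or discrete packets is ambiguous and the discrete reading was chosen. A
5-minute session therefore has 750 packets (60,000 samples per time
channel); uniform{15..25} has mean 20 packets, so sessions are
approximately label-balanced.

Label alignment: packets between consecutive prompt displays inherit the
active label; a prompt whose delay-to-screen exceeds one packet period
(400 ms) gets its first packet marked UNLABELED, since the on-screen
instruction cannot be trusted to match that frame.

The default benchmark trains on 33 five-minute sessions (165 min) and
evaluates on 17 held-out sessions, the platform's historical trial
layout; both counts are parameters, not constants.

## Transport and controller

Messages on three characteristics (settings, status, calibration) are
chunked to a 512-byte MTU with a 12-byte little-endian header
(message_id, chunk_index, total_chunks — the wire format is fixed here
since no header layout is prescribed anywhere). One message may be in
flight per characteristic; reassembly is the exact inverse of chunking,
missing chunks raise a timeout naming the message id, interleaved ids a
protocol error. The default link is an in-process duplex queue pair —
deterministic for tests, swappable for a socket; no real BLE stack is in
scope. "Notify" is a synchronous server-push callback.

The controller interleaves the decode path (blocking packet read →
decode → actuate) with request servicing at frame boundaries. Because
requests are handled in zero simulated time while the next frame
accumulates, client traffic at realistic rates can never cause telemetry
loss — mirroring the dual-event-loop design it models. Device failures
publish a status record and idle the affected path; the loop never
terminates on them.

Timestamps come from a shared simulated clock (`SimClock`), which makes
delay-to-screen measurements and loss accounting exactly reproducible;
the instrumentation (per-iteration acquire/decode/send spans, delay
monitor) reports structure, not hardware performance.

## Design choices on open points

- **One selected input, one selected output** at a time; simultaneous
  multi-device use is out of scope.
- **Disconnection is a state flag** on devices/simulators, not a
  transport exception: deterministic failure-path tests.
- **Decoded samples carry (command, probability, timestamp)** rather than
  a bare command, so clients can display confidence.
- **Plug-in discovery** scans a directory of Python files exporting
  `create_devices(context)`; the registry contract is
  mechanism-agnostic and equally satisfiable by entry points.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 33+17-session
benchmark (≈250,000 simulated packets end to end, about a minute), a
14-month drift evaluation at one 5-minute session per month, oracle
equivalences at T ≤ 12 (exhaustive enumeration over 2^T paths), 3,000-step
transition-matrix recovery, 400-poll adversarial loss schedules, and
1,000 random transport payloads. Training fixtures in unit tests use
six 3-minute sessions — enough data that the 644-dimensional LDA is
well-conditioned (with much less, e.g. under ~1,000 labeled packets, the
discriminant overfits and per-packet error rises visibly).

## Limitations

- The generator is stationary within a state: no spontaneous beta bursts,
  no 1/f slope drift within sessions, no artifacts, no electrode
  degradation. Passing the benchmark says the chain is correct and
  well-behaved under the modeled physiology, not that the accuracy
  numbers transfer to any real subject.
- The default conditions are favorable (high in-band SNR); real ECoG ERD
  is weaker and nonstationary. The ERD depth and noise scales are
  parameters precisely so harder regimes can be studied.
- The on-board power-channel estimator is a guess at undisclosed
  firmware; only its qualitative behavior (band power at 5 Hz) is
  claimed.
- Timing is simulated; no wall-clock latency claims are made anywhere.
- The logistic stage on a single posterior feature is monotone, so it
  mainly recalibrates the posterior scale; with well-separated emissions
  it is near-saturated and the threshold acts close to a posterior
  threshold.
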