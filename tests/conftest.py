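import numpy as np
import pytest

from modbci.decoder import MotorImageryDecoder
from modbci.protocol import (
    featurize_record,
    prompts_to_schedule,
    run_calibration_session,
    schedule_prompts,
)
from modbci.simulator import SimConfig, packetize, synthesize_signal


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def short_session():
    """A 60 s calibration session: (record, X, labels)."""
    record = run_calibration_session(SimConfig(seed=11), 60.0, seed=11)
    X, labels = featurize_record(record)
    return record, X, labels


@pytest.fixture(scope="session")
def short_packets():
    """60 s of packetized telemetry with a fixed prompt schedule."""
    cfg = SimConfig(seed=2)
    prompts = schedule_prompts(60.0, seed=2)
    signal = synthesize_signal(cfg, prompts_to_schedule(prompts, 60.0))
    packets, _ = packetize(signal)
    return cfg, packets


@pytest.fixture(scope="session")
def trained_model():
    """Decoder trained on six 3-minute sessions (default conditions)."""
    Xs, ys, lens = [], [], []
    for i in range(6):
        rec = run_calibration_session(SimConfig(), 180.0, seed=100 + i)
        X, labels = featurize_record(rec)
        Xs.append(X)
        ys.append(labels)
        lens.append(len(X))
    model = MotorImageryDecoder()
    model.fit(np.vstack(Xs), np.concatenate(ys), sequence_lengths=lens)
    return model
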