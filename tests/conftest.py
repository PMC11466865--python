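import numpy as np
import pytest

import coughcount as cc


@pytest.fixture(scope="session")
def grid() -> cc.FrameGrid:
    """Default 25 ms / 10 ms frame grid at the canonical 8 kHz rate."""
    return cc.FrameGrid.from_ms(cc.DEFAULT_SAMPLE_RATE)


@pytest.fixture(scope="session")
def bank() -> cc.MelFilterbank:
    return cc.build_filterbank()


@pytest.fixture(scope="session")
def benchmark400() -> cc.LabeledDataset:
    """The default 400-segment synthetic benchmark (17-dim features)."""
    return cc.benchmark_dataset(400, seed=0)


@pytest.fixture(scope="session")
def training_sessions() -> list[tuple[cc.AudioSignal, cc.SessionTruth]]:
    """Annotated 60-s sessions used to train the pipeline's classifier."""
    rng = np.random.default_rng(7)
    sessions = []
    for i in range(15):
        n_coughs = int(rng.integers(3, 9))
        sessions.append(
            cc.generate_session(
                n_coughs,
                {"speech": 2, "impact": 1, "background": 1},
                duration_s=60.0,
                seed=5000 + i,
            )
        )
    return sessions


@pytest.fixture(scope="session")
def pipeline_model(training_sessions) -> cc.CoughClassifier:
    """Classifier trained on candidates extracted through the pipeline."""
    data = cc.candidate_dataset(training_sessions, cc.RunConfig())
    return cc.train_classifier(data, seed=0)


def detect_session(signal: cc.AudioSignal, grid: cc.FrameGrid,
                   cfg: cc.EndpointConfig = cc.EndpointConfig()):
    """Endpoint detection + cough constraints over a whole session;
    returns (start_s, end_s) pairs in session time."""
    out = []
    for chunk in cc.coarse_segment(signal):
        th = cc.resolve_thresholds(chunk, grid, cfg)
        for seg in cc.apply_cough_constraints(
            cc.dual_threshold_detect(chunk, grid, th), th
        ):
            out.append((seg.session_start_s, seg.session_end_s))
    return out
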