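"""Shared fixtures: small synthetic recordings and models."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from somnonet.epoching import EpochSet
from somnonet.mvgc import MVARModel
from somnonet.synth import (
    DEFAULT_PROFILES,
    graph_to_mvar,
    make_coupling_graph,
    simulate_recording,
    _simulate_var,
)

FS = 200.0


@pytest.fixture(scope="session")
def rem_models():
    """Per-stage VAR models for a small REM-dominated night."""
    models = {}
    for k, stage in enumerate(("W", "3", "4", "REM")):
        g = make_coupling_graph(19, 4, DEFAULT_PROFILES[stage].rewiring_prob, seed=k)
        models[stage] = graph_to_mvar(g, DEFAULT_PROFILES[stage], order=3, fs=FS, seed=10 + k)
    return models


@pytest.fixture(scope="session")
def small_night(rem_models):
    """A short recording with all four analysed stages and a clean mask."""
    template = ("W",) * 4 + ("3",) * 4 + ("4",) * 4 + ("REM",) * 4
    rec, hyp, mask = simulate_recording(
        rem_models, template, fs=FS, seed=99, artifact_fraction=0.0
    )
    return rec, hyp, mask


@pytest.fixture(scope="session")
def var3_segments():
    """12 x 1000-sample segments simulated from a known stable 3-channel VAR(3)."""
    rng = np.random.default_rng(7)
    A = np.zeros((3, 3, 3))
    A[0] = [[0.4, 0.2, 0.0], [0.0, 0.3, 0.25], [0.0, 0.0, 0.35]]
    A[1] = [[-0.3, 0.0, 0.0], [0.0, -0.25, 0.0], [0.15, 0.0, -0.2]]
    A[2] = [[0.15, 0.0, 0.1], [0.0, 0.1, 0.0], [0.0, 0.0, 0.05]]
    model = MVARModel(order=3, coeffs=A, resid_cov=np.diag([1.0, 1.5, 0.8]))
    segs = np.stack([_simulate_var(model, 1000, np.random.default_rng(100 + s))
                     for s in range(12)])
    return model, segs


def make_epochset(segments, fs=FS, stage="REM", subject="S1"):
    labels = tuple(f"ch{i}" for i in range(segments.shape[1]))
    return EpochSet(
        subject_id=subject, stage=stage, segments=segments, fs=fs,
        channel_labels=labels, segment_len_s=segments.shape[2] / fs,
    )
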