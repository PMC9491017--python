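"""Shared fixtures: the study's patient record, synthetic transients, and a
baseline left-heart simulation reused across feature tests."""

from __future__ import annotations

import numpy as np
import pytest

import heartgsa as hg
from heartgsa.pipeline import RunConfig, baseline_params, side_context


@pytest.fixture(scope="session")
def record() -> hg.PatientRecord:
    """The clinical scalars anchoring all baselines."""
    return hg.PatientRecord(
        lvedv=414.0, lvesv=274.0, hr=83.0, p_sys_cuff=97.0, p_dia_cuff=57.0, co=11.62
    )


@pytest.fixture(scope="session")
def transients(record):
    return hg.generate_volume_transients(record, seed=0)


@pytest.fixture(scope="session")
def fluxes(transients):
    return hg.derive_fluxes(transients)


@pytest.fixture(scope="session")
def timings(fluxes):
    return hg.detect_valve_events(fluxes, dur_ms=15.0)


@pytest.fixture(scope="session")
def left_context(record):
    return side_context(RunConfig(record=record), record, "left")


@pytest.fixture(scope="session")
def baseline_left_params(left_context):
    return baseline_params("left", left_context)


@pytest.fixture(scope="session")
def baseline_trace(baseline_left_params, transients, timings):
    trace = hg.simulate(baseline_left_params, transients, timings)
    assert trace.converged, trace.diagnostic
    return trace


@pytest.fixture()
def constant_volume_transients(record):
    """Degenerate motion: constant chamber volumes (no prescribed flow)."""
    T = record.period_s
    n = 1024
    t = np.arange(n) * (T / n)
    return hg.VolumeTransients(
        t=t,
        volumes={"LV": np.full(n, 300.0), "LA": np.full(n, 80.0)},
        period=T,
    )
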