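"""Shared fixtures.

The expensive artefact -- ten full 20-minute sessions pushed through the
complete telemetry chain -- is computed once per test run in a session-scoped
fixture and shared by the end-to-end spectral tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dreamstream import analysis, pipeline, synthgen

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: seeds for the stochastic end-to-end checks, fixed a priori
PIPELINE_SEEDS = tuple(range(1, 11))


def run_full_pipeline(seed: int) -> dict:
    """Generate one default session, run the telemetry chain, and collect the
    spectral summaries used by the end-to-end tests."""
    rec = synthgen.generate_session(synthgen.SessionConfig(seed=seed))
    decoded = pipeline.roundtrip(rec)

    out = {"seed": seed}
    for tag, r in (("coded", decoded), ("uncoded", rec)):
        clean = analysis.preprocess(r)
        eo, ec = analysis.epoch(clean)
        spec_open, spec_closed = analysis.psd(eo), analysis.psd(ec)
        if tag == "coded":
            oz = clean.labels.index("OZ")
            m = spec_closed.mean()[oz]
            mask = (spec_closed.freqs >= 1.0) & (spec_closed.freqs <= 30.0)
            out["oz_peak_hz"] = float(
                spec_closed.freqs[mask][np.argmax(m[mask])])
        out[tag] = {
            "labels": clean.labels,
            "alpha_open": analysis.band_power(spec_open, "alpha"),
            "alpha_closed": analysis.band_power(spec_closed, "alpha"),
            "delta_open": analysis.band_power(spec_open, "delta"),
            "delta_closed": analysis.band_power(spec_closed, "delta"),
        }
    return out


@pytest.fixture(scope="session")
def pipeline_runs() -> list[dict]:
    return [run_full_pipeline(seed) for seed in PIPELINE_SEEDS]


@pytest.fixture(scope="session")
def short_session():
    """A fast 4-minute session (two blocks) for unit-level checks."""
    return synthgen.generate_session(
        synthgen.SessionConfig(seed=7, duration_s=240.0))
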