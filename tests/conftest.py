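"""Shared fixtures: small seeded performances and a default analyzed cohort.

Everything is generated programmatically at test time; the expensive
default-cohort pipeline run is session-scoped and shared by the tests that
check cohort-level orderings.
"""

from __future__ import annotations

import numpy as np
import pytest

from pianokin import pipeline, synth


@pytest.fixture(scope="session")
def clean_signature() -> synth.PerformerSignature:
    """A deterministic signature: no timing noise, no per-stroke jitter."""
    return synth.PerformerSignature(
        timing_cv_base=0.0, timing_cv_slope=0.0,
        amp_jitter_sd=0.0, peak_jitter_sd=0.0, shape_jitter_sd=0.0,
        rest_prob=0.0)


@pytest.fixture(scope="session")
def slow_performance():
    """One noiseless uncoupled slow performance with exact ground truth."""
    rec, notes, truth = synth.generate_performance(
        synth.PerformerSignature(
            timing_cv_base=0.0, timing_cv_slope=0.0,
            amp_jitter_sd=0.0, peak_jitter_sd=0.0, shape_jitter_sd=0.0,
            rest_prob=0.0),
        500.0, synth.MELODIES[0], noise_sd=0.0, seed=1, coupling=0.0)
    return rec, notes, truth


@pytest.fixture(scope="session")
def noisy_performance():
    """A realistic single performance (default signature, 0.1 mm noise)."""
    rec, notes, truth = synth.generate_performance(
        synth.PerformerSignature(), 500.0, synth.MELODIES[0],
        noise_sd=0.1, seed=3)
    return rec, notes, truth


@pytest.fixture(scope="session")
def default_cohort_run(tmp_path_factory):
    """Full pipeline on the default 4x2x5 cohort (the study conditions)."""
    out = tmp_path_factory.mktemp("cohort_run")
    cfg = pipeline.RunConfig(seed=1, out_dir=str(out))
    report = pipeline.run_pipeline(cfg)
    return cfg, report, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
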