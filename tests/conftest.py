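"""Shared fixtures: simulated datasets and pipeline results reused across
test modules (session-scoped because HRF fitting dominates runtime)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import bold_linearity as bl

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_dataset() -> bl.SyntheticDataset:
    """20 zero-noise voxels with a perfectly linear neural model."""
    cfg = bl.SimulationConfig(seed=42, noise_sd=0.0, drift_components=(),
                              linear_trend_per_run=0.0, nonlinearity="none")
    return bl.simulate_dataset(20, cfg)


@pytest.fixture(scope="session")
def linear_result(linear_dataset) -> bl.PipelineResult:
    """Full analysis of the linear dataset (ground-truth active set)."""
    settings = bl.AnalysisSettings(n_null=300, seed=1)
    return bl.run_pipeline(linear_dataset, settings, skip_selection=True)


@pytest.fixture(scope="session")
def nonlinear_result() -> tuple[bl.SyntheticDataset, bl.PipelineResult]:
    """50 noisy voxels with injected transients and duration-dependent gain."""
    cfg = bl.SimulationConfig(seed=7, noise_sd=0.5, nonlinearity="mixed")
    dataset = bl.simulate_dataset(50, cfg)
    settings = bl.AnalysisSettings(n_null=400, selection_q=0.01, seed=2)
    return dataset, bl.run_pipeline(dataset, settings)


@pytest.fixture(scope="session")
def recovery_errors() -> dict[str, np.ndarray]:
    """Relative HRF peak-amplitude recovery errors over 100 seeded fits,
    noise-free and with white noise at 20% of the response peak."""
    rng = np.random.default_rng(123)
    errs: dict[str, list[float]] = {"noise_free": [], "noisy": []}
    for i in range(100):
        truth = bl.synthetic.sample_hrf(rng)
        true_amp = bl.hrf_amplitude(truth)
        clean = bl.boxcar_response(truth, 3.0)
        fit = bl.fit_hrf(clean, 3.0, seed=1000 + i)
        errs["noise_free"].append(abs(fit.amplitude - true_amp) / true_amp)
        noisy = clean + rng.normal(0.0, 0.2 * np.abs(clean).max(), size=25)
        fit_n = bl.fit_hrf(noisy, 3.0, seed=2000 + i)
        errs["noisy"].append(abs(fit_n.amplitude - true_amp) / true_amp)
    return {k: np.asarray(v) for k, v in errs.items()}
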