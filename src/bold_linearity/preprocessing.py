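"""Temporal preprocessing: percent-signal conversion, Fourier-mask
filtering, trial extraction/recombination and trial averaging.

Filtering follows the hard-cutoff DFT-mask convention of AFNI's 3dFourier:
the mean and linear trend are removed before filtering (and not restored),
discrete Fourier bins strictly outside the pass band are zeroed, and the
series is inverse-transformed.

The adaptation-run chain is::

    discard 90 volumes -> percent signal change -> linear detrend of the
    test period -> low-pass 0.2 Hz -> per-condition trial recombination
    (d+30-sample windows, run-then-onset order) -> high-pass at the 10th
    DFT component of the recombined course -> average 12 trials -> keep
    the first 25 samples

which yields one 25-sample measured response per (voxel, condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import CONDITIONS, Condition, MeasuredResponse, Paradigm, TimeCourse

__all__ = [
    "percent_signal_change",
    "fourier_filter",
    "extract_and_recombine",
    "highpass_by_component",
    "measured_response",
    "PreprocessSettings",
    "preprocess_adaptation_run",
    "preprocess_voxel",
    "measured_responses_for_voxel",
    "preprocess_localizer",
    "trial_matrix",
]


def percent_signal_change(tc: TimeCourse, n_discard: int = 0) -> TimeCourse:
    """Convert a raw course to percent signal change about its own mean.

    The first ``n_discard`` volumes are dropped and the mean is taken over
    the retained part only; the output's ``t0_s`` records the discarded
    duration so paradigm onsets stay aligned.
    """
    if tc.unit != "raw":
        raise ValueError("percent_signal_change expects a raw-unit course")
    if n_discard < 0 or n_discard >= len(tc):
        raise ValueError("n_discard must leave at least one volume")
    kept = tc.values[n_discard:]
    m = kept.mean()
    if m <= 0:
        raise ValueError("invalid baseline: retained-part mean must be positive")
    return tc.with_values(100.0 * (kept - m) / m, unit="percent",
                          t0_s=tc.t0_s + n_discard * tc.tr_s)


def _detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (mean + linear trend)."""
    n = len(x)
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def fourier_filter(tc: TimeCourse, low_cut_hz: float | None = None,
                   high_cut_hz: float | None = None, *, detrend: bool = True
                   ) -> TimeCourse:
    """Brick-wall DFT band-pass: zero bins strictly below ``low_cut_hz``
    or strictly above ``high_cut_hz``.

    With ``detrend`` the mean and linear trend are subtracted first (and
    not restored).  Passing only one cutoff gives a pure high- or
    low-pass.
    """
    nyquist = 0.5 / tc.tr_s
    for cut in (low_cut_hz, high_cut_hz):
        if cut is not None and not 0 < cut <= nyquist:
            raise ValueError(f"cutoff {cut} Hz outside (0, {nyquist}] Hz")
    if low_cut_hz is not None and high_cut_hz is not None and low_cut_hz >= high_cut_hz:
        raise ValueError("low_cut_hz must be below high_cut_hz")
    x = tc.values
    if detrend:
        x = _detrend(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=tc.tr_s)
    mask = np.ones_like(freqs, dtype=bool)
    if low_cut_hz is not None:
        mask &= freqs >= low_cut_hz - 1e-12
    if high_cut_hz is not None:
        mask &= freqs <= high_cut_hz + 1e-12
    spec[~mask] = 0.0
    return tc.with_values(np.fft.irfft(spec, n=len(x)))


def extract_and_recombine(runs: Sequence[TimeCourse], paradigms: Sequence[Paradigm],
                          condition: Condition, *, gap_s: float = 30.0) -> TimeCourse:
    """Concatenate per-trial windows of ``condition`` across runs.

    A trial window for a d-s test stimulus at onset t covers the samples
    [t, t + d + gap) — i.e. d + 30 samples at TR = 1 s, the "volume
    201-231" convention for a 1-s stimulus at 200 s.  Windows are taken
    in run order, then onset order within each run.
    """
    if len(runs) != len(paradigms):
        raise ValueError("runs and paradigms must pair up")
    segments = []
    n_trials = 0
    for tc, par in zip(runs, paradigms):
        if abs(tc.tr_s - par.tr_s) > 1e-12:
            raise ValueError("run TR does not match paradigm TR")
        window = condition.test_duration_s + gap_s
        w = window / tc.tr_s
        if abs(w - round(w)) > 1e-9:
            raise ValueError("trial window is not an integer number of samples")
        w = int(round(w))
        for ev in par.events_for(condition):
            i0 = (ev.onset_s - tc.t0_s) / tc.tr_s
            if abs(i0 - round(i0)) > 1e-9:
                raise ValueError("event onset is off the sampling grid")
            i0 = int(round(i0))
            if i0 < 0 or i0 + w > len(tc):
                raise ValueError(
                    f"trial window [{ev.onset_s}, {ev.onset_s + window}) s "
                    "does not fit the run"
                )
            segments.append(tc.values[i0: i0 + w])
            n_trials += 1
    if n_trials == 0:
        raise ValueError(f"condition {condition.label} absent from paradigms")
    return TimeCourse(
        values=np.concatenate(segments), tr_s=runs[0].tr_s, unit=runs[0].unit,
        origin=f"recombined/{condition.label}/{n_trials}trials",
    )


def highpass_by_component(tc: TimeCourse, k: int = 10) -> TimeCourse:
    """Zero the DC and the first ``k`` DFT components (cycles per course).

    The cutoff frequency is k / (length * TR); signal at component k+1
    and above is untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(tc) <= 2 * k:
        raise ValueError("course too short for the requested component cutoff")
    spec = np.fft.rfft(tc.values)
    spec[: k + 1] = 0.0
    return tc.with_values(np.fft.irfft(spec, n=len(tc)))


def component_cutoff_hz(length: int, tr_s: float, k: int = 10) -> float:
    """Frequency of the k-th DFT component of a course of ``length`` samples."""
    return k / (length * tr_s)


def trial_matrix(recombined: TimeCourse, trial_length: int) -> np.ndarray:
    """Reshape a recombined course into its (n_trials, trial_length) matrix."""
    n = len(recombined)
    if n % trial_length:
        raise ValueError(
            f"course length {n} is not divisible by trial length {trial_length}"
        )
    return recombined.values.reshape(n // trial_length, trial_length)


def measured_response(recombined: TimeCourse, trial_length: int, *,
                      keep: int = 25, voxel_id: int = -1,
                      condition: Condition | None = None) -> MeasuredResponse:
    """Average the trials of a recombined course; keep the first 25 samples."""
    if keep > trial_length:
        raise ValueError("keep must not exceed trial_length")
    trials = trial_matrix(recombined, trial_length)
    mean = trials.mean(axis=0)[:keep]
    return MeasuredResponse(
        values=mean, voxel_id=voxel_id,
        condition=condition or Condition("increment", 1.0),
        n_trials_averaged=trials.shape[0], tr_s=recombined.tr_s,
    )


@dataclass(frozen=True)
class PreprocessSettings:
    """Filter chain settings (defaults follow the analysis protocol)."""

    n_discard: int = 90
    low_pass_hz: float = 0.2
    hp_components: int = 10
    keep_samples: int = 25
    localizer_band_hz: tuple[float, float] = (0.0125, 0.2)


def preprocess_adaptation_run(tc: TimeCourse, settings: PreprocessSettings
                              ) -> TimeCourse:
    """Per-run stages: discard, percent conversion, detrend + low-pass."""
    pct = percent_signal_change(tc, settings.n_discard)
    return fourier_filter(pct, None, settings.low_pass_hz, detrend=True)


def preprocess_voxel(
    runs: Sequence[TimeCourse], paradigms: Sequence[Paradigm],
    settings: PreprocessSettings | None = None, *, voxel_id: int = -1,
    conditions: Sequence[Condition] = CONDITIONS,
) -> tuple[dict[Condition, MeasuredResponse], dict[Condition, np.ndarray]]:
    """Full adaptation chain for one voxel.

    Returns the 6 trial-averaged measured responses and, per condition,
    the individual preprocessed trials as an (n_trials, keep) array (the
    input to the SNR computation).
    """
    settings = settings or PreprocessSettings()
    filtered = [
        preprocess_adaptation_run(tc, settings) if tc.unit == "raw" else tc
        for tc in runs
    ]
    responses: dict[Condition, MeasuredResponse] = {}
    trials: dict[Condition, np.ndarray] = {}
    for cond in conditions:
        recombined = extract_and_recombine(filtered, paradigms, cond)
        trial_len = int(round((cond.test_duration_s + 30.0) / recombined.tr_s))
        highpassed = highpass_by_component(recombined, settings.hp_components)
        mat = trial_matrix(highpassed, trial_len)
        trials[cond] = mat[:, : settings.keep_samples]
        responses[cond] = measured_response(highpassed, trial_len,
                                            keep=settings.keep_samples,
                                            voxel_id=voxel_id, condition=cond)
    return responses, trials


def measured_responses_for_voxel(
    runs: Sequence[TimeCourse], paradigms: Sequence[Paradigm],
    settings: PreprocessSettings | None = None, *, voxel_id: int = -1,
    conditions: Sequence[Condition] = CONDITIONS,
) -> dict[Condition, MeasuredResponse]:
    """Full adaptation chain for one voxel: raw runs -> 6 measured responses."""
    responses, _ = preprocess_voxel(runs, paradigms, settings,
                                    voxel_id=voxel_id, conditions=conditions)
    return responses


def preprocess_localizer(tc: TimeCourse, settings: PreprocessSettings | None = None
                         ) -> TimeCourse:
    """Localizer chain: percent conversion, detrend + 0.0125-0.2 Hz band-pass."""
    settings = settings or PreprocessSettings()
    pct = percent_signal_change(tc, 0) if tc.unit == "raw" else tc
    lo, hi = settings.localizer_band_hz
    return fourier_filter(pct, lo, hi, detrend=True)
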