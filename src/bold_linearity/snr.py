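"""FFT-based signal-to-noise ratio per voxel and the nonparametric
group statistics.

Trials of one response type are truncated to 25 samples and
concatenated, which makes the task periodicity 25 s per cycle
(task frequency 0.04 Hz at TR = 1 s).  The SNR is the DFT magnitude at
the task-frequency bin divided by the mean magnitude over the
high-frequency noise band 0.33-0.50 Hz.  Voxels are split into low/high
SNR groups at the median, and group comparisons use Wilcoxon signed-rank
and Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SNRResult",
    "compute_snr",
    "median_split",
    "paired_compare",
    "distribution_compare",
    "run_report",
]

NOISE_BAND_HZ = (0.33, 0.50)


@dataclass(frozen=True)
class SNRResult:
    """SNR of one voxel's concatenated trials for one response type."""

    voxel_id: int
    response_type: str
    snr: float
    task_freq_hz: float
    noise_band_hz: tuple[float, float]
    group: str | None = None


def compute_snr(trials: Sequence[np.ndarray] | np.ndarray, tr_s: float = 1.0, *,
                voxel_id: int = -1, response_type: str = "",
                noise_band_hz: tuple[float, float] | None = NOISE_BAND_HZ) -> SNRResult:
    """SNR of concatenated 25-sample trials.

    ``trials`` is an (n_trials, 25) stack (or a sequence of 25-sample
    segments).  The task-frequency bin of the concatenated course is
    ``n_trials`` cycles per course = 1/25 Hz; the noise level is the mean
    DFT magnitude over bins inside ``noise_band_hz`` (endpoints
    inclusive).  ``noise_band_hz=None`` uses the alternative band of all
    non-DC frequencies except the task frequency.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[1] != 25:
        raise ValueError("trials must be an (n_trials, 25) array")
    if trials.shape[0] < 2:
        raise ValueError("at least 2 trials are required")
    n_trials = trials.shape[0]
    x = trials.reshape(-1)
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=tr_s)
    task_bin = n_trials  # n_trials cycles over the concatenated course
    task_freq = float(freqs[task_bin])
    if noise_band_hz is None:
        band = np.ones_like(freqs, dtype=bool)
        band[0] = False
        band[task_bin] = False
        lo, hi = float(freqs[1]), float(freqs[-1])
    else:
        lo, hi = noise_band_hz
        if lo <= task_freq <= hi:
            raise ValueError("task frequency falls inside the noise band")
        band = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    noise_level = float(mag[band].mean())
    if noise_level <= 1e-12 * float(mag.max()):
        raise ValueError("degenerate noise band: zero magnitude")
    return SNRResult(voxel_id=voxel_id, response_type=response_type,
                     snr=float(mag[task_bin] / noise_level),
                     task_freq_hz=task_freq, noise_band_hz=(lo, hi))


def median_split(values: Sequence[float], *,
                 tie_rule: Literal["median_to_low", "median_to_high"] = "median_to_low"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into low/high groups at the median value.

    With ``median_to_low`` (default) values equal to the median go to the
    low group, so an odd count gives the low group one more member.
    Returns (low indices, high indices).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("at least 2 values are required")
    med = float(np.median(values))
    if tie_rule == "median_to_low":
        low = values <= med
    elif tie_rule == "median_to_high":
        low = values < med
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    idx = np.arange(values.size)
    return idx[low], idx[~low]


def paired_compare(x: Sequence[float], y: Sequence[float]
                   ) -> tuple[float, float, str]:
    """Two-tailed Wilcoxon signed-rank test on paired per-voxel values.

    Zero differences are dropped; the normal approximation (with
    continuity and tie correction) is used for n > 25 and exact
    enumeration otherwise.  Returns (Z or W statistic, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0, "degenerate"
    if nonzero.size > 25:
        res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="approx")
        return float(abs(res.zstatistic)), float(res.pvalue), "normal_approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox",
                         alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue), "exact"


def distribution_compare(x: Sequence[float],
                         y: Sequence[float] | None = None, *,
                         reference: str | None = None) -> tuple[float, float]:
    """Kolmogorov-Smirnov test: two-sample, or one-sample against a
    zero-mean normal with the sample's own standard deviation.

    Returns (D, p).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x must be nonempty")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("y must be nonempty")
        res = stats.ks_2samp(x, y)
        return float(res.statistic), float(res.pvalue)
    if reference != "centered_normal":
        raise ValueError("reference must be 'centered_normal' when y is omitted")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: KS reference is degenerate")
    res = stats.kstest(x, "norm", args=(0.0, sd))
    return float(res.statistic), float(res.pvalue)


def run_report(*args, **kwargs):
    """End-to-end pipeline report; see :func:`bold_linearity.workflow.run_report`."""
    from .workflow import run_report as _run_report

    return _run_report(*args, **kwargs)
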