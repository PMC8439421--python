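"""Activated-voxel selection from the localizer run.

A finite-impulse-response (FIR) deconvolution measures, per voxel, the
fraction of time-course variance accounted for by the stimulus (r^2).
Significance is assessed against a permutation null built by shuffling
time points of the source courses and re-running the identical
preprocessing chain; per-voxel empirical false-positive rates are
corrected with Benjamini-Hochberg FDR, and surviving voxels are kept only
if they sit in face-connected clusters of a minimum size and responded
with a positive early FIR deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .core import Condition, Paradigm, TimeCourse

__all__ = [
    "FIREstimate",
    "NullDistribution",
    "VoxelRecord",
    "stimulus_indicator",
    "fir_r2",
    "build_null",
    "fdr_bh",
    "select_voxels",
]


@dataclass(frozen=True)
class FIREstimate:
    """Least-squares impulse-response estimate (one weight per lag)."""

    taps: np.ndarray
    fitted: np.ndarray

    @property
    def window(self) -> int:
        return len(self.taps)

    def mean_early_response(self, *, upto_s: float = 15.0, tr_s: float = 1.0) -> float:
        """Mean estimated impulse response over lags 0..upto_s (positivity check)."""
        n = min(len(self.taps), int(round(upto_s / tr_s)) + 1)
        return float(self.taps[:n].mean())


@dataclass(frozen=True)
class VoxelRecord:
    """Per-voxel analysis results accumulated across pipeline stages."""

    voxel_id: int
    coords: tuple[int, int, int]
    r2: float
    fpr_raw: float = np.nan
    fpr_fdr: float = np.nan
    selected: bool = False
    dice: dict = field(default_factory=dict)
    contrast: dict = field(default_factory=dict)
    amp_ratio: dict = field(default_factory=dict)
    snr: dict = field(default_factory=dict)


def stimulus_indicator(paradigm: Paradigm, *, condition: object | None = None
                       ) -> np.ndarray:
    """Binary indicator series (1 while the stimulus is on) at TR resolution."""
    ind = np.zeros(paradigm.n_volumes)
    for ev in paradigm.events:
        if condition is not None and ev.condition != condition:
            continue
        i0 = int(round(ev.onset_s / paradigm.tr_s))
        i1 = int(round(ev.offset_s / paradigm.tr_s))
        ind[i0:i1] = 1.0
    return ind


def fir_r2(tc: TimeCourse, stimulus: np.ndarray, L: int = 25
           ) -> tuple[FIREstimate, float]:
    """FIR deconvolution and the fraction of variance it accounts for.

    Fits ``y_t = sum_k h_k s_{t-k} + b`` by least squares over lags
    0..L-1 and returns r^2 = 1 - SS_res / SS_tot (SS_tot about the mean),
    clipped to [0, 1].  A zero-variance course returns r^2 = 0.
    """
    y = tc.values
    s = np.asarray(stimulus, dtype=float)
    if len(s) != len(y):
        raise ValueError("stimulus must be aligned to the time course")
    if len(y) <= L:
        raise ValueError("time course must be longer than the FIR window")
    n = len(y)
    X = np.zeros((n, L + 1))
    for k in range(L):
        X[k:, k] = s[: n - k]
    X[:, L] = 1.0  # intercept
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: stimulus lags are collinear for this window"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    taps = coef[:L]
    fitted_full = X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return FIREstimate(taps=np.zeros(L), fitted=np.zeros(n)), 0.0
    ss_res = float(np.sum((y - fitted_full) ** 2))
    r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    fitted_conv = np.convolve(taps, s)[:n]
    return FIREstimate(taps=taps, fitted=fitted_conv), r2


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null of a statistic computed on randomized time courses."""

    statistic_name: Literal["r2", "dice"]
    samples: np.ndarray
    tail: Literal["upper", "lower", "two"] = "upper"
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def threshold(self, fpr: float) -> float:
        """Statistic value exceeded by a ``fpr`` fraction of null samples."""
        if not 0 < fpr < 1:
            raise ValueError("fpr must be in (0, 1)")
        if self.tail == "lower":
            return float(np.quantile(self.samples, fpr))
        return float(np.quantile(self.samples, 1.0 - fpr))

    def empirical_fpr(self, observed: float) -> float:
        """Permutation p-value with the +1 correction (never exactly zero)."""
        if self.tail == "lower":
            exceed = np.sum(self.samples <= observed)
        else:
            exceed = np.sum(self.samples >= observed)
        return float((1 + exceed) / (1 + self.n_samples))


def _ar1_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with the course's lag-1 autocorrelation, mean and variance."""
    z = x - x.mean()
    denom = float(z[:-1] @ z[:-1])
    phi = float(z[1:] @ z[:-1]) / denom if denom > 0 else 0.0
    phi = float(np.clip(phi, -0.99, 0.99))
    innov_sd = z.std() * np.sqrt(max(1.0 - phi**2, 1e-12))
    out = np.empty_like(z)
    out[0] = rng.normal(0.0, z.std() if z.std() > 0 else 1.0)
    eps = rng.normal(0.0, innov_sd, size=len(z) - 1)
    for i in range(1, len(z)):
        out[i] = phi * out[i - 1] + eps[i - 1]
    return out + x.mean()


def build_null(timecourses: Sequence[TimeCourse],
               pipeline: Callable[[TimeCourse], TimeCourse],
               statistic: Callable[[TimeCourse], float],
               n_total: int = 1000, seed: int = 0, *,
               statistic_name: Literal["r2", "dice"] = "r2",
               null_model: Literal["shuffle", "ar1"] = "shuffle"
               ) -> NullDistribution:
    """Pool ``n_total`` statistic values from randomized source courses.

    Each draw takes a source course (round-robin), randomizes it —
    uniform permutation of its time points, or an AR(1) surrogate — runs
    it through the full preprocessing ``pipeline``, and evaluates the
    ``statistic``.
    """
    if n_total < 100:
        raise ValueError("n_total must be >= 100 for a usable null")
    if not timecourses:
        raise ValueError("at least one source course is required")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_total)
    for i in range(n_total):
        src = timecourses[i % len(timecourses)]
        if null_model == "shuffle":
            vals = src.values[rng.permutation(len(src))]
        elif null_model == "ar1":
            vals = _ar1_surrogate(src.values, rng)
        else:
            raise ValueError(f"unknown null model {null_model!r}")
        randomized = src.with_values(vals, origin=f"null/{i}")
        samples[i] = statistic(pipeline(randomized))
    return NullDistribution(statistic_name=statistic_name, samples=samples, seed=seed)


def fdr_bh(p: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, reject flags at level ``q``).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def _cluster_filter(table: pd.DataFrame, flags: np.ndarray, min_cluster: int
                    ) -> np.ndarray:
    """Keep flagged voxels only in face-connected clusters of >= min_cluster."""
    if min_cluster <= 1:
        return flags
    for col in ("x", "y", "z"):
        if col not in table.columns or table[col].isna().any():
            raise ValueError("grid coordinates required when min_cluster > 1")
    coords = table[["x", "y", "z"]].to_numpy(int)
    offset = coords.min(axis=0)
    shape = coords.max(axis=0) - offset + 1
    grid = np.zeros(shape, dtype=bool)
    sel = coords[flags] - offset
    grid[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    structure = ndimage.generate_binary_structure(3, 1)  # 6-neighbor faces
    labels, n_lab = ndimage.label(grid, structure=structure)
    sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n_lab + 1))
    keep_labels = {lab for lab, sz in enumerate(sizes, start=1) if sz >= min_cluster}
    out = flags.copy()
    for i, (x, y, z) in enumerate(coords - offset):
        if out[i] and labels[x, y, z] not in keep_labels:
            out[i] = False
    return out


def select_voxels(table: pd.DataFrame, null: NullDistribution, *,
                  q: float = 0.001, min_cluster: int = 4) -> pd.DataFrame:
    """Flag significantly activated voxels.

    ``table`` needs columns voxel_id, x, y, z, r2 and (optionally)
    ``fir_positive`` — whether the mean estimated impulse response over
    0-15 s is positive, the requirement that the localizer stimulus
    elicited a signal increment.  Adds fpr_raw, fpr_fdr and selected
    columns.
    """
    table = table.copy()
    table["fpr_raw"] = [null.empirical_fpr(v) for v in table["r2"]]
    adjusted, reject = fdr_bh(table["fpr_raw"].to_numpy(), q)
    table["fpr_fdr"] = adjusted
    flags = reject & (adjusted < q)
    if "fir_positive" in table.columns:
        flags &= table["fir_positive"].to_numpy(bool)
    flags = _cluster_filter(table, flags, min_cluster)
    table["selected"] = flags
    return table
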