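"""Superposition predictions and Dice-index similarity.

Under linearity, the response to a long stimulus equals the sum of the
short-stimulus response and its temporally shifted copies.  This module
builds those predictions from the 25-sample measured responses, scores
each prediction P against the measured long-stimulus response M with the
signed, amplitude-sensitive Dice index

    s_Dice = 2 * sum_t P_t M_t / (sum_t P_t^2 + sum_t M_t^2),

and assesses significance against permutation nulls built by shuffling
time points of the per-run courses and rebuilding responses and
predictions from the shuffled data.  Unlike a correlation coefficient,
the Dice index penalizes amplitude mismatch: dice(k*M, M) = 2k/(k^2+1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CONDITIONS, Condition, MeasuredResponse, Paradigm, TimeCourse
from .preprocessing import (
    PreprocessSettings,
    extract_and_recombine,
    highpass_by_component,
    measured_response,
    percent_signal_change,
    fourier_filter,
)
from .selection import NullDistribution, fdr_bh

__all__ = [
    "PredictionPair",
    "Prediction",
    "PREDICTION_PAIRS",
    "superposition_predict",
    "dice_index",
    "build_dice_null",
    "dice_chance_threshold",
    "evaluate_linearity",
]

_VALID_PAIRS = ((1.0, 3.0), (1.0, 6.0), (3.0, 6.0))


@dataclass(frozen=True)
class PredictionPair:
    """A (short -> long) duration pair for one response type."""

    short_dur_s: float
    long_dur_s: float
    response_type: str

    def __post_init__(self) -> None:
        if (self.short_dur_s, self.long_dur_s) not in _VALID_PAIRS:
            raise ValueError(
                f"invalid pair {self.short_dur_s}->{self.long_dur_s}; "
                "valid pairs are 1->3, 1->6, 3->6"
            )

    @property
    def n_copies(self) -> int:
        return int(round(self.long_dur_s / self.short_dur_s))

    @property
    def label(self) -> str:
        return f"{self.response_type}_{int(self.short_dur_s)}to{int(self.long_dur_s)}"

    @property
    def short_condition(self) -> Condition:
        return Condition(self.response_type, self.short_dur_s)

    @property
    def long_condition(self) -> Condition:
        return Condition(self.response_type, self.long_dur_s)


#: all six (pair x response type) combinations, in reporting order
PREDICTION_PAIRS: tuple[PredictionPair, ...] = tuple(
    PredictionPair(s, l, rt)
    for rt in ("increment", "decrement")
    for s, l in _VALID_PAIRS
)


@dataclass(frozen=True)
class Prediction:
    """A 25-sample superposition prediction P for one voxel and pair."""

    values: np.ndarray
    pair: PredictionPair
    voxel_id: int


def superposition_predict(short: MeasuredResponse | np.ndarray, pair: PredictionPair,
                          *, tr_s: float = 1.0, voxel_id: int = -1) -> Prediction:
    """Sum the short response with its duration-shifted copies.

    The response to the long stimulus is predicted as
    ``P = sum_{j=0}^{r-1} shift(short, j * short_dur)`` with zeros shifted
    in, truncated to 25 samples after summation.
    """
    if isinstance(short, MeasuredResponse):
        x = short.values
        tr_s = short.tr_s
        voxel_id = short.voxel_id
    else:
        x = np.asarray(short, dtype=float)
    shift = pair.short_dur_s / tr_s
    if abs(shift - round(shift)) > 1e-9 or shift <= 0:
        raise ValueError("shift must be a positive integer number of samples")
    shift = int(round(shift))
    out = np.zeros(len(x))
    for j in range(pair.n_copies):
        k = j * shift
        if k < len(x):
            out[k:] += x[: len(x) - k]
    return Prediction(values=out[:25], pair=pair, voxel_id=voxel_id)


def dice_index(P: Prediction | np.ndarray, M: MeasuredResponse | np.ndarray) -> float:
    """Signed amplitude-sensitive similarity of prediction and measurement.

    1 iff P = M, -1 iff P = -M; bounded in [-1, 1] for any finite nonzero
    inputs.
    """
    p = P.values if isinstance(P, Prediction) else np.asarray(P, dtype=float)
    m = M.values if isinstance(M, MeasuredResponse) else np.asarray(M, dtype=float)
    if p.shape != m.shape:
        raise ValueError("P and M must have equal lengths")
    denom = float(p @ p + m @ m)
    if denom == 0:
        raise ValueError("undefined similarity: both inputs are all-zero")
    return float(2.0 * (p @ m) / denom)


def build_dice_null(voxel_runs: Sequence[Sequence[TimeCourse]],
                    paradigms: Sequence[Paradigm],
                    settings: PreprocessSettings | None = None,
                    n_total: int = 1000, seed: int = 0) -> NullDistribution:
    """Null Dice distribution from time-point-shuffled run courses.

    Each draw permutes the time points of one voxel's percent-converted
    run courses, pushes them through the identical filter chain
    (low-pass, recombination, component high-pass, trial averaging),
    rebuilds all six (pair x response type) predictions, and pools the
    resulting Dice values until ``n_total`` samples are collected.
    """
    if n_total < 100:
        raise ValueError("n_total must be >= 100 for a usable null")
    settings = settings or PreprocessSettings()
    rng = np.random.default_rng(seed)
    percent_runs: list[list[TimeCourse]] = []
    for runs in voxel_runs:
        percent_runs.append([
            percent_signal_change(tc, settings.n_discard) if tc.unit == "raw" else tc
            for tc in runs
        ])
    samples: list[float] = []
    vi = 0
    while len(samples) < n_total:
        runs = percent_runs[vi % len(percent_runs)]
        vi += 1
        shuffled = [
            fourier_filter(tc.with_values(tc.values[rng.permutation(len(tc))]),
                           None, settings.low_pass_hz, detrend=True)
            for tc in runs
        ]
        responses: dict[Condition, MeasuredResponse] = {}
        for cond in CONDITIONS:
            recombined = extract_and_recombine(shuffled, paradigms, cond)
            trial_len = int(round((cond.test_duration_s + 30.0) / recombined.tr_s))
            highpassed = highpass_by_component(recombined, settings.hp_components)
            responses[cond] = measured_response(highpassed, trial_len,
                                                keep=settings.keep_samples,
                                                condition=cond)
        for pair in PREDICTION_PAIRS:
            P = superposition_predict(responses[pair.short_condition], pair)
            samples.append(dice_index(P, responses[pair.long_condition]))
    return NullDistribution(statistic_name="dice",
                            samples=np.asarray(samples[:n_total]), seed=seed)


def dice_chance_threshold(null: NullDistribution, fpr: float = 0.05,
                          n_voxels: int = 1,
                          observed: Sequence[float] | None = None) -> float:
    """Upper-tail chance threshold for the Dice index.

    Without observed values (or with ``n_voxels == 1``) this is the
    uncorrected ``(1 - fpr)`` null quantile.  With observed per-voxel Dice
    values, a Benjamini-Hochberg step-up across voxels (one-tailed) picks
    the largest k such that at least k observed values exceed the
    ``1 - fpr*k/n`` null quantile; the threshold at that step is
    returned.
    """
    if null.statistic_name != "dice":
        raise ValueError("null must be a dice null distribution")
    if observed is None or n_voxels <= 1:
        return null.threshold(fpr)
    obs = np.sort(np.asarray(observed, dtype=float))[::-1]
    n = n_voxels
    best_k = 0
    for k in range(1, len(obs) + 1):
        thr = null.threshold(fpr * k / n)
        if np.sum(obs >= thr) >= k:
            best_k = k
    level = fpr * best_k / n if best_k else fpr / n
    return null.threshold(level)


def evaluate_linearity(
    responses: Mapping[int, Mapping[Condition, MeasuredResponse]],
    null: NullDistribution | None = None,
    fpr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Dice index per selected voxel for all six (pair x response type) combos.

    Returns a long-format table (voxel_id, response_type, pair, dice,
    above_chance) and a summary with per-condition medians, percent above
    chance (when a null is supplied) and BH-corrected paired Wilcoxon
    comparisons across response types and durations.
    """
    rows = []
    for voxel_id in sorted(responses):
        vox = responses[voxel_id]
        for pair in PREDICTION_PAIRS:
            P = superposition_predict(vox[pair.short_condition], pair)
            d = dice_index(P, vox[pair.long_condition])
            rows.append({"voxel_id": voxel_id, "response_type": pair.response_type,
                         "pair": f"{int(pair.short_dur_s)}to{int(pair.long_dur_s)}",
                         "dice": d})
    table = pd.DataFrame(rows)

    summary: dict = {"conditions": {}, "comparisons": {}}
    thresholds: dict[str, float] = {}
    if null is not None:
        n_vox = table["voxel_id"].nunique()
        for (rt, pr), grp in table.groupby(["response_type", "pair"]):
            thresholds[f"{rt}_{pr}"] = dice_chance_threshold(
                null, fpr, n_vox, observed=grp["dice"].to_numpy())
        table["above_chance"] = [
            d >= thresholds[f"{rt}_{pr}"]
            for rt, pr, d in zip(table["response_type"], table["pair"], table["dice"])
        ]
    for (rt, pr), grp in table.groupby(["response_type", "pair"]):
        entry = {"n": int(len(grp)), "median_dice": float(grp["dice"].median())}
        if null is not None:
            entry["chance_threshold"] = thresholds[f"{rt}_{pr}"]
            entry["percent_above_chance"] = float(100.0 * grp["above_chance"].mean())
        summary["conditions"][f"{rt}_{pr}"] = entry

    # paired comparisons: increment vs decrement per pair, and short vs long
    # predictors per response type (1to3 vs 3to6, 1to6 vs 3to6)
    wide = table.pivot(index="voxel_id", columns=["response_type", "pair"],
                       values="dice")
    comparisons = []
    for pr in ("1to3", "1to6", "3to6"):
        comparisons.append((f"increment_vs_decrement_{pr}",
                            wide[("increment", pr)], wide[("decrement", pr)]))
    for rt in ("increment", "decrement"):
        comparisons.append((f"{rt}_1to3_vs_3to6", wide[(rt, "1to3")], wide[(rt, "3to6")]))
        comparisons.append((f"{rt}_1to6_vs_3to6", wide[(rt, "1to6")], wide[(rt, "3to6")]))
    pvals = []
    for name, x, y in comparisons:
        from .snr import paired_compare
        stat, p, method = paired_compare(x.to_numpy(), y.to_numpy())
        summary["comparisons"][name] = {"statistic": stat, "p": p, "method": method}
        pvals.append(p)
    if pvals:
        adjusted, _ = fdr_bh(pvals, 0.05)
        for (name, *_), p_adj in zip(comparisons, adjusted):
            summary["comparisons"][name]["p_corrected"] = float(p_adj)
    return table, summary
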