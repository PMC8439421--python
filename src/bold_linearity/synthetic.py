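"""Forward simulator for contrast-adaptation fMRI experiments.

Generates the two run types the analysis consumes:

* a block-design localizer (30-s rest / 30-s stimulus, four alternations,
  240 s), and
* event-related contrast-adaptation runs (890 s: 30-s rest baseline, 60-s
  adaptation pedestal onset, then 24 test trials — 4 repetitions of each of
  the 6 conditions in seeded random order — each followed by 30 s of
  adaptation stimulus),

and per-voxel BOLD time courses built as

    raw = baseline_level * (1 + (neural drive (*) HRF + noise) / 100)

with the neural drive evaluated as a boxcar at 10-Hz internal resolution,
convolved with a two-gamma HRF, and sampled at TR.  Optional
nonlinearities (duration-dependent gain, onset/offset transients,
within-stimulus habituation) can be injected to emulate deviations from
superposition; with all of them off the simulated system is exactly
linear and time-invariant, which is the ground truth the linearity
statistics are validated against.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .core import CONDITIONS, Condition, Event, Paradigm, TimeCourse
from .hrf import HRFParams, hrf_eval

__all__ = [
    "NeuralModel",
    "NoiseModel",
    "SimulationConfig",
    "SimulatedVoxel",
    "SyntheticDataset",
    "generate_paradigm",
    "neural_drive",
    "simulate_voxel",
    "simulate_dataset",
    "signal_band",
    "estimate_signal_band",
    "sample_hrf",
    "NONLINEARITY_PRESETS",
]

#: internal drive resolution (s); sub-second HRF onsets/peaks need finer-than-TR sampling
DT = 0.1

LOCALIZER_BLOCK_S = 30.0
ADAPT_BASELINE_S = 30.0
ADAPT_PEDESTAL_S = 60.0
TRIAL_GAP_S = 30.0
N_TRIALS_PER_RUN = 24
N_REPS_PER_CONDITION = 4


@dataclass(frozen=True)
class NeuralModel:
    """Neural drive model of one voxel.

    With ``duration_gain`` identically 1, no transients and infinite
    habituation time constant, the drive to each test stimulus is an exact
    boxcar and the voxel is a perfectly linear system.

    Parameters
    ----------
    base_gain
        Dimensionless response gain of the test contrast step; 0 marks an
        inactive voxel.
    duration_gain
        Per-duration multiplicative amplitude factor, one map per response
        type.  Values above 1 for short durations inflate short-stimulus
        responses, which downstream appears as overestimation by the
        superposition prediction.
    onset_offset_transient
        (amplitude, width_s) of square bursts added at stimulus onset and
        offset, emulating transient neural activity at contrast changes.
    habituation_tau_s
        Time constant of exponential decay of the sustained drive during a
        stimulus (``inf`` = no habituation).
    adaptation_baseline
        (amplitude, decay_tau_s) of the drive pedestal during the
        adaptation phase.  The pedestal decays from ``amplitude`` toward
        ``amplitude * plateau_fraction`` and persists (the adaptation
        stimulus stays on screen for the rest of the run).
    decrement_gain
        Magnitude of decrement drives relative to increments (decrements
        are sign-flipped drives; the smaller default mimics the weaker,
        lower-SNR decrement responses).
    """

    base_gain: float = 1.0
    duration_gain: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {
            "increment": {1.0: 1.0, 3.0: 1.0, 6.0: 1.0},
            "decrement": {1.0: 1.0, 3.0: 1.0, 6.0: 1.0},
        }
    )
    onset_offset_transient: tuple[float, float] = (0.0, 0.5)
    habituation_tau_s: float = np.inf
    adaptation_baseline: tuple[float, float] = (1.0, 15.0)
    plateau_fraction: float = 0.5
    decrement_gain: float = 0.6

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_gain):
            raise ValueError("base_gain must be finite")
        if self.habituation_tau_s <= 0:
            raise ValueError("habituation_tau_s must be > 0 (use inf for none)")
        if self.adaptation_baseline[1] <= 0:
            raise ValueError("adaptation decay constant must be > 0")
        if not 0 <= self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in [0, 1]")

    @property
    def is_linear(self) -> bool:
        gains_flat = [g for m in self.duration_gain.values() for g in m.values()]
        return (
            all(g == gains_flat[0] for g in gains_flat)
            and self.onset_offset_transient[0] == 0.0
            and np.isinf(self.habituation_tau_s)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise in percent-signal units.

    ``drift_components`` are (frequency_hz, amplitude) sinusoids with
    seeded random phases; defaults stay below the 0.0125-Hz high-pass so
    the filtering stages can remove them.
    """

    white_sd: float = 0.5
    drift_components: tuple[tuple[float, float], ...] = ((0.003, 0.3), (0.008, 0.2))
    linear_trend_per_run: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (
            self.white_sd == 0
            and all(a == 0 for _, a in self.drift_components)
            and self.linear_trend_per_run == 0
        )

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(white_sd=0.0, drift_components=(), linear_trend_per_run=0.0)


def generate_paradigm(kind: Literal["localizer", "adaptation"], seed: int = 0,
                      *, tr_s: float = 1.0) -> Paradigm:
    """Generate one run's trial schedule.

    Localizer: four 30-s stimulus blocks at onsets 30, 90, 150, 210 s
    (240-s run).  Adaptation: 30-s rest, adaptation pedestal onset, then
    24 test trials (4 per condition, seeded random order), each a test
    event followed by 30 s of adaptation stimulus; the run lasts 890 s.
    """
    if kind == "localizer":
        events = tuple(
            Event(onset_s=LOCALIZER_BLOCK_S * (2 * i + 1), duration_s=LOCALIZER_BLOCK_S,
                  condition="localizer")
            for i in range(4)
        )
        return Paradigm(events=events, run_length_s=240.0, tr_s=tr_s, kind="localizer")
    if kind != "adaptation":
        raise ValueError(f"unknown paradigm kind {kind!r}")

    rng = np.random.default_rng(seed)
    conditions = [c for c in CONDITIONS for _ in range(N_REPS_PER_CONDITION)]
    order = rng.permutation(len(conditions))
    events = []
    t = ADAPT_BASELINE_S + ADAPT_PEDESTAL_S
    for idx in order:
        cond = conditions[idx]
        events.append(Event(onset_s=t, duration_s=cond.test_duration_s, condition=cond))
        t += cond.test_duration_s + TRIAL_GAP_S
    return Paradigm(
        events=tuple(events), run_length_s=t, tr_s=tr_s, kind="adaptation",
        adaptation_onset_s=ADAPT_BASELINE_S,
    )


def neural_drive(paradigm: Paradigm, neural: NeuralModel, *, dt: float = DT) -> np.ndarray:
    """Evaluate the voxel's neural drive on the fine (``dt``) time grid."""
    n_fine = int(round(paradigm.run_length_s / dt))
    t = dt * np.arange(n_fine)
    drive = np.zeros(n_fine)

    if paradigm.kind == "adaptation" and paradigm.adaptation_onset_s is not None:
        amp, tau = neural.adaptation_baseline
        t0 = paradigm.adaptation_onset_s
        ped = t >= t0
        frac = neural.plateau_fraction
        drive[ped] += amp * (frac + (1 - frac) * np.exp(-(t[ped] - t0) / tau))

    trans_amp, trans_w = neural.onset_offset_transient
    for ev in paradigm.events:
        if ev.offset_s > paradigm.run_length_s + 1e-9:
            raise ValueError("event extends past run end")
        if isinstance(ev.condition, Condition):
            cond = ev.condition
            sign = 1.0 if cond.response_type == "increment" else -neural.decrement_gain
            gain = neural.base_gain * neural.duration_gain[cond.response_type][cond.test_duration_s]
        else:
            sign, gain = 1.0, neural.base_gain
        i0 = int(round(ev.onset_s / dt))
        i1 = int(round(ev.offset_s / dt))
        seg = np.full(i1 - i0, gain * sign)
        if np.isfinite(neural.habituation_tau_s):
            seg *= np.exp(-(t[i0:i1] - ev.onset_s) / neural.habituation_tau_s)
        drive[i0:i1] += seg
        if trans_amp != 0.0 and isinstance(ev.condition, Condition):
            w = int(round(trans_w / dt))
            burst = trans_amp * neural.base_gain * np.sign(sign)
            drive[i0: i0 + w] += burst
            drive[i1: i1 + w] += burst
    return drive


def simulate_voxel(paradigm: Paradigm, hrf: HRFParams, neural: NeuralModel,
                   noise: NoiseModel, *, baseline_level: float = 1000.0,
                   rng: np.random.Generator | None = None,
                   origin: str = "") -> TimeCourse:
    """Simulate one voxel's raw BOLD run.

    The percent-signal component is (neural drive (*) HRF) sampled at TR
    plus noise; the raw series is ``baseline_level * (1 + percent/100)``.
    With zero noise and a linear :class:`NeuralModel` the mapping from
    stimulus schedule to percent signal is exactly linear time-invariant.
    """
    dt = DT
    drive = neural_drive(paradigm, neural, dt=dt)
    n_fine = len(drive)
    kernel = hrf_eval(hrf, dt * np.arange(n_fine))
    signal_fine = np.convolve(drive, kernel)[:n_fine] * dt
    step = int(round(paradigm.tr_s / dt))
    signal = signal_fine[::step][: paradigm.n_volumes]

    n = len(signal)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    noise_series = np.zeros(n)
    t = paradigm.tr_s * np.arange(n)
    for f_hz, amp in noise.drift_components:
        if amp != 0.0:
            phase = rng.uniform(0, 2 * np.pi)
            noise_series += amp * np.sin(2 * np.pi * f_hz * t + phase)
    if noise.linear_trend_per_run != 0.0:
        noise_series += noise.linear_trend_per_run * (t / t[-1] - 0.5)
    if noise.white_sd > 0:
        noise_series += rng.normal(0.0, noise.white_sd, size=n)

    raw = baseline_level * (1.0 + (signal + noise_series) / 100.0)
    return TimeCourse(values=raw, tr_s=paradigm.tr_s, unit="raw", origin=origin)


# --- dataset-level simulation -------------------------------------------------

#: presets for injected deviation from superposition, per response type
NONLINEARITY_PRESETS: dict[str, dict] = {
    "none": {},
    "overest": {
        "increment": {1.0: 1.6, 3.0: 1.15, 6.0: 1.0},
        "decrement": {1.0: 1.6, 3.0: 1.15, 6.0: 1.0},
        "transient": (0.8, 0.5),
    },
    "underest": {
        "increment": {1.0: 0.65, 3.0: 0.9, 6.0: 1.0},
        "decrement": {1.0: 0.65, 3.0: 0.9, 6.0: 1.0},
    },
    # increments consistently overestimate; decrement patterns vary per voxel
    # from under- to overestimation
    "mixed": {
        "increment": {1.0: 1.6, 3.0: 1.15, 6.0: 1.0},
        "decrement": "per_voxel",
        "transient": (0.8, 0.5),
    },
}

#: plausible sub-box of the restricted HRF bounds that ground truth is drawn from
_TRUTH_RANGES = {
    "A": (2.0, 6.0),
    "mu1": (4.0, 7.0),
    "mu2": (9.0, 14.0),
    "beta1": (0.8, 1.4),
    "beta2": (0.8, 1.4),
    "c": (0.2, 0.6),
    "t_onset": (0.0, 1.5),
}


def sample_hrf(rng: np.random.Generator) -> HRFParams:
    """Draw a ground-truth HRF from plausible ranges inside the restricted bounds."""
    draw = {k: rng.uniform(*v) for k, v in _TRUTH_RANGES.items()}
    return HRFParams(**draw, sign=1, bounds_mode="restricted")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of :func:`simulate_dataset`."""

    seed: int = 0
    n_runs: int = 3
    tr_s: float = 1.0
    active_fraction: float = 1.0
    nonlinearity: str = "none"
    noise_sd: float = 0.5
    drift_components: tuple[tuple[float, float], ...] = ((0.003, 0.3), (0.008, 0.2))
    linear_trend_per_run: float = 0.5
    baseline_level: float = 1000.0
    decrement_gain: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("invalid config: active_fraction must be in [0, 1]")
        if self.nonlinearity not in NONLINEARITY_PRESETS:
            raise ValueError(
                f"invalid config: nonlinearity must be one of {sorted(NONLINEARITY_PRESETS)}"
            )
        if self.noise_sd < 0:
            raise ValueError("invalid config: noise_sd must be >= 0")
        if self.n_runs < 1:
            raise ValueError("invalid config: n_runs must be >= 1")
        if self.tr_s <= 0:
            raise ValueError("invalid config: tr_s must be > 0")

    @property
    def zero_noise(self) -> bool:
        return (self.noise_sd == 0 and self.linear_trend_per_run == 0
                and all(a == 0 for _, a in self.drift_components))


@dataclass(frozen=True)
class SimulatedVoxel:
    """One simulated voxel: ground truth plus raw runs."""

    voxel_id: int
    coords: tuple[int, int, int]
    hrf: HRFParams
    neural: NeuralModel
    active: bool
    localizer: TimeCourse
    adaptation_runs: tuple[TimeCourse, ...]


@dataclass(frozen=True)
class SyntheticDataset:
    """A full simulated experiment: paradigms plus per-voxel raw runs."""

    voxels: tuple[SimulatedVoxel, ...]
    localizer_paradigm: Paradigm
    adaptation_paradigms: tuple[Paradigm, ...]
    config: SimulationConfig

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def digest(self) -> str:
        """SHA-256 over every time course (bit-exact reproducibility check)."""
        h = hashlib.sha256()
        for vox in self.voxels:
            h.update(vox.localizer.values.tobytes())
            for run in vox.adaptation_runs:
                h.update(run.values.tobytes())
        return h.hexdigest()


def _grid_coords(n_voxels: int) -> list[tuple[int, int, int]]:
    """Raster-order coordinates on a near-square single-slice grid."""
    nx = int(np.ceil(np.sqrt(n_voxels)))
    return [(i % nx, i // nx, 0) for i in range(n_voxels)]


def _voxel_neural(config: SimulationConfig, active: bool,
                  rng: np.random.Generator) -> NeuralModel:
    preset = NONLINEARITY_PRESETS[config.nonlinearity]
    gains: dict[str, dict[float, float]] = {}
    for rt in ("increment", "decrement"):
        preset_gain = preset.get(rt)
        if preset_gain == "per_voxel":
            g1 = rng.uniform(0.6, 1.6)
            g3 = rng.uniform(0.85, 1.05)
            gains[rt] = {1.0: g1, 3.0: g3, 6.0: 1.0}
        elif preset_gain is None:
            gains[rt] = {1.0: 1.0, 3.0: 1.0, 6.0: 1.0}
        else:
            gains[rt] = dict(preset_gain)
    transient = preset.get("transient", (0.0, 0.5))
    return NeuralModel(
        base_gain=1.0 if active else 0.0,
        duration_gain=gains,
        onset_offset_transient=transient,
        decrement_gain=config.decrement_gain,
    )


def simulate_dataset(n_voxels: int, config: SimulationConfig | None = None) -> SyntheticDataset:
    """Simulate a dataset of ``n_voxels`` voxels under ``config``.

    The first ``ceil(n_voxels * active_fraction)`` voxels (contiguous on the
    grid, so they form a face-connected cluster) are active; the rest have
    zero response gain.  Each voxel draws its ground-truth HRF, noise and
    any per-voxel nonlinearity from an independent stream spawned from the
    master seed, so changing ``n_voxels`` does not perturb earlier voxels.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    config = config or SimulationConfig()
    master = np.random.SeedSequence(config.seed)
    paradigm_seeds = np.random.default_rng(master.spawn(1)[0]).integers(0, 2**31, size=config.n_runs)
    localizer = generate_paradigm("localizer", tr_s=config.tr_s)
    adaptation = tuple(
        generate_paradigm("adaptation", int(s), tr_s=config.tr_s) for s in paradigm_seeds
    )
    noise_template = NoiseModel(
        white_sd=config.noise_sd,
        drift_components=config.drift_components,
        linear_trend_per_run=config.linear_trend_per_run,
    )

    n_active = int(np.ceil(n_voxels * config.active_fraction))
    coords = _grid_coords(n_voxels)
    voxel_streams = master.spawn(n_voxels)
    voxels = []
    for vid in range(n_voxels):
        rng = np.random.default_rng(voxel_streams[vid])
        hrf = sample_hrf(rng)
        active = vid < n_active
        neural = _voxel_neural(config, active, rng)
        loc = simulate_voxel(localizer, hrf, neural, noise_template,
                             baseline_level=config.baseline_level, rng=rng,
                             origin=f"voxel{vid}/localizer")
        runs = tuple(
            simulate_voxel(par, hrf, neural, noise_template,
                           baseline_level=config.baseline_level, rng=rng,
                           origin=f"voxel{vid}/adaptation{ri}")
            for ri, par in enumerate(adaptation)
        )
        voxels.append(SimulatedVoxel(vid, coords[vid], hrf, neural, active, loc, runs))
    return SyntheticDataset(tuple(voxels), localizer, adaptation, config)


# --- signal-band estimation ---------------------------------------------------

def signal_band(values: np.ndarray, tr_s: float, power_fraction: float = 0.95
                ) -> tuple[float, float]:
    """Narrowest contiguous frequency interval holding ``power_fraction``
    of the non-DC spectral power of ``values``."""
    if not 0 < power_fraction < 1:
        raise ValueError("power_fraction must be in (0, 1)")
    x = np.asarray(values, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    spec = spec[1:]  # drop DC
    freqs = np.fft.rfftfreq(len(x), d=tr_s)[1:]
    total = spec.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: input has no non-DC power")
    target = power_fraction * total
    # two-pointer scan for the narrowest window with enough power
    best: tuple[float, int, int] | None = None
    lo = 0
    acc = 0.0
    for hi in range(len(spec)):
        acc += spec[hi]
        while acc - spec[lo] >= target:
            acc -= spec[lo]
            lo += 1
        if acc >= target:
            width = freqs[hi] - freqs[lo]
            if best is None or width < best[0]:
                best = (width, lo, hi)
    assert best is not None
    return float(freqs[best[1]]), float(freqs[best[2]])


def estimate_signal_band(paradigm: Paradigm, hrf: HRFParams,
                         power_fraction: float = 0.95) -> tuple[float, float]:
    """Signal frequency band of the noiseless response to ``paradigm``.

    Simulates a linear, noise-free voxel with the given HRF and returns
    the narrowest contiguous frequency interval containing
    ``power_fraction`` of the non-DC spectral power.  This is the
    simulation that motivates the choice of band-pass cutoffs.
    """
    neural = NeuralModel(adaptation_baseline=(0.0, 15.0))
    tc = simulate_voxel(paradigm, hrf, neural, NoiseModel.zero())
    percent = 100.0 * (tc.values / tc.values.mean() - 1.0)
    return signal_band(percent, paradigm.tr_s, power_fraction)
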