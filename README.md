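# bold-linearity

Voxel-wise superposition (linearity) analysis of BOLD fMRI signal
**increments and decrements**, built around a contrast-adaptation
paradigm, with a forward simulator of the full experiment as its primary
test surface.

Most fMRI analyses presume the BOLD response is linear and
time-invariant: the response to a long stimulus should equal the sum of
the short-stimulus response and its temporally shifted copies
(the superposition principle).  This package tests that assumption per
voxel, for both positive BOLD deflections (contrast increments from an
adapted baseline) and negative ones (contrast decrements), and
quantifies *how* superposition fails — overestimation or underestimation
of the long-stimulus response by transient-stimulus predictions.

## Who it is for

Researchers analyzing event-related fMRI with short stimuli (1–6 s), who
need to know whether linear-systems analysis (GLM convolution,
deconvolution) is safe for their responses — especially for BOLD signal
decrements, whose behavior is far less characterized than increments —
and methodologists who want a fully simulated, ground-truth-controlled
harness for linearity statistics.

## The statistics at its core

**Superposition prediction.** For a short-stimulus measured response
`M_short` (25 samples at TR = 1 s), the prediction of the long-stimulus
response is `P = Σ_{j=0}^{r−1} shift(M_short, j·d_short)` with
`r = d_long / d_short`; the analyzed pairs are 1→3 s, 1→6 s and 3→6 s.

**Dice index** (amplitude-sensitive similarity):

    s_Dice = 2 Σ_t P_t M_t / (Σ_t P_t² + Σ_t M_t²)  ∈ [−1, 1]

`s_Dice = 1` iff `P = M`, `−1` iff `P = −M`; unlike a correlation it
penalizes pure amplitude mismatch (`dice(kM, M) = 2k/(k²+1)`).
Significance is assessed against permutation nulls built by shuffling
time points of the per-run courses and re-running the identical
preprocessing.

**Two-gamma HRF and contrast index.** Each measured response is fitted
with a difference-of-gammas hemodynamic response function
`h(t) = A[g(t−t₀; α₁, β₁) − c·g(t−t₀; α₂, β₂)]` (with `αᵢ = μᵢβᵢ + 1`,
bounded trust-region least squares, Latin-hypercube multi-start),
convolved with the stimulus boxcar.  Peak amplitudes across durations
give the deviation statistic

    Contrast = (Amp_short − Amp_long) / (Amp_short + Amp_long)

which is 0 under linearity, > 0 for overestimation, < 0 for
underestimation.

**Selection and SNR.** Activated voxels are selected from a block-design
localizer by FIR-deconvolution r², permutation nulls, Benjamini–Hochberg
FDR and face-connected cluster filtering.  Per-voxel SNR is the DFT
magnitude at the 0.04 Hz task frequency of concatenated 25-s trials over
the mean magnitude in the 0.33–0.50 Hz noise band, with median-split
group comparisons (Wilcoxon signed-rank, Kolmogorov–Smirnov).

## Worked example

```python
import bold_linearity as bl

config = bl.SimulationConfig(seed=3, noise_sd=0.5, active_fraction=0.5,
                             nonlinearity="mixed")
dataset = bl.simulate_dataset(12, config)

settings = bl.AnalysisSettings(n_null=400, selection_q=0.01, seed=7)
result = bl.run_pipeline(dataset, settings)

print("selected voxels:", result.selected_ids)
for key, entry in sorted(result.dice_summary["conditions"].items()):
    dev = result.deviation_summary["conditions"][key]
    print(f"{key:18s} median Dice {entry['median_dice']:.3f} "
          f"({entry['percent_above_chance']:.0f}% above chance)  "
          f"median contrast {dev['median_contrast']:+.3f}")
snr = result.snr_summary["increment_vs_decrement"]
print(f"SNR increments vs decrements: median {snr['median_increment']:.0f} vs "
      f"{snr['median_decrement']:.0f} (Wilcoxon p = {snr['p']:.2g})")
```

Output:

```
selected voxels: [0, 1, 2, 3, 4, 5]
decrement_1to3     median Dice 0.788 (100% above chance)  median contrast +0.323
decrement_1to6     median Dice 0.760 (100% above chance)  median contrast +0.356
decrement_3to6     median Dice 0.976 (100% above chance)  median contrast +0.097
increment_1to3     median Dice 0.847 (100% above chance)  median contrast +0.282
increment_1to6     median Dice 0.739 (100% above chance)  median contrast +0.396
increment_3to6     median Dice 0.959 (100% above chance)  median contrast +0.134
SNR increments vs decrements: median 258 vs 177 (Wilcoxon p = 0.031)
```

Reading it: the permutation selection recovered exactly the six planted
active voxels.  The simulated nonlinearity (onset/offset neural
transients plus extra gain for 1-s stimuli) makes the 3→6 s predictions
nearly linear (Dice ≈ 0.96–0.98, contrast near 0) while the 1-s-based
predictions are less similar to the measured responses and
systematically **overestimate** them (right-shifted contrast); decrement
SNR is significantly lower than increment SNR, as the generator's weaker
decrement drive dictates.

The same pipeline is scriptable from the shell:

```sh
bold-linearity simulate --n-voxels 20 --seed 3 --nonlinearity mixed --out data/
bold-linearity report --data data/ --n-null 400 --out results/
```

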