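"""Forward simulator: paradigm structure, determinism, linearity ground
truth, and signal-band estimation."""

import numpy as np
import pytest

import bold_linearity as bl
from bold_linearity.core import CONDITIONS, Condition, Event, Paradigm
from bold_linearity.synthetic import sample_hrf, signal_band


def _single_event_paradigm(duration, rt="increment", onset=30.0, length=120.0):
    return Paradigm(
        events=(Event(onset, duration, Condition(rt, duration)),),
        run_length_s=length, tr_s=1.0, kind="adaptation", adaptation_onset_s=None,
    )


class TestParadigm:
    def test_adaptation_run_structure(self):
        par = bl.generate_paradigm("adaptation", seed=0)
        assert par.run_length_s == 890.0
        events = par.test_events()
        assert len(events) == 24
        counts = {}
        for ev in events:
            counts[ev.condition] = counts.get(ev.condition, 0) + 1
        assert set(counts) == set(CONDITIONS)
        assert all(n == 4 for n in counts.values())
        # each test event is followed by a 30-s adaptation gap
        for a, b in zip(events, events[1:]):
            assert b.onset_s - a.offset_s == 30.0

    def test_seed_changes_order_not_conditions(self):
        a = bl.generate_paradigm("adaptation", seed=0)
        b = bl.generate_paradigm("adaptation", seed=1)
        conds_a = sorted(ev.condition.label for ev in a.test_events())
        conds_b = sorted(ev.condition.label for ev in b.test_events())
        assert conds_a == conds_b
        assert [ev.condition for ev in a.test_events()] != \
               [ev.condition for ev in b.test_events()]

    def test_localizer_blocks(self):
        par = bl.generate_paradigm("localizer", seed=5)
        assert [ev.onset_s for ev in par.events] == [30.0, 90.0, 150.0, 210.0]
        assert all(ev.duration_s == 30.0 for ev in par.events)
        assert par.run_length_s == 240.0

    def test_events_per_condition_across_runs(self):
        runs = [bl.generate_paradigm("adaptation", s) for s in (0, 1, 2)]
        for cond in CONDITIONS:
            assert sum(len(p.events_for(cond)) for p in runs) == 12


class TestSimulateVoxel:
    HRF = bl.HRFParams(4.0, 5.0, 11.0, 1.1, 1.0, 0.4, 0.5)
    LINEAR = bl.NeuralModel(adaptation_baseline=(0.0, 15.0))

    def test_superposition_of_short_responses(self):
        """An LTI voxel's 6-s response equals the 3-s response plus its
        3-s-shifted copy."""
        resp = {}
        for d in (3.0, 6.0):
            par = _single_event_paradigm(d)
            tc = bl.simulate_voxel(par, self.HRF, self.LINEAR, bl.NoiseModel.zero())
            resp[d] = 100.0 * (tc.values / 1000.0 - 1.0)
        pred = resp[3.0].copy()
        pred[3:] += resp[3.0][:-3]
        assert np.max(np.abs(pred - resp[6.0])) < 1e-10

    def test_determinism(self):
        par = bl.generate_paradigm("adaptation", 3)
        nm = bl.NeuralModel()
        noise = bl.NoiseModel(seed=9)
        a = bl.simulate_voxel(par, self.HRF, nm, noise)
        b = bl.simulate_voxel(par, self.HRF, nm, noise)
        assert np.array_equal(a.values, b.values)

    def test_adaptation_pedestal_rises_then_decays(self):
        """Zero-noise run: signal rises after adaptation onset (30 s) and
        decays toward a nonzero pedestal during 30-90 s."""
        par = bl.generate_paradigm("adaptation", 0)
        nm = bl.NeuralModel()
        tc = bl.simulate_voxel(par, self.HRF, nm, bl.NoiseModel.zero())
        pct = 100.0 * (tc.values / 1000.0 - 1.0)
        assert pct[:28].max() < 1e-9          # flat rest baseline
        peak_idx = int(np.argmax(pct[:90]))
        assert 30 < peak_idx < 70             # rise after onset
        assert pct[88] < pct[peak_idx]        # decay under way
        assert pct[88] > 0.2 * pct[peak_idx]  # toward a pedestal, not zero

    def test_decrement_events_deflect_negative(self):
        par = _single_event_paradigm(3.0, rt="decrement")
        tc = bl.simulate_voxel(par, self.HRF, self.LINEAR, bl.NoiseModel.zero())
        pct = 100.0 * (tc.values / 1000.0 - 1.0)
        assert pct.min() < -0.1
        # dominant deflection is negative; only the undershoot rebound is positive
        assert abs(pct.min()) > pct.max()
        assert np.allclose(pct[:28], 0.0, atol=1e-9)

    def test_event_past_run_end_rejected(self):
        with pytest.raises(ValueError, match="past run end"):
            _single_event_paradigm(6.0, onset=118.0, length=120.0)


class TestSimulateDataset:
    def test_active_fraction_and_bounds(self):
        cfg = bl.SimulationConfig(seed=0, active_fraction=0.5)
        ds = bl.simulate_dataset(20, cfg)
        inactive = [v for v in ds.voxels if v.neural.base_gain == 0]
        assert len(inactive) == 10
        assert all(not v.active for v in inactive)
        assert all(0.5 <= v.hrf.mu1 <= 8.0 for v in ds.voxels)

    def test_seed_reproducibility_digest(self):
        cfg = bl.SimulationConfig(seed=4)
        assert bl.simulate_dataset(5, cfg).digest() == \
               bl.simulate_dataset(5, cfg).digest()

    def test_voxel_streams_independent_of_count(self):
        """Adding voxels must not perturb earlier voxels' data."""
        cfg = bl.SimulationConfig(seed=4)
        small = bl.simulate_dataset(3, cfg)
        large = bl.simulate_dataset(6, cfg)
        for a, b in zip(small.voxels, large.voxels):
            assert np.array_equal(a.localizer.values, b.localizer.values)

    @pytest.mark.parametrize("bad, msg", [
        ({"active_fraction": 1.5}, "active_fraction"),
        ({"nonlinearity": "bogus"}, "nonlinearity"),
        ({"noise_sd": -1.0}, "noise_sd"),
    ])
    def test_invalid_config_names_field(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            bl.SimulationConfig(**bad)

    def test_injected_gain_raises_contrast(self):
        """Raising the 1-s duration gain above the 3-s gain strictly
        increases the (1->3) contrast index on noise-free data."""
        cfg = bl.SimulationConfig(seed=8, noise_sd=0.0, drift_components=(),
                                  linear_trend_per_run=0.0)
        ds = bl.simulate_dataset(1, cfg)
        vox = ds.voxels[0]
        contrasts = []
        for g1 in (1.0, 1.5):
            neural = bl.NeuralModel(duration_gain={
                "increment": {1.0: g1, 3.0: 1.0, 6.0: 1.0},
                "decrement": {1.0: 1.0, 3.0: 1.0, 6.0: 1.0}})
            runs = [bl.simulate_voxel(p, vox.hrf, neural, bl.NoiseModel.zero())
                    for p in ds.adaptation_paradigms]
            resp = bl.preprocessing.measured_responses_for_voxel(
                runs, ds.adaptation_paradigms)
            amps = {d: bl.fit_hrf(resp[Condition("increment", d)], d,
                                  seed=3).amplitude for d in (1.0, 3.0)}
            contrasts.append(bl.contrast_index(amps[1.0], amps[3.0])[0])
        assert contrasts[1] > contrasts[0]


class TestSignalBand:
    HRF = bl.HRFParams(4.0, 5.0, 11.0, 1.1, 1.0, 0.4, 0.5)

    def test_localizer_band_starts_at_block_fundamental(self):
        loc = bl.generate_paradigm("localizer")
        f_lo, f_hi = bl.estimate_signal_band(loc, self.HRF, 0.95)
        # fundamental of the 60-s block cycle, within one DFT bin of the run
        assert f_lo == pytest.approx(1.0 / 60.0, abs=1.0 / 240.0)
        assert f_hi < 0.15

    def test_adaptation_band_motivates_low_pass(self):
        par = bl.generate_paradigm("adaptation", 0)
        _, f_hi = bl.estimate_signal_band(par, self.HRF, 0.99)
        assert f_hi <= 0.2

    def test_sinusoid_band_collapses(self):
        t = np.arange(600.0)
        f_lo, f_hi = signal_band(np.sin(2 * np.pi * 0.1 * t), 1.0, 0.95)
        assert f_lo == f_hi == pytest.approx(0.1)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate spectrum"):
            signal_band(np.ones(100), 1.0, 0.9)
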