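import numpy as np
import pytest

import casr_coop as cc
from casr_coop.oscillation import Peak, PeakConfig, _peaks_in_step


def make_trace(protocol, ratios, cell_id="c"):
    return cc.Trace(cell_id, protocol.time_grid(), ratios, protocol)


def inject_spikes(protocol, times, amplitude=0.5, sd=2.0, baseline=0.3, noise_sd=0.0, seed=0):
    grid = protocol.time_grid()
    y = np.full(grid.size, baseline)
    for t in times:
        y = y + amplitude * np.exp(-0.5 * ((grid - t) / sd) ** 2)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, grid.size)
    return make_trace(protocol, y)


class TestDetectPeaks:
    def test_finds_injected_spikes(self):
        proto = cc.StepProtocol.ramp([1.0], dwell_s=600.0)
        times = [50, 150, 250, 350, 450, 550]
        tr = inject_spikes(proto, times, amplitude=0.5, noise_sd=0.05, seed=1)
        peaks = cc.detect_peaks(tr)
        assert len(peaks) == 6
        assert np.allclose(sorted(p.time_s for p in peaks), times, atol=5)

    def test_false_positive_rate_on_noise(self):
        proto = cc.StepProtocol.ramp([1.0], dwell_s=300.0)
        n_spurious = 0
        for seed in range(200):
            tr = inject_spikes(proto, [], noise_sd=0.02, seed=seed)
            if cc.detect_peaks(tr):
                n_spurious += 1
        assert n_spurious <= 2  # >= 99% clean at prominence factor 3

    def test_constant_trace_has_no_peaks(self):
        proto = cc.StepProtocol.ramp([1.0], dwell_s=120.0)
        tr = make_trace(proto, np.full(proto.time_grid().size, 0.5))
        assert cc.detect_peaks(tr) == []

    def test_short_trace_rejected(self):
        proto = cc.StepProtocol.ramp([1.0], dwell_s=3.0)
        tr = make_trace(proto, np.linspace(0, 1, 3))
        with pytest.raises(ValueError, match="smoothing window"):
            cc.detect_peaks(tr)

    def test_monotone_in_prominence_factor(self):
        proto = cc.StepProtocol.ramp([1.0], dwell_s=600.0)
        tr = inject_spikes(
            proto, [60, 160, 260, 360, 460], amplitude=0.2, noise_sd=0.05, seed=4
        )
        counts = [
            len(cc.detect_peaks(tr, PeakConfig(prominence_factor=k)))
            for k in (1.0, 2.0, 3.0, 5.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassifyOscillatory:
    @pytest.mark.parametrize("n_peaks, expected", [(0, False), (1, False), (3, False), (4, True), (7, True)])
    def test_three_fluctuations_after_initial_peak(self, n_peaks, expected):
        peaks = [Peak(10.0 * i, 1.0, 0.5, 0) for i in range(n_peaks)]
        assert cc.classify_oscillatory(peaks) is expected

    def test_monotone_in_peaks(self):
        peaks = [Peak(10.0 * i, 1.0, 0.5, 0) for i in range(3)]
        assert not cc.classify_oscillatory(peaks)
        for i in range(3, 10):
            peaks.append(Peak(10.0 * i, 1.0, 0.5, 0))
            assert cc.classify_oscillatory(peaks)


class TestStartPoint:
    def test_wt_cell_starts_at_three_mM(self, wt_cell, wt_protocol):
        tr = cc.simulate_trace(wt_cell, wt_protocol, seed=0)
        assert cc.find_start_point(tr) == 3.0

    def test_onset_above_protocol_is_undefined(self, wt_protocol):
        params = cc.CellParams(onset_mM=50.0, plateau_mM=60.0, rate_fn=cc.constant_rate(1.3))
        tr = cc.simulate_trace(params, wt_protocol, seed=0)
        assert cc.find_start_point(tr) is None

    def test_loss_of_function_cell_under_extended_protocol(self):
        preset = cc.get_preset("L173P")
        proto = preset.protocol()
        params = cc.CellParams(onset_mM=12.5, plateau_mM=40.0, rate_fn=cc.constant_rate(1.3))
        tr = cc.simulate_trace(params, proto, seed=0)
        assert cc.find_start_point(tr) == 12.5


class TestFrequency:
    def test_recovers_generator_rate(self):
        proto = cc.StepProtocol.ramp([0.5, 3.0], dwell_s=300.0)
        params = cc.CellParams(onset_mM=3.0, plateau_mM=10.0, rate_fn=cc.constant_rate(1.3))
        freqs = [
            cc.compute_frequency(cc.simulate_trace(params, proto, seed=s), 3.0)
            for s in range(10)
        ]
        assert abs(np.mean(freqs) - 1.3) < 0.2

    def test_zero_when_no_spikes(self, wt_protocol):
        params = cc.CellParams(
            onset_mM=50.0, plateau_mM=60.0, rate_fn=cc.constant_rate(0.0), noise_sd=0.0
        )
        tr = cc.simulate_trace(params, wt_protocol, seed=0)
        assert cc.compute_frequency(tr, 3.0) == 0.0

    def test_exact_division(self):
        # 10 peaks (9 qualifying after the step transient) in a 6-min dwell
        proto = cc.StepProtocol.ramp([3.0], dwell_s=360.0)
        tr = inject_spikes(proto, [10.0 + 35 * i for i in range(10)])
        assert cc.compute_frequency(tr, 3.0) == pytest.approx(1.5)

    def test_unknown_step_raises_with_available_steps(self, wt_cell, wt_protocol):
        tr = cc.simulate_trace(wt_cell, wt_protocol, seed=0)
        with pytest.raises(KeyError, match="available steps"):
            cc.compute_frequency(tr, 2.7)

    def test_invariant_to_amplitude_rescaling(self, wt_cell, wt_protocol):
        tr = cc.simulate_trace(wt_cell, wt_protocol, seed=0)
        scaled = cc.Trace(tr.cell_id, tr.times_s, tr.ratios * 7.5, tr.protocol)
        assert cc.compute_frequency(scaled, 3.0) == cc.compute_frequency(tr, 3.0)


class TestEndPoint:
    def test_wt_cell_plateaus_at_five_mM(self, wt_cell, wt_protocol):
        tr = cc.simulate_trace(wt_cell, wt_protocol, seed=0)
        assert cc.find_end_point(tr) == 5.0

    def test_still_oscillating_at_top_step_is_undefined(self):
        preset = cc.get_preset("L173P")
        proto = preset.protocol()
        params = cc.CellParams(onset_mM=12.5, plateau_mM=100.0, rate_fn=cc.constant_rate(1.3))
        tr = cc.simulate_trace(params, proto, seed=0)
        assert cc.find_end_point(tr) is None

    def test_plateau_without_oscillation_reports_end_only(self, wt_protocol):
        # cell that plateaus at the first step above its (tiny) plateau threshold
        params = cc.CellParams(
            onset_mM=0.1, plateau_mM=0.2, rate_fn=cc.constant_rate(1.3), noise_sd=0.005
        )
        tr = cc.simulate_trace(params, wt_protocol, seed=0)
        features = cc.analyze_trace(tr)
        assert features.start_mM is None and not features.oscillatory
        assert features.end_mM == wt_protocol.steps[0].ca_mM


class TestPipelineRecovery:
    """Noiseless single cells recover the generator thresholds snapped to steps."""

    @pytest.mark.parametrize("name", list(cc.PRESETS))
    def test_threshold_recovery_all_presets(self, name):
        preset = cc.get_preset(name)
        proto = preset.protocol()
        o = preset.osc
        params = cc.CellParams(
            onset_mM=o.onset_median_mM,
            plateau_mM=o.plateau_median_mM,
            rate_fn=preset.rate_fn(),
            noise_sd=0.0,
        )
        tr = cc.simulate_trace(params, proto, seed=0)
        cas = [s.ca_mM for s in proto.steps]
        expected_start = next((c for c in cas if c >= o.onset_median_mM), None)
        if expected_start is not None and expected_start >= o.plateau_median_mM:
            expected_start = None  # cell plateaus before it can oscillate
        expected_end = next((c for c in cas if c >= o.plateau_median_mM), None)
        assert cc.find_start_point(tr) == expected_start
        assert cc.find_end_point(tr) == expected_end


class TestPopulationSummary:
    def test_degenerate_population_single_bin(self, wt_protocol):
        pop = cc.PopulationParams(
            n_cells=50,
            onset_median_mM=3.0,
            onset_cv=0.0,
            plateau_median_mM=5.0,
            plateau_cv=0.0,
            rate_fn=cc.constant_rate(1.3),
        )
        traces, _ = cc.simulate_population(pop, wt_protocol, seed=0)
        feats = [cc.analyze_trace(t) for t in traces]
        edges = [0.0] + [s.ca_mM for s in wt_protocol.steps]
        summary = cc.summarize_population(feats, edges)
        assert summary.fraction_oscillatory == 1.0
        assert summary.start_modal_fraction() == 1.0
        assert summary.modal_start_mM() == 3.0

    def test_fraction_oscillatory_tracks_nonresponders(self, wt_protocol):
        pop = cc.PopulationParams(
            n_cells=200,
            onset_median_mM=3.0,
            onset_cv=0.1,
            plateau_median_mM=5.0,
            plateau_cv=0.1,
            rate_fn=cc.constant_rate(1.3),
            fraction_nonresponding=0.25,
        )
        traces, truth = cc.simulate_population(pop, wt_protocol, seed=2)
        feats = [cc.analyze_trace(t) for t in traces]
        edges = [0.0] + [s.ca_mM for s in wt_protocol.steps]
        summary = cc.summarize_population(feats, edges)
        assert summary.fraction_oscillatory == pytest.approx(
            truth["responding"].mean(), abs=0.02
        )

    def test_wt_modal_start_fraction_calibration(self, wt_protocol):
        # the WT preset is calibrated so the modal starting bin (3.0 mM)
        # holds about half of the oscillatory cells
        preset = cc.get_preset("WT")
        pop = preset.population_params(n_cells=300, fraction_nonresponding=0.0)
        traces, _ = cc.simulate_population(pop, wt_protocol, seed=4)
        feats = [cc.analyze_trace(t) for t in traces]
        edges = [0.0] + [s.ca_mM for s in wt_protocol.steps]
        summary = cc.summarize_population(feats, edges)
        assert summary.modal_start_mM() == 3.0
        assert abs(summary.start_modal_fraction() - 0.53) < 0.10

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            cc.summarize_population([], [0, 1, 2])
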