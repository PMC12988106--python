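"""Deconvolution: binning, smoothing, peak spotting, NNLS purification."""

import numpy as np
import pytest

from ventree.annotation import Spectrum, weighted_cosine
from ventree.deconvolution import (
    ChromPeak,
    DeconvConfig,
    DeconvolvedSpectrum,
    IonTrace,
    detect_peaks,
    extract_ion_traces,
    model_peak_quality,
    process_run,
    reconstruction_residual,
    smooth_trace,
)
from ventree.errors import ConfigurationError, MalformedRunError
from ventree.evaluation import match_spectra_to_truth
from ventree.synthetic import PanelDesign, RawRun, default_sample_meta, simulate_run


def _run_from_traces(traces, rt=None):
    rt = np.arange(0.0, 1.0, 0.01) if rt is None else rt
    return RawRun("t", "Edmond", "active", rt, traces)


def _gaussian(rt, centre, height, sigma=0.0425):
    return height * np.exp(-0.5 * ((rt - centre) / sigma) ** 2)


class TestIonTraces:
    def test_single_centroid_single_trace(self):
        run = _run_from_traces({57.1: np.array([0.0, 5.0, 0.0])},
                               rt=np.array([0.0, 0.01, 0.02]))
        traces = extract_ion_traces(run)
        assert len(traces) == 1 and traces[0].mz_bin == 57
        assert traces[0].intensity.sum() == 5.0

    def test_half_rounds_up(self):
        rt = np.array([0.0, 0.01])
        run = _run_from_traces({57.4: np.ones(2), 57.6: np.ones(2),
                                58.5: np.ones(2)}, rt=rt)
        bins = {t.mz_bin for t in extract_ion_traces(run)}
        assert bins == {57, 58, 59}

    def test_total_intensity_conserved(self, small_library, quiet_design):
        ids = [c.id for c in small_library[:5]]
        run, _ = simulate_run(small_library, ids, quiet_design, seed=3)
        traces = extract_ion_traces(run)
        assert sum(t.intensity.sum() for t in traces) == pytest.approx(
            run.total_ion_current().sum(), rel=1e-12)

    def test_non_monotone_rt_rejected(self):
        run = _run_from_traces({57.0: np.ones(3)}, rt=np.array([0.0, 0.02, 0.01]))
        with pytest.raises(MalformedRunError):
            extract_ion_traces(run)


class TestSmoothing:
    def test_level_zero_identity(self):
        t = IonTrace(57, np.arange(5.0), np.array([1.0, 5.0, 2.0, 8.0, 3.0]))
        assert np.array_equal(smooth_trace(t, 0).intensity, t.intensity)

    def test_constant_trace_unchanged(self):
        t = IonTrace(57, np.arange(20.0), np.full(20, 7.0))
        assert np.allclose(smooth_trace(t, 3).intensity, 7.0)

    def test_unit_impulse_level_one(self):
        y = np.zeros(9)
        y[4] = 1.0
        sm = smooth_trace(IonTrace(57, np.arange(9.0), y), 1)
        # triangular weights (1,2,1)/4 -> centre value 0.5
        assert sm.intensity[4] == pytest.approx(0.5)
        assert sm.intensity[3] == pytest.approx(0.25)

    def test_mean_preserved_on_periodic_trace(self):
        # interior of a periodic trace (full windows): mean exact
        rng = np.random.default_rng(0)
        period = rng.random(16)
        y = np.tile(period, 10)
        sm = smooth_trace(IonTrace(57, np.arange(y.size, dtype=float), y), 3)
        interior = sm.intensity[16:-16]
        assert interior.mean() == pytest.approx(period.mean(), rel=1e-9)

    def test_negative_level_rejected(self):
        t = IonTrace(57, np.arange(3.0), np.ones(3))
        with pytest.raises(ConfigurationError):
            smooth_trace(t, -1)


class TestPeakDetection:
    def test_flat_trace_no_peaks(self):
        t = IonTrace(57, np.arange(0, 5, 0.01), np.full(500, 1e6))
        assert detect_peaks(t, DeconvConfig()) == []

    def test_single_gaussian_apex_location(self):
        rt = np.arange(5.0, 15.0, 0.01)
        t = IonTrace(57, rt, _gaussian(rt, 10.0, 1e6))
        peaks = detect_peaks(t, DeconvConfig())
        assert len(peaks) == 1
        assert abs(peaks[0].rt_apex - 10.0) <= 0.011

    def test_below_threshold_not_detected(self):
        rt = np.arange(5.0, 15.0, 0.01)
        t = IonTrace(57, rt, _gaussian(rt, 10.0, 1e5))
        assert detect_peaks(t, DeconvConfig()) == []

    def test_raising_threshold_never_adds_peaks(self):
        rng = np.random.default_rng(4)
        rt = np.arange(0.0, 20.0, 0.01)
        y = sum(_gaussian(rt, c, h) for c, h in
                [(3, 8e5), (7, 5e5), (12, 2e6), (16, 4e5)])
        y = y + rng.normal(0, 2e4, rt.size).clip(0)
        t = IonTrace(57, rt, y)
        n_low = len(detect_peaks(t, DeconvConfig(min_peak_height=3.5e5)))
        n_high = len(detect_peaks(t, DeconvConfig(min_peak_height=6e5)))
        assert n_high <= n_low


class TestModelPeakQuality:
    def _peak(self, y):
        rt = np.arange(float(y.size))
        trace = IonTrace(57, rt, y)
        apex = int(np.argmax(y))
        return ChromPeak(57, 0, apex, y.size - 1, 0.0, float(apex),
                         float(y.size - 1), float(y.max()), 0.0), trace

    def test_monotone_flanks_score_one(self):
        peak, trace = self._peak(np.array([0.0, 2, 5, 9, 5, 2, 0]))
        assert model_peak_quality(peak, trace).ideal_slope == pytest.approx(1.0)

    def test_zigzag_flanks_below_one(self):
        peak, trace = self._peak(np.array([0.0, 3, 1, 4, 9, 4, 1, 3, 0]))
        assert model_peak_quality(peak, trace).ideal_slope < 1.0

    def test_tall_smooth_beats_short_noisy(self):
        tall, tr1 = self._peak(np.array([0.0, 2e5, 6e5, 1e6, 6e5, 2e5, 0]))
        short, tr2 = self._peak(np.array([0.0, 2e4, 1e4, 1e5, 1e4, 2e4, 0]))
        assert (model_peak_quality(tall, tr1).quality
                > model_peak_quality(short, tr2).quality)

    def test_degenerate_peak_scores_zero(self):
        peak, trace = self._peak(np.array([0.0, 9, 0]))
        assert model_peak_quality(peak, trace).quality == 0.0


class TestDeconvolution:
    LOW = DeconvConfig(min_peak_height=1e3)

    def test_isolated_compound_exact(self, partial_overlap_pair, quiet_design):
        a, b = partial_overlap_pair
        run, _ = simulate_run([a, b], ["A"], quiet_design, seed=3)
        spectra = process_run(run, self.LOW)
        assert len(spectra) == 1
        cos = weighted_cosine(Spectrum.from_deconvolved(spectra[0]),
                              Spectrum.from_pairs(a.spectrum))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_pair_one_fwhm_apart(self, quiet_design):
        from ventree.synthetic import CompoundSpec
        a = CompoundSpec("A", "other", ((57, 100.0), (71, 50.0)), 40.0, 4e6)
        b = CompoundSpec("B", "other", ((91, 100.0), (105, 50.0)), 40.1, 3e6)
        run, _ = simulate_run([a, b], ["A", "B"], quiet_design, seed=1)
        spectra = process_run(run, self.LOW)
        for comp in (a, b):
            best = max(weighted_cosine(Spectrum.from_deconvolved(s),
                                       Spectrum.from_pairs(comp.spectrum))
                       for s in spectra)
            assert best >= 0.99

    def test_chimeric_pair_with_shared_fragments(self, partial_overlap_pair,
                                                 quiet_design):
        a, b = partial_overlap_pair
        run, _ = simulate_run([a, b], ["A", "B"], quiet_design, seed=3)
        spectra = process_run(run, self.LOW)
        for comp in (a, b):
            best = max(weighted_cosine(Spectrum.from_deconvolved(s),
                                       Spectrum.from_pairs(comp.spectrum))
                       for s in spectra)
            assert best >= 0.95

    def test_empty_run(self):
        run = _run_from_traces({})
        assert process_run(run) == []

    def test_deterministic(self, small_library, quiet_design):
        ids = [c.id for c in small_library[:6]]
        run, _ = simulate_run(small_library, ids, quiet_design, seed=9)
        assert process_run(run) == process_run(run)

    def test_apex_on_detected_peak(self, small_library, quiet_design):
        ids = [c.id for c in small_library[:6]]
        run, _ = simulate_run(small_library, ids, quiet_design, seed=9)
        cfg = DeconvConfig()
        apexes = set()
        for t in extract_ion_traces(run):
            apexes.update(round(p.rt_apex, 6) for p in detect_peaks(t, cfg))
        for s in process_run(run, cfg):
            assert round(s.rt_apex, 6) in apexes

    def test_raising_ei_cutoff_never_adds_fragments(self, small_library,
                                                    quiet_design):
        ids = [c.id for c in small_library[:6]]
        run, _ = simulate_run(small_library, ids, quiet_design, seed=9)
        lo = process_run(run, DeconvConfig(ei_cutoff=10.0))
        hi = process_run(run, DeconvConfig(ei_cutoff=1e5))
        assert sum(len(s.peaks) for s in hi) <= sum(len(s.peaks) for s in lo)

    def test_raising_min_height_never_adds_spectra(self, small_library,
                                                   quiet_design):
        ids = [c.id for c in small_library[:6]]
        run, _ = simulate_run(small_library, ids, quiet_design, seed=9)
        n_lo = len(process_run(run, DeconvConfig(min_peak_height=3.5e5)))
        n_hi = len(process_run(run, DeconvConfig(min_peak_height=1e6)))
        assert n_hi <= n_lo

    def test_reconstruction_residual_noise_free(self, partial_overlap_pair,
                                                quiet_design):
        a, b = partial_overlap_pair
        run, _ = simulate_run([a, b], ["A", "B"], quiet_design, seed=3)
        assert reconstruction_residual(run, self.LOW) < 1e-6

    def test_simulated_run_recovery(self, quiet_design):
        from ventree.synthetic import make_compound_library
        lib = make_compound_library(6, seed=2)
        by_id = {c.id: c for c in lib}
        design = PanelDesign(n_samples=2, sample_meta=default_sample_meta(2),
                             chimera_rate=0.2)
        ids = [c.id for c in lib][:50]
        run, truth = simulate_run(lib, ids, design, seed=23)
        res = match_spectra_to_truth(process_run(run),
                                     truth.placements["S01"], by_id)
        assert res.rate >= 0.9
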