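"""GC-EI-MS spectral deconvolution.

A raw run is reduced to purified, compound-specific spectra in four steps:

1. nominal-mass ion traces over the shared retention-time grid,
2. triangular (linear-weighted) moving-average smoothing,
3. two-axis peak spotting with model-peak quality scoring
   (ideal slope x sharpness x height), and
4. non-negative least-squares decomposition of every co-eluting fragment
   trace onto the model elution profiles, separating chimeric spectra.

Definitions of the quality terms and the sigma window follow common
deconvolution practice for unit-resolution EI data; all constants are
exposed on :class:`DeconvConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .errors import ConfigurationError, MalformedRunError
from .synthetic import RawRun

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeconvConfig:
    """Deconvolution parameters.

    ``min_peak_height`` defaults into the 3-4e5 detector-unit band typical
    for this data; ``sigma_window`` scales the model half-width when
    gathering fragment peaks; ``ei_cutoff`` drops reconstructed fragment
    amplitudes below threshold (detector units).
    """

    mz_bin_width: float = 1.0
    smoothing_level: int = 3
    min_peak_height: float = 3.5e5
    sigma_window: float = 0.5
    ei_cutoff: float = 10.0
    # fragment traces are gathered well below the model threshold; this
    # factor sets the fragment-level peak height floor
    fragment_height_factor: float = 0.1
    # hard cap on a peak's half-span, in scans (~4 peak widths): EMG tails
    # decay over minutes on noise-free traces and would otherwise drag
    # peak edges across unrelated neighbours
    max_half_span_scans: int = 40

    def __post_init__(self):
        if (self.mz_bin_width <= 0 or self.smoothing_level < 0
                or self.min_peak_height <= 0 or self.sigma_window <= 0
                or self.ei_cutoff <= 0 or self.fragment_height_factor <= 0):
            raise ConfigurationError("all DeconvConfig values must be positive")

    @property
    def fragment_min_height(self) -> float:
        return self.fragment_height_factor * self.min_peak_height


@dataclass
class IonTrace:
    mz_bin: int
    rt: np.ndarray
    intensity: np.ndarray


@dataclass
class ChromPeak:
    mz_bin: int
    i_left: int
    i_apex: int
    i_right: int
    rt_left: float
    rt_apex: float
    rt_right: float
    height: float
    area: float


@dataclass(frozen=True)
class ModelPeakScore:
    sharpness: float
    ideal_slope: float
    quality: float


@dataclass
class DeconvolvedSpectrum:
    """A purified compound spectrum at a retention-time apex."""

    rt_apex: float
    model_mz: int
    peaks: tuple[tuple[int, float], ...]  # (m/z bin, relative intensity 0-100]
    amplitude: float  # base-peak amplitude, detector units

    @property
    def base_peak(self) -> int:
        return max(self.peaks, key=lambda p: p[1])[0]


def extract_ion_traces(run: RawRun, bin_width: float = 1.0) -> list[IonTrace]:
    """Bin centroids to nominal mass; .5 rounds up; intensity conserved."""
    rt = np.asarray(run.rt, dtype=float)
    if rt.size > 1 and np.any(np.diff(rt) <= 0):
        raise MalformedRunError("retention times must be strictly increasing")
    binned: dict[int, np.ndarray] = {}
    for mz, trace in run.traces.items():
        b = int(math.floor(mz / bin_width + 0.5))
        if b in binned:
            binned[b] = binned[b] + np.asarray(trace, dtype=float)
        else:
            binned[b] = np.asarray(trace, dtype=float).copy()
    return [IonTrace(b, rt, binned[b]) for b in sorted(binned)]


def smooth_trace(trace: IonTrace, level: int) -> IonTrace:
    """Linear-weighted (triangular) moving average, window 2*level+1.

    Edge windows are truncated and renormalized, so a constant trace is
    reproduced exactly everywhere.
    """
    if level < 0:
        raise ConfigurationError("smoothing level must be >= 0")
    if level == 0:
        return IonTrace(trace.mz_bin, trace.rt, trace.intensity.copy())
    w = np.concatenate([np.arange(1, level + 2), np.arange(level, 0, -1)]).astype(float)
    y = np.asarray(trace.intensity, dtype=float)
    num = np.convolve(y, w, mode="same")
    den = np.convolve(np.ones_like(y), w, mode="same")
    return IonTrace(trace.mz_bin, trace.rt, num / den)


def _edges(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk down both flanks until the first rise (local minimum) or floor."""
    i = apex
    while i > 0 and y[i - 1] < y[i]:
        i -= 1
    j = apex
    n = y.size
    while j < n - 1 and y[j + 1] < y[j]:
        j += 1
    return i, j


def detect_peaks(trace: IonTrace, config: DeconvConfig,
                 min_height: float | None = None,
                 smoothed: IonTrace | None = None) -> list[ChromPeak]:
    """Spot significant peaks on the smoothed trace.

    Apexes are local maxima of the smoothed trace at or above
    ``min_peak_height`` (or an explicit ``min_height``); edges sit at the
    nearest local minima of the smoothed trace on either flank.
    """
    min_height = config.min_peak_height if min_height is None else min_height
    sm = smoothed or smooth_trace(trace, config.smoothing_level)
    y = sm.intensity
    if y.size < 3 or y.max() < min_height:
        return []
    # prominence keeps only peaks rising min_height above their local
    # baseline, i.e. significant above the noise floor / UCM hump
    apexes, _ = find_peaks(y, height=min_height, prominence=min_height)
    peaks = []
    for a in apexes:
        a = int(a)
        i, j = _edges(y, a)
        i = max(i, a - config.max_half_span_scans)
        j = min(j, a + config.max_half_span_scans)
        if j - i < 2:
            continue
        area = float(np.trapezoid(trace.intensity[i:j + 1], trace.rt[i:j + 1]))
        peaks.append(ChromPeak(
            trace.mz_bin, i, int(a), j,
            float(trace.rt[i]), float(trace.rt[a]), float(trace.rt[j]),
            float(y[a]), area,
        ))
    return peaks


def model_peak_quality(peak: ChromPeak, trace: IonTrace) -> ModelPeakScore:
    """Score a candidate model peak by ideal slope and sharpness.

    ideal_slope = 1 - (counter-directional steps / total steps), averaged
    over the two flanks; sharpness = mean flank rise per step divided by
    the square root of the apex height; quality multiplies both by height.
    Degenerate peaks (three points or fewer) score zero.
    """
    y = np.asarray(trace.intensity, dtype=float)
    i, a, j = peak.i_left, peak.i_apex, peak.i_right
    if j - i + 1 <= 3:
        return ModelPeakScore(0.0, 0.0, 0.0)
    height = max(y[a], 1e-12)

    left = np.diff(y[i:a + 1])
    right = np.diff(y[a:j + 1])
    slopes = []
    sharps = []
    for flank, good_sign in ((left, 1.0), (right, -1.0)):
        steps = flank.size
        if steps == 0:
            continue
        wrong = int(np.sum(flank * good_sign < 0))
        slopes.append(1.0 - wrong / steps)
        rise = abs(y[a] - (y[i] if good_sign > 0 else y[j]))
        sharps.append((rise / steps) / math.sqrt(height))
    ideal_slope = float(np.mean(slopes)) if slopes else 0.0
    sharpness = float(np.mean(sharps)) if sharps else 0.0
    return ModelPeakScore(sharpness, ideal_slope, float(height * ideal_slope * sharpness))


def _half_width_scans(y: np.ndarray, apex: int, left: int, right: int) -> int:
    """Half-width at half-maximum of the smoothed model peak, in scans."""
    half = y[apex] / 2.0
    i = apex
    while i > left and y[i] > half:
        i -= 1
    j = apex
    while j < right and y[j] > half:
        j += 1
    return max((j - i) // 2, 1)


def _select_models(
    peaks: list[ChromPeak],
    scored: dict[int, ModelPeakScore],
    eligible: list[int],
    tol_scans: int = 1,
) -> list[tuple[ChromPeak, list[ChromPeak]]]:
    """Cluster co-apexing candidates; keep one model per apex cluster.

    Heads are taken in quality order (equal quality: earlier rt wins); a
    candidate within ``tol_scans`` of an existing head joins that head's
    cluster. Returns (head, members-including-head) per cluster.
    """
    order = sorted(
        eligible,
        key=lambda k: (-scored[k].quality, peaks[k].rt_apex, peaks[k].mz_bin),
    )
    heads: list[int] = []
    members: dict[int, list[int]] = {}
    for k in order:
        for h in heads:
            if abs(peaks[k].i_apex - peaks[h].i_apex) <= tol_scans:
                members[h].append(k)
                break
        else:
            heads.append(k)
            members[k] = [k]
    # fragment-tier peaks join the nearest cluster too (pure weak traces
    # sharpen the median profile)
    for k, p in enumerate(peaks):
        if k in members or any(k in ms for ms in members.values()):
            continue
        near = [h for h in heads if abs(p.i_apex - peaks[h].i_apex) <= tol_scans]
        if near:
            members[near[0]].append(k)
    heads.sort(key=lambda k: (peaks[k].rt_apex, peaks[k].mz_bin))
    return [(peaks[h], [peaks[m] for m in members[h]]) for h in heads]


def deconvolute_window(
    peaks: list[ChromPeak],
    traces: dict[int, IonTrace],
    config: DeconvConfig,
    smoothed: dict[int, IonTrace] | None = None,
    return_fit: bool = False,
):
    """Decompose a group of co-eluting chromatographic peaks.

    Model peaks are the highest-quality non-redundant apexes at or above
    ``min_peak_height``; every fragment trace with a peak apex within
    ``sigma_window`` x the model half-width of a model apex is decomposed
    by NNLS onto the smoothed model elution profiles; per-model fragment
    amplitudes below ``ei_cutoff`` are dropped.
    """
    if not peaks:
        return ([], None) if return_fit else []
    if smoothed is None:
        smoothed = {b: smooth_trace(traces[b], config.smoothing_level)
                    for b in {p.mz_bin for p in peaks}}
    scored = {k: model_peak_quality(p, smoothed[p.mz_bin]) for k, p in enumerate(peaks)}
    eligible = [k for k, p in enumerate(peaks)
                if p.height >= config.min_peak_height]
    clusters = _select_models(peaks, scored, eligible)
    if not clusters:
        return ([], None) if return_fit else []
    models = [head for head, _ in clusters]

    lo = min(p.i_left for p in peaks)
    hi = max(p.i_right for p in peaks)
    idx = np.arange(lo, hi + 1)

    # local baseline per trace (10th percentile over the window) removes
    # the UCM hump and any stacked noise floor before decomposition
    def _corrected(bin_id: int) -> np.ndarray:
        y = smoothed[bin_id].intensity[lo:hi + 1]
        return np.clip(y - np.percentile(y, 10.0), 0.0, None)

    profiles = np.zeros((idx.size, len(models)))
    windows = []
    for m, (model, members) in enumerate(clusters):
        # initial elution profile: pointwise median of the normalized member
        # traces, which votes out members contaminated by a co-eluter
        # (refined below by alternating least squares)
        shapes = []
        for mem in members:
            yc = _corrected(mem.mz_bin)
            ref = yc[model.i_apex - lo]
            if ref > 0:
                shapes.append(yc / ref)
        if shapes:
            prof = np.median(shapes, axis=0)
        else:
            prof = _corrected(model.mz_bin)
        prof = np.clip(prof, 0.0, None)
        # confine the profile to the model peak's own span: the median
        # cannot vote out peaks that all members share elsewhere in the
        # region (homologous compounds on common fragment bins)
        prof[:model.i_left - lo] = 0.0
        prof[model.i_right - lo + 1:] = 0.0
        peak_val = prof.max()
        if peak_val > 0:
            prof /= peak_val
        y = smoothed[model.mz_bin].intensity
        hw = _half_width_scans(y, model.i_apex, model.i_left, model.i_right)
        profiles[:, m] = prof
        windows.append(max(int(round(config.sigma_window * hw)), 1))

    def _belongs(p: ChromPeak, model: ChromPeak, w: int) -> bool:
        # apex within the model window, or the fragment peak (e.g. a merged
        # chimeric peak) spans the model apex
        return (abs(p.i_apex - model.i_apex) <= w
                or p.i_left <= model.i_apex <= p.i_right)

    # fragment traces attributed to at least one model window
    frag_bins: list[int] = []
    columns: list[np.ndarray] = []
    for b in sorted({p.mz_bin for p in peaks}):
        bin_peaks = [p for p in peaks if p.mz_bin == b]
        near_any = any(
            _belongs(p, m, w)
            for p in bin_peaks
            for m, w in zip(models, windows)
        )
        if not near_any:
            continue
        frag_bins.append(b)
        columns.append(_corrected(b))

    if not frag_bins:
        return ([], None) if return_fit else []
    Y = np.column_stack(columns)

    def _solve_amps(P: np.ndarray) -> np.ndarray:
        A = np.zeros((len(models), len(frag_bins)))
        for f in range(len(frag_bins)):
            try:
                coef, _ = nnls(P, Y[:, f])
            except Exception:  # singular / no convergence
                log.warning("NNLS failed for m/z %d; falling back to apex assignment",
                            frag_bins[f])
                coef = np.array([Y[m.i_apex - lo, f] for m in models])
            A[:, f] = coef
        return A

    amps = _solve_amps(profiles)

    # MCR-ALS refinement: alternate nonnegative updates of the elution
    # profiles and the fragment amplitudes. The member-median profile is
    # only an initial guess; when co-eluters share most fragments (e.g.
    # homologous pairs) alternating least squares converges to the exact
    # bilinear factorization as long as some fragments differ
    ynorm = max(np.linalg.norm(Y), 1e-30)
    prev_res = np.inf
    for _ in range(2000):
        res = np.linalg.norm(Y - profiles @ amps)
        if res <= 1e-9 * ynorm or res > 0.999 * prev_res:
            break  # converged, or stalled (noise floor reached)
        prev_res = res
        C = np.zeros_like(profiles)
        S = amps.T  # (n_frag, k)
        for t in range(C.shape[0]):
            try:
                coef, _ = nnls(S, Y[t, :])
            except Exception:
                continue
            C[t, :] = coef
        peak_vals = C.max(axis=0)
        for m in np.flatnonzero(peak_vals <= 0):
            C[:, m] = profiles[:, m]  # keep previous estimate
            peak_vals[m] = 1.0
        profiles = C / peak_vals
        amps = _solve_amps(profiles)

    # per-trace noise scale from the NNLS residual (robust MAD estimate);
    # a retained fragment must rise clear of its own trace's noise
    resid = Y - profiles @ amps
    noise_scale = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=0)),
                                     axis=0)

    spectra = []
    for m, model in enumerate(models):
        frag = [
            (b, a) for (b, a, ns) in zip(frag_bins, amps[m], noise_scale)
            if a >= max(config.ei_cutoff, 3.0 * ns)
        ]
        # keep only fragments with a peak belonging to this model's window
        frag = [
            (b, a) for b, a in frag
            if any(p.mz_bin == b and _belongs(p, model, windows[m]) for p in peaks)
        ]
        if not frag:
            continue
        base = max(a for _, a in frag)
        # the purified base peak must itself be significant: models whose
        # baseline-corrected amplitude stays below the peak-height floor
        # are baseline undulations, not compounds
        if base < config.min_peak_height:
            continue
        rel = tuple(sorted((b, 100.0 * a / base) for b, a in frag))
        spectra.append(DeconvolvedSpectrum(model.rt_apex, model.mz_bin, rel, base))
    if return_fit:
        return spectra, (np.array(frag_bins), Y, profiles, amps)
    return spectra


def _group_windows(peaks: list[ChromPeak]) -> list[list[ChromPeak]]:
    """Connected components of peaks whose [left, right] spans overlap."""
    if not peaks:
        return []
    order = sorted(peaks, key=lambda p: (p.i_left, p.i_apex, p.mz_bin))
    groups: list[list[ChromPeak]] = [[order[0]]]
    reach = order[0].i_right
    for p in order[1:]:
        if p.i_left <= reach:
            groups[-1].append(p)
            reach = max(reach, p.i_right)
        else:
            groups.append([p])
            reach = p.i_right
    return groups


def reconstruction_residual(run: RawRun, config: DeconvConfig | None = None) -> float:
    """Worst relative L2 error of the NNLS reconstruction over all windows.

    For each co-elution window, compares the windowed fragment traces
    against model profiles x fragment amplitudes; on noise-free input the
    decomposition is exact and this is at floating-point level.
    """
    config = config or DeconvConfig()
    traces = {t.mz_bin: t for t in extract_ion_traces(run, config.mz_bin_width)}
    smoothed = {b: smooth_trace(t, config.smoothing_level) for b, t in traces.items()}
    model_peaks: list[ChromPeak] = []
    frag_peaks: list[ChromPeak] = []
    for b, t in traces.items():
        for p in detect_peaks(t, config, min_height=config.fragment_min_height,
                              smoothed=smoothed[b]):
            (model_peaks if p.height >= config.min_peak_height else frag_peaks).append(p)
    worst = 0.0
    for group in _group_windows(model_peaks):
        lo = min(p.i_left for p in group)
        hi = max(p.i_right for p in group)
        extra = [p for p in frag_peaks if lo <= p.i_apex <= hi]
        _, fit = deconvolute_window(group + extra, traces, config, smoothed,
                                    return_fit=True)
        if fit is None:
            continue
        _, Y, profiles, amps = fit
        denom = np.linalg.norm(Y)
        if denom > 0:
            worst = max(worst, float(np.linalg.norm(Y - profiles @ amps) / denom))
    return worst


def process_run(run: RawRun, config: DeconvConfig | None = None) -> list[DeconvolvedSpectrum]:
    """Full deconvolution of one raw run; deterministic.

    Model-level peaks (>= ``min_peak_height``) define the co-elution
    windows; fragment-level peaks are gathered down to
    ``fragment_min_height`` and attributed to the window containing them.
    """
    config = config or DeconvConfig()
    traces = {t.mz_bin: t for t in extract_ion_traces(run, config.mz_bin_width)}
    smoothed = {b: smooth_trace(t, config.smoothing_level) for b, t in traces.items()}
    model_peaks: list[ChromPeak] = []
    frag_peaks: list[ChromPeak] = []
    for b, t in traces.items():
        for p in detect_peaks(t, config, min_height=config.fragment_min_height,
                              smoothed=smoothed[b]):
            (model_peaks if p.height >= config.min_peak_height else frag_peaks).append(p)
    spectra: list[DeconvolvedSpectrum] = []
    for group in _group_windows(model_peaks):
        lo = min(p.i_left for p in group)
        hi = max(p.i_right for p in group)
        extra = [p for p in frag_peaks if lo <= p.i_apex <= hi]
        spectra.extend(deconvolute_window(group + extra, traces, config, smoothed))
    spectra.sort(key=lambda s: (s.rt_apex, s.model_mz))
    log.info("run %s: %d traces, %d model peaks, %d purified spectra",
             run.sample_id, len(traces), len(model_peaks), len(spectra))
    return spectra
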