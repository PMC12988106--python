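"""Spectral similarity, library annotation, panel alignment, co-annotation.

Similarity is a square-root-intensity weighted cosine with greedy nearest
m/z matching; library annotation combines forward cosine, a matched-peaks
(reverse) cosine, and the fraction of significant reference peaks found in
the query. Alignment merges deconvolved spectra across runs by a combined
retention-time / EI-similarity score, after which co-annotation retains
the features detected in every sample — the panel-wide compound set the
relatedness tree is built on. A triple-threshold sweep (20/50/70 % by
default) cross-validates the stability of that set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .deconvolution import DeconvolvedSpectrum
from .errors import (
    ConfigurationError,
    InternalConsistencyError,
    UndefinedSimilarityError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spectrum:
    """A stick spectrum normalized to base peak 100, sorted by m/z."""

    peaks: tuple[tuple[float, float], ...]

    @staticmethod
    def from_pairs(pairs) -> "Spectrum":
        pairs = [(float(m), float(i)) for m, i in pairs if i > 0]
        if not pairs:
            raise UndefinedSimilarityError("empty spectrum")
        top = max(i for _, i in pairs)
        return Spectrum(tuple(sorted((m, 100.0 * i / top) for m, i in pairs)))

    @staticmethod
    def from_deconvolved(s: DeconvolvedSpectrum) -> "Spectrum":
        return Spectrum.from_pairs(s.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class LibraryRecord:
    name: str
    class_label: str
    spectrum: Spectrum
    formula: str | None = None


@dataclass(frozen=True)
class MatchResult:
    record_name: str
    forward: float
    reverse: float
    presence: float

    @property
    def total(self) -> float:
        return (self.forward + self.reverse + self.presence) / 3.0


@dataclass(frozen=True)
class AnnotationConfig:
    min_total: float = 0.70
    mz_tol: float = 0.5
    presence_min_rel: float = 10.0  # reference peaks >= this count for presence

    def __post_init__(self):
        if not 0.0 < self.min_total <= 1.0:
            raise ConfigurationError("min_total must lie in (0, 1]")
        if self.mz_tol <= 0:
            raise ConfigurationError("mz_tol must be positive")


@dataclass(frozen=True)
class AlignConfig:
    rt_tol: float = 0.075  # minutes
    sim_threshold: float = 0.70
    rt_factor: float = 0.5
    ei_factor: float = 0.5
    mz_tol: float = 0.5
    # within-run duplicate suppression: two spectra this close in rt and
    # this similar are one compound reported twice by deconvolution
    dedup_rt_tol: float = 0.03
    dedup_min_cos: float = 0.85

    def __post_init__(self):
        if self.rt_factor < 0 or self.ei_factor < 0:
            raise ConfigurationError("factors must be >= 0")
        if abs(self.rt_factor + self.ei_factor - 1.0) > 1e-9:
            raise ConfigurationError("rt_factor + ei_factor must equal 1")


def match_peaks(a: Spectrum, b: Spectrum, mz_tol: float) -> list[tuple[int, int]]:
    """Greedy nearest-m/z peak pairing within tolerance; each peak used once."""
    cands = []
    bmz = b.mz
    for i, (ma, _) in enumerate(a.peaks):
        lo = np.searchsorted(bmz, ma - mz_tol)
        hi = np.searchsorted(bmz, ma + mz_tol, side="right")
        for j in range(lo, hi):
            cands.append((abs(ma - bmz[j]), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def weighted_cosine(a: Spectrum, b: Spectrum, mz_tol: float = 0.5) -> float:
    """Sqrt-intensity weighted cosine over the union of matched dimensions."""
    if not a.peaks or not b.peaks:
        raise UndefinedSimilarityError("cannot score an empty spectrum")
    pairs = match_peaks(a, b, mz_tol)
    wa = np.sqrt(a.intensity)
    wb = np.sqrt(b.intensity)
    dot = sum(wa[i] * wb[j] for i, j in pairs)
    denom = np.linalg.norm(wa) * np.linalg.norm(wb)
    return float(min(max(dot / denom, 0.0), 1.0))


def total_similarity(query: Spectrum, ref: Spectrum,
                     cfg: AnnotationConfig | None = None) -> MatchResult:
    """Composite match score: mean of forward, reverse, and presence.

    forward — weighted cosine over all peaks of both spectra;
    reverse — cosine restricted to the matched peak pairs (1.0 when the
    query's fragments are a proportional subset of the reference);
    presence — fraction of significant (>= 10 % relative) reference peaks
    matched in the query.
    """
    cfg = cfg or AnnotationConfig()
    if not query.peaks or not ref.peaks:
        raise UndefinedSimilarityError("cannot score an empty spectrum")
    pairs = match_peaks(query, ref, cfg.mz_tol)
    wq = np.sqrt(query.intensity)
    wr = np.sqrt(ref.intensity)
    dot = sum(wq[i] * wr[j] for i, j in pairs)
    forward = dot / (np.linalg.norm(wq) * np.linalg.norm(wr))
    if pairs:
        nq = np.sqrt(sum(wq[i] ** 2 for i, _ in pairs))
        nr = np.sqrt(sum(wr[j] ** 2 for _, j in pairs))
        reverse = dot / (nq * nr)
    else:
        reverse = 0.0
    sig = [j for j, (_, inten) in enumerate(ref.peaks)
           if inten >= cfg.presence_min_rel]
    matched_ref = {j for _, j in pairs}
    presence = (sum(1 for j in sig if j in matched_ref) / len(sig)) if sig else 0.0
    clamp = lambda x: float(min(max(x, 0.0), 1.0))
    return MatchResult("", clamp(forward), clamp(reverse), clamp(presence))


def match_library(spectrum: Spectrum, library: list[LibraryRecord],
                  cfg: AnnotationConfig | None = None) -> list[MatchResult]:
    """Score against every record, best first; ties broken by record name."""
    cfg = cfg or AnnotationConfig()
    results = []
    for rec in library:
        r = total_similarity(spectrum, rec.spectrum, cfg)
        results.append(MatchResult(rec.name, r.forward, r.reverse, r.presence))
    results.sort(key=lambda r: (-r.total, r.record_name))
    return results


def annotate(spectrum: Spectrum, library: list[LibraryRecord],
             cfg: AnnotationConfig | None = None) -> MatchResult | None:
    """Best library hit, or None when the top total misses min_total."""
    cfg = cfg or AnnotationConfig()
    results = match_library(spectrum, library, cfg)
    if results and results[0].total >= cfg.min_total:
        return results[0]
    return None


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class Hit:
    sample_id: str
    rt: float
    amplitude: float
    spectrum: Spectrum
    score: float = 0.0  # identification score


@dataclass
class AlignedFeature:
    feature_id: str
    hits: dict[str, Hit]
    representative: Spectrum
    annotation: tuple[str, float] | None = None
    class_label: str | None = None

    @property
    def mean_rt(self) -> float:
        return float(np.mean([h.rt for h in self.hits.values()]))


def _pair_score(h1: Hit, h2: Hit, cfg: AlignConfig) -> float | None:
    drt = abs(h1.rt - h2.rt)
    if drt > cfg.rt_tol:
        return None
    cos = weighted_cosine(h1.spectrum, h2.spectrum, cfg.mz_tol)
    if cos < cfg.sim_threshold:
        return None
    return cfg.rt_factor * (1.0 - drt / cfg.rt_tol) + cfg.ei_factor * cos


class _Union:
    def __init__(self, n): self.p = list(range(n))
    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x
    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def _dedupe_run(spectra: list[DeconvolvedSpectrum], cfg: AlignConfig) -> list[DeconvolvedSpectrum]:
    """Collapse within-run ghosts: near-identical spectra a scan or two apart."""
    order = sorted(spectra, key=lambda s: (-s.amplitude, s.rt_apex, s.model_mz))
    kept: list[DeconvolvedSpectrum] = []
    for s in order:
        dup = any(
            abs(s.rt_apex - k.rt_apex) <= cfg.dedup_rt_tol
            and weighted_cosine(Spectrum.from_deconvolved(s),
                                Spectrum.from_deconvolved(k),
                                cfg.mz_tol) >= cfg.dedup_min_cos
            for k in kept
        )
        if not dup:
            kept.append(s)
    kept.sort(key=lambda s: (s.rt_apex, s.model_mz))
    return kept


def _candidate_pairs(hits: list[Hit], cfg: AlignConfig):
    """All cross-sample hit pairs within rt_tol with cosine >= threshold."""
    order = sorted(range(len(hits)), key=lambda k: (hits[k].rt, hits[k].sample_id))
    rts = [hits[k].rt for k in order]
    pairs = []
    for a in range(len(order)):
        b = a + 1
        while b < len(order) and rts[b] - rts[a] <= cfg.rt_tol:
            i, j = order[a], order[b]
            if hits[i].sample_id != hits[j].sample_id:
                s = _pair_score(hits[i], hits[j], cfg)
                if s is not None:
                    i0, j0 = min(i, j), max(i, j)
                    pairs.append((s, i0, j0))
            b += 1
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    return pairs


def align_panel(
    per_run: dict[str, list[DeconvolvedSpectrum]],
    cfg: AlignConfig | None = None,
    library: list[LibraryRecord] | None = None,
    ann_cfg: AnnotationConfig | None = None,
) -> list[AlignedFeature]:
    """Merge deconvolved spectra across runs into aligned features.

    Candidate pairs need |drt| <= rt_tol and weighted cosine >= threshold;
    the combined score rt_factor*(1 - |drt|/rt_tol) + ei_factor*cosine is
    processed best-first, merging groups only when their sample sets are
    disjoint (each run contributes at most one hit per feature). Input
    order of runs does not affect the result.
    """
    cfg = cfg or AlignConfig()
    ann_cfg = ann_cfg or AnnotationConfig()
    if len(per_run) < 2:
        raise ConfigurationError("alignment needs at least two runs")
    hits: list[Hit] = []
    for sid in sorted(per_run):
        for s in _dedupe_run(per_run[sid], cfg):
            hits.append(Hit(sid, s.rt_apex, s.amplitude,
                            Spectrum.from_deconvolved(s)))
    uf = _Union(len(hits))
    samples: dict[int, set[str]] = {}
    conflicts = 0
    for s, i, j in _candidate_pairs(hits, cfg):
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        si = samples.get(ri, {hits[ri].sample_id})
        sj = samples.get(rj, {hits[rj].sample_id})
        if si & sj:
            conflicts += 1
            continue
        uf.union(ri, rj)
        samples[uf.find(ri)] = si | sj
    if conflicts:
        log.info("alignment: %d conflicting merges skipped (resolved by score)",
                 conflicts)

    groups: dict[int, list[int]] = {}
    for k in range(len(hits)):
        groups.setdefault(uf.find(k), []).append(k)

    # consolidate split groups: two groups this close in rt whose member
    # spectra are near-identical are one compound reported twice (ghost
    # apexes a couple of scans apart); keep the stronger hit per run
    glist = sorted(groups.values(),
                   key=lambda g: float(np.mean([hits[k].rt for k in g])))
    merged: list[list[int]] = []
    for g in glist:
        g_rt = float(np.mean([hits[k].rt for k in g]))
        target = None
        for prev in reversed(merged):
            p_rt = float(np.mean([hits[k].rt for k in prev]))
            if g_rt - p_rt > cfg.dedup_rt_tol:
                break
            ga = max(g, key=lambda k: hits[k].amplitude)
            pa = max(prev, key=lambda k: hits[k].amplitude)
            if weighted_cosine(hits[ga].spectrum, hits[pa].spectrum,
                               cfg.mz_tol) >= cfg.dedup_min_cos:
                target = prev
                break
        if target is None:
            merged.append(list(g))
        else:
            pool: dict[str, int] = {}
            for k in target + g:
                s = hits[k].sample_id
                if s not in pool or hits[k].amplitude > hits[pool[s]].amplitude:
                    pool[s] = k
            target[:] = sorted(pool.values())

    features: list[AlignedFeature] = []
    ordered = sorted(merged,
                     key=lambda g: (min(hits[k].rt for k in g),
                                    min(hits[k].sample_id for k in g)))
    for n, g in enumerate(ordered):
        fhits = {hits[k].sample_id: hits[k] for k in g}
        if library:
            for h in fhits.values():
                res = match_library(h.spectrum, library, ann_cfg)
                h.score = res[0].total if res else 0.0
        else:
            # no library: score by mean cosine to the other hits
            hlist = list(fhits.values())
            for h in hlist:
                others = [o for o in hlist if o is not h]
                h.score = (float(np.mean([
                    weighted_cosine(h.spectrum, o.spectrum, cfg.mz_tol)
                    for o in others])) if others else 1.0)
        # deterministic tie-break: highest score, then smallest sample_id
        best = max(h.score for h in fhits.values())
        rep_hit = min((h for h in fhits.values() if h.score == best),
                      key=lambda h: h.sample_id)
        feat = AlignedFeature(f"F{n + 1:05d}", fhits, rep_hit.spectrum)
        if library:
            top = annotate(rep_hit.spectrum, library, ann_cfg)
            if top is not None:
                feat.annotation = (top.record_name, top.total)
                rec = next(r for r in library if r.name == top.record_name)
                feat.class_label = rec.class_label
        features.append(feat)
    return features


def select_representative(feature: AlignedFeature) -> Spectrum:
    """Hit spectrum with the highest identification score (ties: smallest sample_id)."""
    best = max(h.score for h in feature.hits.values())
    hit = min((h for h in feature.hits.values() if h.score == best),
              key=lambda h: h.sample_id)
    return hit.spectrum


def co_annotate(features: list[AlignedFeature], n_samples: int) -> list[AlignedFeature]:
    """Retain exactly the features detected in all n_samples runs."""
    return [f for f in features if len(f.hits) == n_samples]


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    thresholds: tuple[float, ...]
    sets: dict[float, frozenset[str]]
    sizes: dict[float, int] = field(default_factory=dict)
    jaccard: dict[tuple[float, float], float] = field(default_factory=dict)

    def __post_init__(self):
        self.sizes = {t: len(s) for t, s in self.sets.items()}
        ts = self.thresholds
        for a in range(len(ts)):
            for b in range(a + 1, len(ts)):
                sa, sb = self.sets[ts[a]], self.sets[ts[b]]
                union = sa | sb
                self.jaccard[(ts[a], ts[b])] = (
                    len(sa & sb) / len(union) if union else 1.0
                )


def threshold_sweep(
    per_run: dict[str, list[DeconvolvedSpectrum]],
    cfg: AlignConfig | None = None,
    thresholds: tuple[float, ...] = (0.20, 0.50, 0.70),
) -> StabilityReport:
    """Co-annotation stability across similarity thresholds (default 20/50/70 %).

    The panel is aligned once at the loosest threshold; a feature then
    qualifies at threshold t when its hits remain connected across all
    samples using only pairs with cosine >= t, which makes the retained
    sets nested by construction: S(0.70) subset of S(0.50) subset of S(0.20).
    """
    if list(thresholds) != sorted(thresholds):
        raise ConfigurationError("thresholds must be ascending")
    cfg = cfg or AlignConfig()
    base_cfg = AlignConfig(cfg.rt_tol, min(thresholds), cfg.rt_factor,
                           cfg.ei_factor, cfg.mz_tol)
    n_samples = len(per_run)
    features = align_panel(per_run, base_cfg)
    sets: dict[float, frozenset[str]] = {}
    for t in thresholds:
        kept = []
        for f in features:
            if len(f.hits) < n_samples:
                continue
            hlist = sorted(f.hits.values(), key=lambda h: h.sample_id)
            uf = _Union(len(hlist))
            for i in range(len(hlist)):
                for j in range(i + 1, len(hlist)):
                    if abs(hlist[i].rt - hlist[j].rt) > cfg.rt_tol:
                        continue
                    if weighted_cosine(hlist[i].spectrum, hlist[j].spectrum,
                                       cfg.mz_tol) >= t:
                        uf.union(i, j)
            comp_sizes: dict[int, int] = {}
            for k in range(len(hlist)):
                r = uf.find(k)
                comp_sizes[r] = comp_sizes.get(r, 0) + 1
            if max(comp_sizes.values()) == n_samples:
                kept.append(f.feature_id)
        sets[t] = frozenset(kept)
    report = StabilityReport(tuple(thresholds), sets)
    for a, b in zip(thresholds, thresholds[1:]):
        if not sets[b] <= sets[a]:
            raise InternalConsistencyError(
                f"threshold nesting violated between {a} and {b}"
            )
    return report
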