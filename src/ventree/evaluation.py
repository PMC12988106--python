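"""Scoring recovered pipeline output against generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import AlignedFeature, Spectrum, weighted_cosine
from .deconvolution import DeconvolvedSpectrum
from .synthetic import CompoundSpec, Placement


@dataclass
class RecoveryResult:
    n_truth: int
    n_recovered: int
    matches: dict[str, tuple[int, float]]  # compound_id -> (spectrum index, cosine)

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else 1.0


def match_spectra_to_truth(
    spectra: list[DeconvolvedSpectrum],
    placements: list[Placement],
    library_by_id: dict[str, CompoundSpec],
    rt_tol: float = 0.075,
    min_cosine: float = 0.95,
    mz_tol: float = 0.5,
) -> RecoveryResult:
    """Count placed compounds recovered by a purified spectrum.

    A compound counts as recovered when some output spectrum sits within
    ``rt_tol`` of its placement and matches its library spectrum at
    weighted cosine >= ``min_cosine``; each spectrum may certify one
    compound (best cosine wins).
    """
    matches: dict[str, tuple[int, float]] = {}
    used: set[int] = set()
    scored = []
    for p in placements:
        truth_spec = Spectrum.from_pairs(library_by_id[p.compound_id].spectrum)
        for k, s in enumerate(spectra):
            if abs(s.rt_apex - p.rt) > rt_tol:
                continue
            cos = weighted_cosine(Spectrum.from_deconvolved(s), truth_spec, mz_tol)
            if cos >= min_cosine:
                scored.append((cos, p.compound_id, k))
    scored.sort(reverse=True)
    for cos, cid, k in scored:
        if cid in matches or k in used:
            continue
        matches[cid] = (k, cos)
        used.add(k)
    return RecoveryResult(len(placements), len(matches), matches)


def identify_feature(
    feature: AlignedFeature,
    placements_by_sample: dict[str, list[Placement]],
    library_by_id: dict[str, CompoundSpec],
    rt_tol: float = 0.075,
    min_cosine: float = 0.9,
    mz_tol: float = 0.5,
) -> str | None:
    """Majority-vote true compound behind an aligned feature's hits."""
    votes: dict[str, int] = {}
    for sid, hit in feature.hits.items():
        best = None
        for p in placements_by_sample.get(sid, []):
            if abs(hit.rt - p.rt) > rt_tol:
                continue
            cos = weighted_cosine(
                hit.spectrum,
                Spectrum.from_pairs(library_by_id[p.compound_id].spectrum),
                mz_tol,
            )
            if cos >= min_cosine and (best is None or cos > best[0]):
                best = (cos, p.compound_id)
        if best is not None:
            votes[best[1]] = votes.get(best[1], 0) + 1
    if not votes:
        return None
    top = max(votes.values())
    return sorted(c for c, v in votes.items() if v == top)[0]


@dataclass
class PrecisionRecall:
    precision: float
    recall: float
    n_predicted: int
    n_truth: int


def coannotation_scores(
    coannotated: list[AlignedFeature],
    shared_ids: frozenset[str],
    placements_by_sample: dict[str, list[Placement]],
    library_by_id: dict[str, CompoundSpec],
    rt_tol: float = 0.075,
) -> PrecisionRecall:
    """Precision/recall of the co-annotated feature set vs the true shared set."""
    predicted: set[str] = set()
    n_correct = 0
    for f in coannotated:
        cid = identify_feature(f, placements_by_sample, library_by_id, rt_tol)
        if cid is not None and cid in shared_ids:
            n_correct += 1
            predicted.add(cid)
    precision = n_correct / len(coannotated) if coannotated else 1.0
    recall = len(predicted) / len(shared_ids) if shared_ids else 1.0
    return PrecisionRecall(precision, recall, len(coannotated), len(shared_ids))
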