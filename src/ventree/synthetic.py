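"""Ground-truthed synthetic inputs for every pipeline stage.

Emulates the statistical structure of the study's three data streams:

* GC-EI-MS panels — class-structured 70 eV fragment spectra for the
  compound families annotated on the relatedness tree (n-alkane ladders,
  aromatic molecular ions, sterane-type diagnostic ions, heteroatom
  series), eluting as exponentially modified Gaussians over a fixed scan
  grid, with co-eluting (chimeric) partners, a broad UCM baseline hump on
  the low-m/z hydrocarbon traces, and white detector noise.
* FT-MS peak lists — [M-H]- masses of valid CHNO(Cl) formulas drawn per
  chemical family with ppm-scale mass jitter.
* Hg isotope ratio tables — bracketed xxxHg/198Hg ratio rows around known
  delta/capital-delta truth, invertible by :mod:`ventree.hg`.

Every generator is deterministic for a fixed seed and returns the ground
truth alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from ._constants import (
    HG_BETA,
    HG_CAPDELTA_ISOTOPES,
    HG_DELTA_ISOTOPES,
    HG_RATIO_198,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
)
from .errors import ConfigurationError

COMPOUND_CLASSES = (
    "alkane",
    "alkene",
    "halogenated",
    "biomarker",
    "aromatic",
    "O_compound",
    "S_compound",
    "N_compound",
    "other",
)

FTMS_CLASSES = ("CHO", "CHON", "CHOCl", "CHONCl")

VENT_FIELDS = ("Edmond", "Kairei", "Longqi")
ACTIVITIES = ("active", "inactive")

#: Default chromatographic peak width (FWHM, minutes): capillary GC peaks.
DEFAULT_FWHM_MIN = 0.1
#: EMG tail constant as a fraction of sigma.
EMG_TAU_FACTOR = 0.2
#: Fixed scan spacing, minutes.
SCAN_INTERVAL_MIN = 0.01


# ---------------------------------------------------------------------------
# compound library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundSpec:
    """One library compound: class label, stick spectrum, elution basics."""

    id: str
    class_label: str
    spectrum: tuple[tuple[int, float], ...]  # (nominal m/z, rel intensity 0-100]
    true_rt: float  # minutes
    response: float  # detector units at the base peak

    def __post_init__(self):
        if self.class_label not in COMPOUND_CLASSES:
            raise ConfigurationError(
                f"unknown compound class label: {self.class_label!r}"
            )
        if not self.spectrum:
            raise ConfigurationError(f"compound {self.id}: empty spectrum")
        intens = [i for _, i in self.spectrum]
        if abs(max(intens) - 100.0) > 1e-9:
            raise ConfigurationError(f"compound {self.id}: base peak must be 100")
        if any(i <= 0 or i > 100 for i in intens):
            raise ConfigurationError(f"compound {self.id}: intensities outside (0,100]")
        if any(mz < 29 or mz > 600 for mz, _ in self.spectrum):
            raise ConfigurationError(f"compound {self.id}: m/z outside [29, 600]")


def _normalize(frags: dict[int, float]) -> tuple[tuple[int, float], ...]:
    frags = {mz: i for mz, i in frags.items() if 29 <= mz <= 600 and i > 0}
    top = max(frags.values())
    return tuple(sorted((mz, 100.0 * i / top) for mz, i in frags.items()))


def _alkane_spectrum(rng) -> dict[int, float]:
    # CnH2n+1 ladder 43/57/71/85... dominated by C4/C5 fragments.
    n_carbon = int(rng.integers(12, 32))
    frags: dict[int, float] = {}
    for k in range(3, n_carbon):
        mz = 14 * k + 1
        if mz > 600:
            break
        rel = 100.0 * math.exp(-0.35 * abs(k - 4)) * (1 + 0.1 * rng.normal())
        frags[mz] = max(rel, 1.0)
    frags[14 * n_carbon + 2] = 2.0 + 3.0 * rng.random()  # weak M+.
    frags[57] = 100.0
    return frags


def _alkene_spectrum(rng) -> dict[int, float]:
    n_carbon = int(rng.integers(10, 28))
    frags: dict[int, float] = {}
    for k in range(3, n_carbon):
        mz = 14 * k - 1  # CnH2n-1 series 41/55/69...
        if mz > 600:
            break
        rel = 100.0 * math.exp(-0.30 * abs(k - 4)) * (1 + 0.1 * rng.normal())
        frags[mz] = max(rel, 1.0)
    frags[14 * n_carbon] = 3.0 + 4.0 * rng.random()
    frags[55] = 100.0
    return frags


def _halogenated_spectrum(rng) -> dict[int, float]:
    m = int(rng.integers(150, 420))
    frags = {
        m: 100.0,
        m + 2: 32.0 * (1 + 0.05 * rng.normal()),  # 37Cl satellite, ~3:1
        m - 35: 40.0 + 20.0 * rng.random(),  # -Cl loss
        m - 63: 15.0 + 10.0 * rng.random(),
        49: 12.0 + 6.0 * rng.random(),  # CH2Cl+
        int(rng.integers(75, 130)): 25.0 + 15.0 * rng.random(),
    }
    return frags


def _biomarker_spectrum(rng) -> dict[int, float]:
    # Sterane/hopane-type diagnostic ions (217/218/231/191 family).
    base = int(rng.choice([217, 231, 213, 191]))
    m = int(rng.integers(358, 415))
    frags = {
        base: 100.0,
        base + 1: 20.0 + 5.0 * rng.random(),
        149: 30.0 + 15.0 * rng.random(),
        95: 25.0 + 10.0 * rng.random(),
        81: 20.0 + 10.0 * rng.random(),
        m: 8.0 + 8.0 * rng.random(),  # molecular ion
        m - 15: 5.0 + 5.0 * rng.random(),
    }
    return frags


def _aromatic_spectrum(rng) -> dict[int, float]:
    # PAHs: dominant molecular ion, weak M-1 and doubly charged M/2.
    m = int(rng.choice([128, 152, 166, 178, 202, 228, 252, 278]))
    frags = {
        m: 100.0,
        m - 1: 15.0 + 10.0 * rng.random(),
        m - 26: 8.0 + 6.0 * rng.random(),  # C2H2 loss
        m // 2: 10.0 + 5.0 * rng.random(),
    }
    return frags


def _oxy_spectrum(rng) -> dict[int, float]:
    n_carbon = int(rng.integers(8, 22))
    frags: dict[int, float] = {43: 80.0 + 15.0 * rng.random()}  # acylium
    for k in range(1, 7):
        mz = 14 * k + 31  # CnH2n+1O+ 45/59/73...
        frags[mz] = 60.0 * math.exp(-0.3 * k) * (1 + 0.1 * rng.normal())
    frags[14 * n_carbon + 32] = 4.0 + 4.0 * rng.random()
    frags[45] = 100.0
    return frags


def _sulfur_spectrum(rng) -> dict[int, float]:
    # Dibenzothiophene-like: strong molecular ion plus CHS fragments.
    m = int(rng.choice([184, 198, 212, 226]))
    frags = {
        m: 100.0,
        m - 32: 12.0 + 8.0 * rng.random(),  # S loss
        139: 18.0 + 8.0 * rng.random(),
        45: 20.0 + 10.0 * rng.random(),  # CHS+
        69: 12.0 + 8.0 * rng.random(),
    }
    return frags


def _nitrogen_spectrum(rng) -> dict[int, float]:
    n_carbon = int(rng.integers(8, 20))
    frags: dict[int, float] = {}
    for k in range(1, 6):
        mz = 14 * k + 16  # CnH2n+2N+ 30/44/58...
        frags[mz] = 90.0 * math.exp(-0.25 * k) * (1 + 0.1 * rng.normal())
    m = 14 * n_carbon + 17  # odd nominal mass: one nitrogen
    frags[m] = 10.0 + 8.0 * rng.random()
    frags[30] = 100.0
    return frags


def _other_spectrum(rng) -> dict[int, float]:
    n = int(rng.integers(5, 10))
    mzs = rng.choice(np.arange(31, 450), size=n, replace=False)
    frags = {int(mz): float(5.0 + 95.0 * rng.random()) for mz in mzs}
    frags[int(rng.choice(list(frags)))] = 100.0
    return frags


_TEMPLATES = {
    "alkane": _alkane_spectrum,
    "alkene": _alkene_spectrum,
    "halogenated": _halogenated_spectrum,
    "biomarker": _biomarker_spectrum,
    "aromatic": _aromatic_spectrum,
    "O_compound": _oxy_spectrum,
    "S_compound": _sulfur_spectrum,
    "N_compound": _nitrogen_spectrum,
    "other": _other_spectrum,
}


def _spaced_rts(n: int, rt_range: tuple[float, float], min_gap: float, rng) -> list[float]:
    """Draw n retention times keeping pairwise gaps >= min_gap."""
    lo, hi = rt_range
    rts: list[float] = []
    for _ in range(n):
        for _try in range(200):
            rt = float(rng.uniform(lo, hi))
            if all(abs(rt - r) >= min_gap for r in rts):
                rts.append(rt)
                break
        else:  # dense fallback: regular grid with jitter
            k = len(rts)
            rt = lo + (k + 0.5) * (hi - lo) / n + float(rng.uniform(-0.3, 0.3)) * min_gap
            rts.append(min(max(rt, lo), hi))
    return rts


def make_compound_library(
    n_per_class: int,
    seed: int,
    classes: tuple[str, ...] = COMPOUND_CLASSES,
    rt_range: tuple[float, float] = (2.0, 85.0),
    min_class_gap: float = 0.5,
) -> list[CompoundSpec]:
    """Build a deterministic library of class-templated EI stick spectra.

    Each class uses a distinct fragment-pattern template (alkanes the
    43/57/71/85 ladder, aromatics a dominant molecular ion, biomarkers
    217/231-type diagnostic ions, heteroatom classes shifted series).
    Same-class compounds — near-identical fingerprints — are spaced at
    least ``min_class_gap`` minutes apart, as homologous series are in
    real temperature-programmed GC; detector responses are log-normal
    around ~4e6 units so base peaks clear typical peak-height thresholds.
    """
    for cls in classes:
        if cls not in _TEMPLATES:
            raise ConfigurationError(f"unknown compound class label: {cls!r}")
    if n_per_class < 0:
        raise ConfigurationError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    library: list[CompoundSpec] = []
    for cls in classes:
        rts = _spaced_rts(n_per_class, rt_range, min_class_gap, rng)
        for j in range(n_per_class):
            frags = _TEMPLATES[cls](rng)
            response = float(4e6 * rng.lognormal(0.0, 0.4))
            library.append(
                CompoundSpec(
                    id=f"{cls}_{j:03d}",
                    class_label=cls,
                    spectrum=_normalize(frags),
                    true_rt=rts[j],
                    response=response,
                )
            )
    return library


# ---------------------------------------------------------------------------
# panel design / raw runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    vent_field: str
    activity: str


def default_sample_meta(n_samples: int = 12) -> tuple[SampleMeta, ...]:
    """3 vent fields x 2 activity states, cycled to n_samples runs."""
    metas = []
    combos = [(f, a) for f in VENT_FIELDS for a in ACTIVITIES]
    for i in range(n_samples):
        fieldname, act = combos[i % len(combos)]
        metas.append(SampleMeta(f"S{i + 1:02d}", fieldname, act))
    return tuple(metas)


def _default_class_mix() -> dict[str, dict[str, float]]:
    # Active vents lean hydrocarbon/aromatic; inactive vents lean NSO —
    # the activity-dependent gradient the tree stages should recover.
    active = {
        "alkane": 0.28, "alkene": 0.14, "halogenated": 0.05, "biomarker": 0.10,
        "aromatic": 0.20, "O_compound": 0.08, "S_compound": 0.07,
        "N_compound": 0.04, "other": 0.04,
    }
    inactive = {
        "alkane": 0.10, "alkene": 0.06, "halogenated": 0.06, "biomarker": 0.06,
        "aromatic": 0.10, "O_compound": 0.22, "S_compound": 0.10,
        "N_compound": 0.24, "other": 0.06,
    }
    return {"active": active, "inactive": inactive}


@dataclass(frozen=True)
class PanelDesign:
    """Study geometry for a simulated multi-sample GC-EI-MS panel.

    Defaults mirror the study conditions: 12 samples across the three
    Indian Ridge vent fields and both activity states; a 1-87 min run
    (40->290 degC at 4 degC/min GC program); activity-dependent compound
    class mixtures.
    """

    n_samples: int = 12
    sample_meta: tuple[SampleMeta, ...] = field(default_factory=default_sample_meta)
    shared_fraction: float = 0.3
    class_mix_by_activity: dict[str, dict[str, float]] = field(
        default_factory=_default_class_mix
    )
    chimera_rate: float = 0.2
    noise_sd: float = 2e4
    ucm_amplitude: float = 2e5
    rt_range: tuple[float, float] = (1.0, 87.0)
    rt_jitter_sd: float = 0.008  # per-run retention drift, minutes
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if len(self.sample_meta) != self.n_samples:
            raise ConfigurationError("sample_meta length must equal n_samples")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ConfigurationError("chimera_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.ucm_amplitude < 0 or self.rt_jitter_sd < 0:
            raise ConfigurationError(
                "noise_sd, ucm_amplitude and rt_jitter_sd must be >= 0")
        for activity, mix in self.class_mix_by_activity.items():
            if activity not in ACTIVITIES:
                raise ConfigurationError(f"unknown activity: {activity!r}")
            for cls in mix:
                if cls not in COMPOUND_CLASSES:
                    raise ConfigurationError(f"unknown compound class label: {cls!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"class mix for {activity!r} must sum to 1"
                )


@dataclass
class RawRun:
    """One sample's centroided scan series on a fixed rt grid.

    Stored trace-wise (measured m/z -> intensity array over the grid) for
    efficiency; ``scans()`` exposes the conventional scan-by-scan view.
    """

    sample_id: str
    vent_field: str
    activity: str
    rt: np.ndarray  # minutes, strictly increasing
    traces: dict[float, np.ndarray]  # measured m/z -> intensities

    def scans(self):
        """Yield (rt, [(m/z, intensity), ...]) per scan, zero peaks dropped."""
        mzs = sorted(self.traces)
        arrays = [self.traces[m] for m in mzs]
        for i, t in enumerate(self.rt):
            peaks = [(m, a[i]) for m, a in zip(mzs, arrays) if a[i] > 0]
            yield float(t), peaks

    def total_ion_current(self) -> np.ndarray:
        if not self.traces:
            return np.zeros_like(self.rt)
        return np.sum(list(self.traces.values()), axis=0)


@dataclass(frozen=True)
class Placement:
    compound_id: str
    rt: float
    abundance: float  # base-peak amplitude, detector units


@dataclass
class GroundTruth:
    """Everything the generators know, for scoring recovery downstream."""

    placements: dict[str, list[Placement]] = field(default_factory=dict)
    shared_ids: frozenset[str] = frozenset()
    ftms: pd.DataFrame | None = None  # columns: mz, formula counts, class
    hg: dict | None = None


def _chimera_rts(
    ids: list[str],
    base_rts: dict[str, float],
    rate: float,
    rng,
    classes: dict[str, str] | None = None,
) -> dict[str, float]:
    """Relocate a ``rate`` fraction of compounds 0.02-0.05 min from a partner.

    Pairs are disjoint where possible, and partners are drawn from a
    different compound class so chimeric spectra overlap partially: two
    same-class homologues share essentially every fragment, and such a
    co-elution is a single merged signal no method could separate.
    """
    rts = dict(base_rts)
    n_chim = int(round(rate * len(ids)))
    if n_chim > 0 and len(ids) >= 2:
        perm = list(rng.permutation(len(ids)))
        movers = perm[:min(n_chim, len(ids) - 1)]
        pool = [k for k in perm if k not in set(movers)]
        def _clear_of_same_class(mover: str, target_rt: float) -> bool:
            if classes is None:
                return True
            cls = classes.get(mover)
            return all(abs(rts[o] - target_rt) > 0.2 for o in ids
                       if o != mover and classes.get(o) == cls)

        for mi in movers:
            partner = None
            if pool:
                cls = classes.get(ids[mi]) if classes else None
                cand = [k for k in pool
                        if (classes is None or classes.get(ids[k]) != cls)
                        and _clear_of_same_class(ids[mi], rts[ids[k]])]
                choice = cand[0] if cand else pool[0]
                pool.remove(choice)
                partner = ids[choice]
            else:  # rate ~ 1: pair movers among themselves
                others = [ids[k] for k in movers if k != mi]
                partner = others[int(rng.integers(len(others)))]
            offset = float(rng.uniform(0.02, 0.05)) * (1 if rng.random() < 0.5 else -1)
            rts[ids[mi]] = rts[partner] + offset
    return rts


def _emg_profile(grid: np.ndarray, rt: float, fwhm: float) -> np.ndarray:
    """Unit-height exponentially modified Gaussian centred near rt."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    tau = EMG_TAU_FACTOR * sigma
    y = exponnorm.pdf(grid, K=tau / sigma, loc=rt, scale=sigma)
    peak = y.max()
    return y / peak if peak > 0 else y


def simulate_run(
    library: list[CompoundSpec],
    selection: list[str],
    design: PanelDesign,
    seed: int,
    meta: SampleMeta | None = None,
    rt_overrides: dict[str, float] | None = None,
) -> tuple[RawRun, GroundTruth]:
    """Render one raw run from a compound selection.

    Each selected compound elutes as an EMG (FWHM 0.1 min, tau = 0.2 sigma);
    a ``chimera_rate`` fraction is re-placed 0.02-0.05 min from a partner
    compound; a broad UCM hump rides on the low-m/z hydrocarbon traces and
    white noise is added to every occupied trace. Fragment m/z values carry
    a fixed sub-Da offset from nominal so downstream binning is exercised.
    """
    by_id = {c.id: c for c in library}
    unknown = [s for s in selection if s not in by_id]
    if unknown:
        raise ConfigurationError(f"selection not in library: {unknown[:3]}")
    meta = meta or SampleMeta("S01", VENT_FIELDS[0], ACTIVITIES[0])
    rng = np.random.default_rng(seed)
    lo, hi = design.rt_range
    grid = np.round(np.arange(lo, hi + SCAN_INTERVAL_MIN / 2, SCAN_INTERVAL_MIN), 6)

    # Retention times: panel callers pass consistent overrides; standalone
    # runs apply chimeric co-elution themselves.
    ordered = list(selection)
    if rt_overrides is not None:
        rts = {cid: rt_overrides.get(cid, by_id[cid].true_rt) for cid in ordered}
    else:
        rts = _chimera_rts(ordered, {c: by_id[c].true_rt for c in ordered},
                           design.chimera_rate, rng,
                           {c: by_id[c].class_label for c in ordered})
    margin = 0.5
    for cid, rt in rts.items():
        rts[cid] = min(max(rt, lo + margin), hi - margin)
        if not lo <= rts[cid] <= hi:
            raise ConfigurationError(f"rt assignment outside rt_range for {cid}")

    traces: dict[float, np.ndarray] = {}
    placements: list[Placement] = []
    for cid in ordered:
        comp = by_id[cid]
        abundance = comp.response * float(rng.lognormal(0.0, 0.25))
        profile = _emg_profile(grid, rts[cid], DEFAULT_FWHM_MIN)
        for mz_nom, rel in comp.spectrum:
            # fixed sub-Da mass error per compound-fragment, reproducible
            mz_meas = mz_nom + float(rng.uniform(-0.2, 0.2))
            amp = abundance * rel / 100.0
            traces.setdefault(mz_meas, np.zeros_like(grid))
            traces[mz_meas] += amp * profile
        placements.append(Placement(cid, rts[cid], abundance))

    # UCM: one broad Gaussian hump spread over the alkyl-fragment traces.
    if design.ucm_amplitude > 0:
        centre = 0.5 * (lo + hi)
        width = 0.2 * (hi - lo)
        hump = np.exp(-0.5 * ((grid - centre) / width) ** 2)
        ucm_bins = [57.25, 71.25, 85.25, 99.25, 43.25]
        for k, mz in enumerate(ucm_bins):
            traces.setdefault(mz, np.zeros_like(grid))
            traces[mz] += design.ucm_amplitude * hump * math.exp(-0.4 * k)

    if design.noise_sd > 0:
        for mz in traces:
            noisy = traces[mz] + rng.normal(0.0, design.noise_sd, size=grid.size)
            traces[mz] = np.clip(noisy, 0.0, None)

    run = RawRun(meta.sample_id, meta.vent_field, meta.activity, grid, traces)
    truth = GroundTruth(placements={meta.sample_id: placements})
    return run, truth


def simulate_panel(
    design: PanelDesign,
    library: list[CompoundSpec],
    seed: int | None = None,
) -> tuple[list[RawRun], GroundTruth]:
    """Render a multi-sample panel with an exact panel-wide shared set.

    Exactly ``round(shared_fraction * n_compounds)`` compounds appear in
    every run; the rest appear in strict subsets of the runs, drawn with
    class weights given by each sample's activity mix. Chimeric
    co-elution is decided once for the panel (co-elution is a property of
    the compounds, not of one injection); each run then adds only a small
    Gaussian retention drift (``rt_jitter_sd``).
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ids = [c.id for c in library]
    n = len(ids)
    n_shared = int(round(design.shared_fraction * n))
    shared = list(rng.choice(ids, size=n_shared, replace=False)) if n_shared else []
    rest = [i for i in ids if i not in set(shared)]
    by_id = {c.id: c for c in library}

    selections: list[list[str]] = []
    for meta in design.sample_meta:
        mix = design.class_mix_by_activity.get(meta.activity, {})
        weights = np.array(
            [mix.get(by_id[cid].class_label, 1e-6) for cid in rest], dtype=float
        )
        extra: list[str] = []
        if rest:
            weights = weights / weights.sum()
            m = int(round(0.5 * len(rest)))
            m = min(m, len(rest))
            extra = list(rng.choice(rest, size=m, replace=False, p=weights))
        selections.append(shared + extra)

    # enforce strict subsets: a non-shared compound must miss >= 1 run
    if selections:
        everywhere = set(rest)
        for sel in selections:
            everywhere &= set(sel)
        for cid in sorted(everywhere):
            selections[-1].remove(cid)

    panel_rts = _chimera_rts(ids, {c.id: c.true_rt for c in library},
                             design.chimera_rate, rng,
                             {c.id: c.class_label for c in library})
    child_seeds = np.random.SeedSequence(seed).generate_state(design.n_samples) % (2**31)
    runs: list[RawRun] = []
    truth = GroundTruth(shared_ids=frozenset(shared))
    for meta, sel, s in zip(design.sample_meta, selections, child_seeds):
        run_rng = np.random.default_rng(int(s))
        # retention drift is dominated by run-level factors: one systematic
        # shift per run, plus sub-scan per-compound wobble
        shift = float(run_rng.normal(0.0, design.rt_jitter_sd))
        overrides = {
            cid: panel_rts[cid] + shift + float(run_rng.normal(0.0, 0.002))
            for cid in sel
        }
        run, rt = simulate_run(library, sel, design, int(s), meta=meta,
                               rt_overrides=overrides)
        runs.append(run)
        truth.placements[meta.sample_id] = rt.placements[meta.sample_id]
    return runs, truth


# ---------------------------------------------------------------------------
# FT-MS peak lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassPeak:
    mz: float
    intensity: float


def _draw_formula(cls: str, mz_range: tuple[float, float], rng, max_tries: int = 1000):
    """Rejection-sample a valid formula of the class with [M-H]- in range."""
    mC, mH, mN, mO, mCl = (
        MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"], MONOISOTOPIC_MASS["N"],
        MONOISOTOPIC_MASS["O"], MONOISOTOPIC_MASS["Cl"],
    )
    for _ in range(max_tries):
        # realistic dissolved-organic-matter space: H/C 0.6-2.2, O/C <= 0.9,
        # N <= 3, Cl <= 2 (vent DOM sits well inside the assignment windows)
        c = int(rng.integers(8, 45))
        n = int(rng.integers(1, 4)) if "N" in cls.replace("Cl", "") else 0
        cl = int(rng.integers(1, 3)) if cls.endswith("Cl") else 0
        o = int(rng.integers(1, max(min(int(0.9 * c), 20), 2) + 1))
        h_lo = max(1, int(0.6 * c))
        h_hi = min(200, int(2.2 * c) + 2)
        h = int(rng.integers(h_lo, h_hi + 1))
        if (h + cl + n) % 2 != 0:
            h += 1
        dbe = c - (h + cl) / 2.0 + n / 2.0 + 1.0
        if dbe < 0 or dbe > 40 or h > 200:
            continue
        mass = c * mC + h * mH + n * mN + o * mO + cl * mCl
        mz = mass - PROTON_MASS
        if mz_range[0] <= mz <= mz_range[1]:
            return {"C": c, "H": h, "N": n, "O": o, "Cl": cl}, mz
    raise ConfigurationError(
        f"could not draw a valid {cls} formula in m/z {mz_range} after {max_tries} tries"
    )


def simulate_ftms_peaklist(
    n_formulae: int,
    class_mix: dict[str, float],
    ppm_sigma: float,
    mz_range: tuple[float, float] = (200.0, 800.0),
    seed: int = 0,
) -> tuple[list[MassPeak], GroundTruth]:
    """Draw n valid CHNO(Cl) formulas per the class mix; jitter masses by ppm."""
    if not (100.0 <= mz_range[0] < mz_range[1] <= 1500.0):
        raise ConfigurationError("mz_range must lie within [100, 1500]")
    unknown = set(class_mix) - set(FTMS_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown FT-MS classes: {sorted(unknown)}")
    probs = np.array([class_mix.get(c, 0.0) for c in FTMS_CLASSES], dtype=float)
    if probs.sum() <= 0:
        raise ConfigurationError("class_mix must have positive mass")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    peaks: list[MassPeak] = []
    rows = []
    for i in range(n_formulae):
        cls = FTMS_CLASSES[int(rng.choice(len(FTMS_CLASSES), p=probs))]
        counts, mz_theo = _draw_formula(cls, mz_range, rng)
        mz_obs = mz_theo * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6) if ppm_sigma > 0 else mz_theo
        intensity = float(rng.lognormal(10.0, 1.0))
        peaks.append(MassPeak(float(mz_obs), intensity))
        rows.append({"mz": float(mz_obs), "mz_theoretical": mz_theo,
                     "class": cls, **counts})
    truth = GroundTruth(ftms=pd.DataFrame(rows))
    return peaks, truth


# ---------------------------------------------------------------------------
# Hg tables
# ---------------------------------------------------------------------------

def simulate_hg_table(
    true_delta202: float,
    true_capdeltas: dict[int, float],
    noise_2sd: float,
    n_replicates: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bracketed Hg isotope ratio measurements around known delta truth.

    Each replicate row carries sample and bracketing-standard xxxHg/198Hg
    ratios; the standard brackets are exact NIST-3133-scale ratios, the
    sample ratios encode delta(xxx) = cap_delta(xxx) + beta * delta202 plus
    measurement noise with the stated 2SD.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if noise_2sd < 0:
        raise ConfigurationError("noise_2sd must be >= 0")
    rng = np.random.default_rng(seed)
    true_deltas = {202: true_delta202}
    for iso in HG_CAPDELTA_ISOTOPES:
        true_deltas[iso] = true_capdeltas.get(iso, 0.0) + HG_BETA[iso] * true_delta202
    rows = []
    for r in range(n_replicates):
        row: dict[str, float | int] = {"replicate": r}
        for iso in HG_DELTA_ISOTOPES:
            delta = true_deltas[iso]
            if noise_2sd > 0:
                delta = delta + rng.normal(0.0, noise_2sd / 2.0)
            r_std = HG_RATIO_198[iso]
            row[f"sample_{iso}_198"] = r_std * (1.0 + delta / 1000.0)
            row[f"std_before_{iso}_198"] = r_std
            row[f"std_after_{iso}_198"] = r_std
        rows.append(row)
    truth = GroundTruth(hg={
        "delta202": true_delta202,
        "cap_deltas": {iso: true_capdeltas.get(iso, 0.0) for iso in HG_CAPDELTA_ISOTOPES},
        "deltas": true_deltas,
    })
    return pd.DataFrame(rows), truth
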