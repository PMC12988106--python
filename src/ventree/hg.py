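"""Mercury stable-isotope delta/capital-delta systematics.

Mass-dependent fractionation is reported as delta-xxx-Hg (permil deviation
of the xxxHg/198Hg ratio from the bracketing NIST-3133 standard); the
mass-independent residual capital-delta subtracts the theoretically
predicted mass-dependent part, delta202 scaled by the kinetic beta factor
(0.252 / 0.5024 / 0.752 for 199/200/201).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._constants import HG_BETA, HG_CAPDELTA_ISOTOPES, HG_DELTA_ISOTOPES
from .errors import ConfigurationError


@dataclass(frozen=True)
class IsotopeRatioSet:
    """xxxHg/198Hg ratios for xxx in {199, 200, 201, 202}."""

    ratios: dict[int, float]

    def __post_init__(self):
        for iso in HG_DELTA_ISOTOPES:
            r = self.ratios.get(iso)
            if r is None or r <= 0:
                raise ConfigurationError(f"ratio {iso}/198 must be positive")


@dataclass(frozen=True)
class DeltaSet:
    """delta values in permil."""

    d199: float
    d200: float
    d201: float
    d202: float

    def get(self, iso: int) -> float:
        return getattr(self, f"d{iso}")


@dataclass(frozen=True)
class CapDeltaSet:
    D199: float
    D200: float
    D201: float

    def get(self, iso: int) -> float:
        return getattr(self, f"D{iso}")


def delta_values(
    sample: IsotopeRatioSet,
    std_before: IsotopeRatioSet,
    std_after: IsotopeRatioSet,
) -> DeltaSet:
    """Standard-sample bracketing: delta against the mean of the brackets.

    delta_xxx = (R_sample / R_std - 1) * 1000, permil.
    """
    vals = {}
    for iso in HG_DELTA_ISOTOPES:
        r_std = 0.5 * (std_before.ratios[iso] + std_after.ratios[iso])
        vals[iso] = (sample.ratios[iso] / r_std - 1.0) * 1000.0
    return DeltaSet(vals[199], vals[200], vals[201], vals[202])


def cap_delta(deltas: DeltaSet, beta: dict[int, float] | None = None) -> CapDeltaSet:
    """capital-delta_xxx = delta_xxx - delta202 * beta_xxx."""
    beta = beta or HG_BETA
    vals = {iso: deltas.get(iso) - deltas.d202 * beta[iso]
            for iso in HG_CAPDELTA_ISOTOPES}
    return CapDeltaSet(vals[199], vals[200], vals[201])


def deltas_from_table(table: pd.DataFrame) -> list[tuple[DeltaSet, CapDeltaSet]]:
    """Invert a bracketed ratio table (one replicate per row)."""
    out = []
    for _, row in table.iterrows():
        sample = IsotopeRatioSet({iso: row[f"sample_{iso}_198"]
                                  for iso in HG_DELTA_ISOTOPES})
        before = IsotopeRatioSet({iso: row[f"std_before_{iso}_198"]
                                  for iso in HG_DELTA_ISOTOPES})
        after = IsotopeRatioSet({iso: row[f"std_after_{iso}_198"]
                                 for iso in HG_DELTA_ISOTOPES})
        d = delta_values(sample, before, after)
        out.append((d, cap_delta(d)))
    return out


@dataclass
class ReplicateSummary:
    mean: dict[str, float]
    two_sd: dict[str, float]
    n: int
    qc_missing: list[int] = field(default_factory=list)


def replicate_summary(
    measurements: list[DeltaSet | CapDeltaSet],
    qc_interval: int = 7,
    sequence_labels: list[str] | None = None,
) -> ReplicateSummary:
    """Per-quantity mean and 2SD over replicates, plus a QC schedule check.

    When ``sequence_labels`` is given (the full run order, "qc" marking
    secondary-standard slots), every ``qc_interval``-th position after a
    block of samples must be a QC slot; missing slots are flagged.
    """
    if not measurements:
        raise ConfigurationError("no measurements")
    cols: dict[str, list[float]] = {}
    for m in measurements:
        isotopes = HG_DELTA_ISOTOPES if isinstance(m, DeltaSet) else HG_CAPDELTA_ISOTOPES
        prefix = "d" if isinstance(m, DeltaSet) else "D"
        for iso in isotopes:
            cols.setdefault(f"{prefix}{iso}", []).append(m.get(iso))
    mean = {k: float(np.mean(v)) for k, v in cols.items()}
    two_sd = {k: 2.0 * float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
              for k, v in cols.items()}
    missing: list[int] = []
    if sequence_labels is not None:
        since_qc = 0
        for pos, lab in enumerate(sequence_labels):
            if lab == "qc":
                since_qc = 0
            else:
                since_qc += 1
                if since_qc > qc_interval:
                    missing.append(pos)
                    since_qc = 0
    return ReplicateSummary(mean, two_sd, len(measurements), missing)
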