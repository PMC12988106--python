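"""Formula assignment: masses, enumeration vs oracle, profiles, trends."""

import numpy as np
import pytest

from ventree._constants import MONOISOTOPIC_MASS, PROTON_MASS
from ventree.errors import ConfigurationError
from ventree.ftms import (
    Assignment,
    AssignmentConfig,
    dom_assignment_config,
    FormulaCandidate,
    assign_peaklist,
    class_profile,
    compare_profiles,
    dbe,
    enumerate_formulas,
    formula_class,
    theoretical_mz,
    van_krevelen,
)
from ventree.synthetic import MassPeak, simulate_ftms_peaklist


def brute_force_enumeration(mz, cfg):
    """Exhaustive oracle over the full element grid, H scanned directly."""
    mC, mH, mN, mO, mCl = (MONOISOTOPIC_MASS[e] for e in ("C", "H", "N", "O", "Cl"))
    neutral = mz + PROTON_MASS
    H = np.arange(cfg.h_range[0], cfg.h_range[1] + 1)
    out = []
    for c in range(cfg.c_range[0], cfg.c_range[1] + 1):
        if c * mC > neutral + 1:
            break
        for n in range(cfg.n_range[0], cfg.n_range[1] + 1):
            for cl in range(cfg.cl_range[0], cfg.cl_range[1] + 1):
                for o in range(cfg.o_range[0], cfg.o_range[1] + 1):
                    base = c * mC + n * mN + o * mO + cl * mCl
                    if base > neutral + 1:
                        break
                    err = (base + H * mH - PROTON_MASS - mz) / mz * 1e6
                    d = c - (H + cl) / 2.0 + n / 2.0 + 1.0
                    keep = ((np.abs(err) <= cfg.ppm_tol)
                            & ((H + cl + n) % 2 == 0)
                            & (d >= cfg.dbe_range[0]) & (d <= cfg.dbe_range[1])
                            & (H / c >= cfg.hc_range[0]) & (H / c <= cfg.hc_range[1])
                            & (o / c >= cfg.oc_range[0]) & (o / c <= cfg.oc_range[1]))
                    out.extend((c, int(h), n, o, cl) for h in H[keep])
    return sorted(out)


class TestTheoreticalMass:
    def test_neutral_is_plain_sum(self):
        counts = {"C": 1, "H": 4}
        assert theoretical_mz(counts, "neutral") == pytest.approx(
            12.0 + 4 * MONOISOTOPIC_MASS["H"], abs=1e-12)

    def test_additivity(self):
        a = {"C": 3, "H": 6, "O": 1}
        b = {"C": 2, "H": 4, "N": 2}
        ab = {"C": 5, "H": 10, "N": 2, "O": 1}
        assert theoretical_mz(a, "neutral") + theoretical_mz(b, "neutral") == \
            pytest.approx(theoretical_mz(ab, "neutral"), abs=1e-12)

    def test_formic_acid_deprotonated(self):
        # CH2O2: independent hand summation from IUPAC monoisotopic masses
        expected = (12.0 + 2 * 1.00782503207 + 2 * 15.9949146196) - 1.00727646
        assert theoretical_mz({"C": 1, "H": 2, "O": 2}) == pytest.approx(
            expected, abs=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            theoretical_mz({"C": -1, "H": 4})


class TestEnumeration:
    def test_known_formula_ranked_first_noise_free(self):
        counts = {"C": 12, "H": 17, "N": 1, "O": 4, "Cl": 0}
        mz = theoretical_mz(counts)
        cands = enumerate_formulas(mz, AssignmentConfig(ppm_tol=0.5))
        assert cands[0].counts == counts
        assert cands[0].error_ppm == pytest.approx(0.0, abs=1e-6)

    def test_no_valid_combination_empty(self):
        cfg = AssignmentConfig(ppm_tol=0.001)
        assert enumerate_formulas(200.0101234, cfg) == []

    def test_widening_tolerance_never_shrinks(self):
        mz = 351.0722
        n_narrow = len(enumerate_formulas(mz, AssignmentConfig(ppm_tol=0.5)))
        n_wide = len(enumerate_formulas(mz, AssignmentConfig(ppm_tol=2.0)))
        assert n_wide >= n_narrow

    def test_matches_brute_force_oracle_below_400(self):
        cfg = AssignmentConfig()
        rng = np.random.default_rng(2)
        for mz in rng.uniform(200, 400, 5):
            fast = sorted(tuple(c.counts[e] for e in ("C", "H", "N", "O", "Cl"))
                          for c in enumerate_formulas(mz, cfg))
            assert fast == brute_force_enumeration(mz, cfg)

    def test_filters_hold_on_all_candidates(self):
        cfg = AssignmentConfig(ppm_tol=2.0)
        for c in enumerate_formulas(420.15, cfg):
            assert c.dbe == int(c.dbe) and c.dbe >= 0
            hc = c.counts["H"] / c.counts["C"]
            oc = c.counts["O"] / c.counts["C"]
            assert cfg.hc_range[0] <= hc <= cfg.hc_range[1]
            assert cfg.oc_range[0] <= oc <= cfg.oc_range[1]


class TestAssignment:
    def test_empty_list(self):
        assert assign_peaklist([]) == []

    def test_default_acquisition_range(self):
        assert AssignmentConfig().mz_range == (200.0, 1500.0)

    def test_order_independence(self):
        peaks, _ = simulate_ftms_peaklist(30, {"CHO": 0.6, "CHON": 0.4},
                                          0.5, seed=4)
        cfg = dom_assignment_config()
        fwd = assign_peaklist(peaks, cfg)
        rev = assign_peaklist(list(reversed(peaks)), cfg)
        fwd_map = {a.peak.mz: (a.candidate.formula if a.candidate else None)
                   for a in fwd}
        for a in rev:
            assert fwd_map[a.peak.mz] == (a.candidate.formula if a.candidate else None)

    def test_true_formula_recovery_rate(self):
        mix = {"CHO": 0.3, "CHON": 0.4, "CHOCl": 0.15, "CHONCl": 0.15}
        peaks, truth = simulate_ftms_peaklist(250, mix, 0.5, seed=11)
        asg = assign_peaklist(peaks, dom_assignment_config())
        hit = tot = 0
        for a, (_, row) in zip(asg, truth.ftms.iterrows()):
            if row["mz"] >= 500:
                continue
            tot += 1
            if a.candidate and all(a.candidate.counts[e] == int(row[e])
                                   for e in ("C", "H", "N", "O", "Cl")):
                hit += 1
        assert hit / tot >= 0.9


class TestVanKrevelen:
    def _assignment(self, counts):
        c = FormulaCandidate(counts, theoretical_mz(counts), 0.0,
                             dbe(counts), formula_class(counts))
        return Assignment(MassPeak(c.theoretical_mz, 1.0), c)

    def test_glucose_ratios(self):
        pts = van_krevelen([self._assignment({"C": 6, "H": 12, "O": 6})])
        assert pts[0].hc == pytest.approx(2.0)
        assert pts[0].oc == pytest.approx(1.0)

    def test_methane_ratios(self):
        pts = van_krevelen([self._assignment({"C": 1, "H": 4, "O": 0})])
        assert pts[0].hc == pytest.approx(4.0)
        assert pts[0].oc == pytest.approx(0.0)

    def test_point_count_conserved(self):
        asg = [self._assignment({"C": 6, "H": 12, "O": 6}),
               Assignment(MassPeak(300.0, 1.0), None)]
        assert len(van_krevelen(asg)) == 1


class TestClassProfile:
    def _assignments(self, class_counts):
        out = []
        for cls, n in class_counts.items():
            counts = {"CHO": {"C": 10, "H": 14, "O": 4},
                      "CHON": {"C": 10, "H": 15, "N": 1, "O": 4},
                      "CHOCl": {"C": 10, "H": 13, "O": 4, "Cl": 1},
                      "CHONCl": {"C": 10, "H": 14, "N": 1, "O": 4, "Cl": 1}}[cls]
            full = {e: counts.get(e, 0) for e in ("C", "H", "N", "O", "Cl")}
            cand = FormulaCandidate(full, theoretical_mz(full), 0.0,
                                    dbe(full), cls)
            out.extend(Assignment(MassPeak(cand.theoretical_mz, 1.0), cand)
                       for _ in range(n))
        return out

    def test_all_cho_zero_n_bearing(self):
        prof = class_profile(self._assignments({"CHO": 10}))
        assert prof.n_bearing == 0.0

    def test_counts_sum_and_oxygen_marginals(self):
        prof = class_profile(self._assignments(
            {"CHO": 5, "CHON": 3, "CHOCl": 2}))
        assert sum(prof.class_counts.values()) == prof.total_assigned == 10
        for cls, hist in prof.oxygen_hist.items():
            assert sum(hist.values()) == prof.class_counts[cls]
        assert prof.n_bearing == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            class_profile([Assignment(MassPeak(300.0, 1.0), None)])


class TestCompareProfiles:
    def _profile(self, label, n_cho, n_chon):
        from ventree.ftms import ClassProfile
        return ClassProfile(label, n_cho + n_chon,
                            {"CHO": n_cho, "CHON": n_chon})

    def test_identical_profiles_no_rise(self):
        tbl = compare_profiles([self._profile("a", 70, 30),
                                self._profile("b", 70, 30)])
        assert not tbl["monotone_rise"].any()
        assert (tbl["diff"] == 0).all()

    def test_strict_rise_flagged(self):
        tbl = compare_profiles([self._profile("a", 70, 30),
                                self._profile("b", 52, 48),
                                self._profile("c", 49, 51)])
        assert tbl["monotone_rise"].all()

    def test_simulated_preset_scenario_monotone_rise(self):
        """Activity presets mirroring the 0.30 -> 0.48 -> 0.51 N-shift."""
        cfg = dom_assignment_config()
        profiles = []
        for label, p, n, sd in (("active", 0.299, 900, 21),
                                ("inactive_longqi", 0.479, 1500, 22),
                                ("inactive_other", 0.513, 1100, 23)):
            mix = {"CHO": (1 - p) * 0.9, "CHOCl": (1 - p) * 0.1,
                   "CHON": p * 0.85, "CHONCl": p * 0.15}
            peaks, _ = simulate_ftms_peaklist(n, mix, 0.5, seed=sd)
            profiles.append(class_profile(assign_peaklist(peaks, cfg), label))
        tbl = compare_profiles(profiles)
        assert tbl["monotone_rise"].all()
        assert bool(tbl.iloc[0]["ci_excludes_zero"])
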