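"""Unit and property tests for the four disproportionality statistics."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pvsignal.errors import DegenerateInputError
from pvsignal.stats import (ContingencyTable, SignalResult, Thresholds,
                            bcpnn_ic, build_contingency, compute_signal,
                            evaluate_thresholds, information_component,
                            mgps_ebgm, prr, ror, round_half_up, screen)
from pvsignal.synthetic import generate_reports

from conftest import SMALL_SYNONYMS, make_universe


def brute_force_stats(a, b, c, d):
    """Independent re-derivation of all five quantities from first
    principles (kept deliberately separate from the implementation)."""
    n = a + b + c + d
    out = {}
    out["ror"] = (a / c) / (b / d)
    out["prr"] = (a / (a + b)) / (c / (c + d))
    exp = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
           [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
    obs = [[a, b], [c, d]]
    out["chi2"] = sum((obs[i][j] - exp[i][j]) ** 2 / exp[i][j]
                      for i in range(2) for j in range(2))
    aexp = exp[0][0]
    out["ic"] = math.log((a + 0.5) / (aexp + 0.5)) / math.log(2)
    out["ebgm"] = a / aexp
    return out


class TestPointEstimates:
    @pytest.mark.parametrize("cells, expected_ror", [
        ((1, 1, 1, 1), 1.0),
        ((4, 10, 20, 650), 13.0),
        ((6, 3, 10, 5), 1.0),      # ad = bc null family
        ((30, 15, 8, 4), 1.0),
    ])
    def test_ror_hand_values(self, cells, expected_ror):
        assert ror(ContingencyTable(*cells)).ror == pytest.approx(expected_ror, rel=1e-12)

    def test_prr_and_chi2_hand_values(self):
        est = prr(ContingencyTable(4, 10, 20, 650))
        assert est.prr == pytest.approx((4 / 14) / (20 / 670), rel=1e-12)
        est2 = prr(ContingencyTable(10, 20, 30, 40))
        assert est2.chi2 == pytest.approx(
            (10 * 40 - 20 * 30) ** 2 * 100 / (30 * 70 * 40 * 60), rel=1e-12)

    def test_chi2_zero_under_independence(self):
        assert prr(ContingencyTable(6, 3, 10, 5)).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_ebgm_hand_value_and_identity(self):
        t = ContingencyTable(4, 10, 20, 650)
        est = mgps_ebgm(t)
        assert est.ebgm == pytest.approx(4 * 684 / (24 * 14), rel=1e-12)
        # EBGM * aexp = a for every table
        assert est.ebgm * t.aexp == pytest.approx(t.a, rel=1e-12)

    def test_ic_zero_when_observed_equals_expected(self):
        ic, _ = information_component(10.0, 10.0)
        assert ic == 0.0

    @pytest.mark.parametrize("a, ebgm, want_ic, want_ic025", [
        # recomputed from printed (case count, observed/expected) pairs
        (1211, 2.42, 1.27, 1.18),
        (330, 4.60, 2.19, 2.01),
        (7, 28.57, 3.33, 2.03),
    ])
    def test_ic_from_observed_expected_pairs(self, a, ebgm, want_ic, want_ic025):
        ic, ic025 = information_component(a, a / ebgm)
        assert round_half_up(ic) == want_ic
        assert round_half_up(ic025) == want_ic025


class TestOracleEquivalence:
    def test_thousand_random_tables_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 200, size=4)
            t = ContingencyTable(float(a), float(b), float(c), float(d))
            want = brute_force_stats(a, b, c, d)
            assert ror(t).ror == pytest.approx(want["ror"], rel=1e-12)
            est = prr(t)
            assert est.prr == pytest.approx(want["prr"], rel=1e-12)
            assert est.chi2 == pytest.approx(want["chi2"], rel=1e-12)
            assert bcpnn_ic(t).ic == pytest.approx(want["ic"], rel=1e-12)
            assert mgps_ebgm(t).ebgm == pytest.approx(want["ebgm"], rel=1e-12)

    def test_chi2_matches_scipy_uncorrected(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable(float(a), float(b), float(c), float(d))
            ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            assert prr(t).chi2 == pytest.approx(ref, rel=1e-10)

    def test_ror_ci_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            table = sm.Table2x2([[a, b], [c, d]])
            est = ror(ContingencyTable(float(a), float(b), float(c), float(d)))
            assert est.ror == pytest.approx(table.oddsratio, rel=1e-10)
            lo, hi = table.oddsratio_confint(alpha=0.05)
            assert est.ror025 == pytest.approx(lo, rel=1e-9)
            assert est.ror975 == pytest.approx(hi, rel=1e-9)


class TestStructuralProperties:
    def test_ci_symmetric_on_log_scale(self):
        t = ContingencyTable(12, 300, 40, 5000)
        r = ror(t)
        assert r.ror975 / r.ror == pytest.approx(r.ror / r.ror025, rel=1e-10)
        e = mgps_ebgm(t)
        assert e.ebgm95 / e.ebgm == pytest.approx(e.ebgm / e.ebgm05, rel=1e-10)

    def test_monotone_in_a(self):
        # strict growth holds in the signal-detection regime a < b, c
        # (for a far beyond its margins EBGM ~ n/a turns over)
        b, c, d = 50.0, 80.0, 4000.0
        prev = None
        for a in [3.0, 10.0, 25.0, 45.0]:
            t = ContingencyTable(a, b, c, d)
            cur = (ror(t).ror, prr(t).prr, bcpnn_ic(t).ic, mgps_ebgm(t).ebgm)
            if prev is not None:
                assert all(x > y for x, y in zip(cur, prev))
            prev = cur

    def test_prr_close_to_ror_for_rare_events(self):
        # event rare within both arms -> the two ratios nearly coincide
        t = ContingencyTable(25, 10000, 400, 900000)
        assert prr(t).prr == pytest.approx(ror(t).ror, rel=5e-3)

    def test_ic_shrinks_below_log2_ebgm_and_converges(self):
        t = ContingencyTable(9, 500, 90, 40000)  # aexp < a
        assert bcpnn_ic(t).ic < math.log2(mgps_ebgm(t).ebgm)
        big = ContingencyTable(1e6, 5e7, 9e6, 4e9)
        assert abs(bcpnn_ic(big).ic - math.log2(mgps_ebgm(big).ebgm)) < 1e-3

    def test_zero_cells_yield_nan_not_exception(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert math.isnan(ror(t).ror)
        res = compute_signal("d", "e", "PT", t)
        assert not (res.ror_flag or res.prr_flag or res.mgps_flag)
        # IC is total even at a = 0
        assert math.isfinite(res.ic)


class TestThresholdFlags:
    def base(self, **kw):
        fields = dict(drug="d", event="e", level="PT", a=10, ror=3, ror025=2,
                      ror975=5, prr=3, chi2=10, ic=1, ic025=0.5, ebgm=3,
                      ebgm05=2.5, aexp=3.0)
        fields.update(kw)
        return SignalResult(**fields)

    def test_min_cases_rule(self):
        assert not evaluate_thresholds(self.base(a=2, ror025=5.0)).ror_flag
        assert evaluate_thresholds(self.base(a=3, ror025=5.0)).ror_flag

    def test_strict_lower_bound_rules(self):
        assert not evaluate_thresholds(self.base(ic025=0.0)).bcpnn_flag
        assert evaluate_thresholds(self.base(ic025=1e-9)).bcpnn_flag
        assert not evaluate_thresholds(self.base(ebgm05=2.0)).mgps_flag
        assert evaluate_thresholds(self.base(ebgm05=2.0 + 1e-9)).mgps_flag
        assert not evaluate_thresholds(self.base(ror025=1.0)).ror_flag

    def test_prr_needs_all_three_conditions(self):
        assert evaluate_thresholds(self.base(prr=2.0, chi2=4.0, a=3)).prr_flag
        assert not evaluate_thresholds(self.base(prr=1.99)).prr_flag
        assert not evaluate_thresholds(self.base(chi2=3.99)).prr_flag
        assert not evaluate_thresholds(self.base(a=2)).prr_flag

    def test_large_count_row_flags(self):
        # strong, high-count pair clears the ROR criterion
        assert evaluate_thresholds(self.base(a=1211, ror025=2.31)).ror_flag


class TestContingencyConstruction:
    def test_enumerable_universe(self, tiny_universe):
        t = build_contingency(tiny_universe, "drugX", {"Seizure"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_report_with_two_target_pts_counts_once(self):
        rs = make_universe([
            (1, 1, [("drugX", "drugX", "PS")], ["Seizure", "Epilepsy"]),
            (2, 2, [("drugY", "drugY", "PS")], ["Nausea"]),
        ])
        t = build_contingency(rs, "drugX", {"Seizure", "Epilepsy"})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_empty_universe_raises(self):
        rs = make_universe([])
        with pytest.raises(DegenerateInputError):
            build_contingency(rs, "drugX", {"Seizure"})

    def test_matches_brute_force_double_loop(self, small_config):
        from pvsignal.ingest import deduplicate, normalize_drug_names
        rs = deduplicate(normalize_drug_names(
            generate_reports(small_config), SMALL_SYNONYMS))
        pts = {"Seizure"}
        for drug in ("drugX", "drugY"):
            t = build_contingency(rs, drug, pts)
            a = b = c = d = 0
            for rep in rs.iter_reports():
                is_ps = any(m.canonical == drug and m.role == "PS" for m in rep.drugs)
                has_ev = bool(rep.events & pts)
                if is_ps and has_ev:
                    a += 1
                elif is_ps:
                    b += 1
                elif has_ev:
                    c += 1
                else:
                    d += 1
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


class TestScreen:
    def test_min_cases_filter_and_ordering(self, small_config):
        from pvsignal.ingest import deduplicate, normalize_drug_names
        rs = deduplicate(normalize_drug_names(generate_reports(small_config), SMALL_SYNONYMS))
        out = screen(rs, ["drugX", "drugY"], {"Seizure", "Nausea", "Headache"},
                     event_set_name="All events")
        frame = out.to_frame()
        pt_rows = frame[frame.level == "PT"]
        assert (pt_rows.a >= 3).all()
        for drug, grp in pt_rows.groupby("drug"):
            assert list(grp.a) == sorted(grp.a, reverse=True)
        # one group-level row per drug
        assert (frame.level == "HLGT").sum() == 2

    def test_injected_pair_has_largest_ror(self, small_config):
        from pvsignal.ingest import deduplicate, normalize_drug_names
        rs = deduplicate(normalize_drug_names(generate_reports(small_config), SMALL_SYNONYMS))
        out = screen(rs, ["drugX"], {"Seizure", "Nausea", "Headache"})
        pt_rows = [r for r in out.results if r.level == "PT"]
        best = max(pt_rows, key=lambda r: r.ror)
        assert best.event == "Seizure"
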