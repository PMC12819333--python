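"""Disproportionality estimators against hand computations, Monte-Carlo
posteriors, closed-form posteriors and the synthetic generator's truth."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignal import cohort, disprop, faers_io, synth
from pvsignal.disprop import (BCPNN_PRIORS, ContingencyTable, bcpnn_ic,
                              build_contingency, evaluate_criteria, mgps_ebgm,
                              mgps_fit, prr_stat, ror_stat)

T_REF = ContingencyTable(10, 90, 100, 9900)


class TestRorPrr:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert ror_stat(t)[0] == 1.0
        prr, chi2 = prr_stat(t)
        assert prr == 1.0 and chi2 == pytest.approx(0.0, abs=1e-12)

    def test_reference_table_hand_computation(self):
        # ror = (10*9900)/(90*100) = 11; Woolf: ln 11 +- 1.96*sqrt(0.121212)
        ror, lo, hi = ror_stat(T_REF)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(11.0 * math.exp(-1.96 * se))
        assert (lo, hi) == (pytest.approx(5.5595, abs=0.0005),
                            pytest.approx(21.7645, abs=0.0005))
        # prr = (10/100)/(100/10000) = 10; Pearson chi2 with E(a)=1.0891
        prr, chi2 = prr_stat(T_REF)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.45, abs=0.01)

    def test_zero_cell_haldane_correction(self):
        t = ContingencyTable(0, 10, 10, 100)
        ror, lo, hi = ror_stat(t)
        expected = (0.5 * 100.5) / (10.5 * 10.5)
        assert ror == pytest.approx(expected)
        assert t.has_zero_cell
        assert np.isfinite([ror, lo, hi]).all()

    def test_equal_proportions_give_zero_chi2(self):
        t = ContingencyTable(5, 45, 20, 180)  # both risks 0.1
        prr, chi2 = prr_stat(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("cells", [
        (10, 990, 100, 98_900),
        (50, 4950, 450, 94_550),
        (3, 197, 800, 99_000),
    ])
    def test_rare_event_ror_close_to_prr(self, cells):
        t = ContingencyTable(*cells)
        assert t.a + t.c <= 0.01 * t.n
        ror, *_ = ror_stat(t)
        prr, _ = prr_stat(t)
        assert abs(ror - prr) / prr < 0.05


class TestBuildContingency:
    def test_four_reports_one_per_cell(self, dictionary):
        import pandas as pd
        store = pd.DataFrame({
            "primaryid": [1, 2, 3, 4],
            "caseid": list("ABCD"), "fda_dt": ["20200101"] * 4,
            "event_dt": [""] * 4, "sex": ["male"] * 4,
            "age_years": [50.0] * 4, "country": ["US"] * 4,
            "reporter": ["missing"] * 4, "outcomes": ["missing"] * 4,
        })
        drug = pd.DataFrame({
            "PRIMARYID": ["1", "2", "3", "4"],
            "DRUGNAME": ["NIVOLUMAB", "NIVOLUMAB", "ASPIRIN", "ASPIRIN"],
            "ROLE_COD": ["PS"] * 4,
        })
        regimens = cohort.assign_regimens(drug, dictionary)
        t = build_contingency(store, regimens, {1, 3}, "nivolumab")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_cells_sum_to_store_size(self, small_store, dictionary):
        tables, store, _ = small_store
        regimens = cohort.assign_regimens(tables.drug, dictionary)
        events = cohort.select_event_reports(
            tables.reac, cohort.load_default_terms())
        for exposure in ("all", "PD-1i", "nivolumab", "Nivo+Ipi"):
            t = build_contingency(store, regimens, events, exposure)
            assert t.n == len(store)

    def test_cells_match_generator_expectation(self):
        """Observed cells stay within 3 binomial SDs of the closed-form
        generator expectation across seeds."""
        for seed in range(10):
            cfg = synth.SyntheticConfig(
                n_reports=20_000, exposure_probs={"nivolumab": 0.02},
                background_event_prob=0.001, signal_rhos={"nivolumab": 10.0},
                seed=seed)
            ds = synth.generate(cfg)
            tables = synth.as_tableset(ds)
            store, _ = faers_io.build_report_store(tables)
            regimens = cohort.assign_regimens(tables.drug)
            events = cohort.select_event_reports(tables.reac, ["Pemphigoid"])
            t = build_contingency(store, regimens, events, "nivolumab")
            exp = synth.expected_cells(cfg, "nivolumab")
            for obs, mean in zip((t.a, t.b, t.c, t.d), exp):
                sd = math.sqrt(max(mean * (1 - mean / cfg.n_reports), 1.0))
                assert abs(obs - mean) <= 3 * sd

    def test_empty_store_is_error(self, dictionary):
        import pandas as pd
        empty = pd.DataFrame(columns=["primaryid"])
        regimens = cohort.assign_regimens(
            pd.DataFrame(columns=["PRIMARYID", "DRUGNAME", "ROLE_COD"]))
        with pytest.raises(ValueError):
            build_contingency(empty, regimens, set(), "all")


def _mc_ic(table, n_draws, rng):
    """Monte-Carlo posterior of the information component: sample the cell,
    row and column probabilities from their stated Beta posteriors."""
    p = BCPNN_PRIORS
    a, cx, cy, C = table.a, table.a + table.b, table.a + table.c, table.n
    g = p["gamma11"] * (C + p["alpha"]) * (C + p["beta"]) / (
        (cx + p["alpha1"]) * (cy + p["beta1"]))
    p11 = rng.beta(a + p["gamma11"], C - a + g - p["gamma11"], n_draws)
    px = rng.beta(cx + p["alpha1"], C - cx + p["alpha"] - p["alpha1"], n_draws)
    py = rng.beta(cy + p["beta1"], C - cy + p["beta"] - p["beta1"], n_draws)
    ic = np.log2(p11 / (px * py))
    return float(ic.mean()), float(np.quantile(ic, 0.025))


class TestBcpnn:
    def test_independent_table_near_zero(self):
        ic, _, ic025 = bcpnn_ic(ContingencyTable(10, 90, 990, 8910))
        assert abs(ic) < 0.15
        assert ic025 < 0

    def test_shrinks_toward_zero_from_point_ic(self):
        ic, _, _ = bcpnn_ic(T_REF)
        point = math.log2(10 * 10100 / (100 * 110))  # 3.1989
        assert point == pytest.approx(3.20, abs=0.005)
        assert 0 < ic < point

    def test_defined_at_zero_count(self):
        ic, var, ic025 = bcpnn_ic(ContingencyTable(0, 50, 50, 900))
        assert np.isfinite([ic, var, ic025]).all()
        assert ic025 < 0

    def test_closed_form_matches_monte_carlo(self):
        """Closed-form IC and IC025 within 0.05 bits of a 1e6-draw
        posterior sample on a 20-table grid (a >= 20, where the normal
        lower-bound approximation is accurate)."""
        rng = np.random.default_rng(2024)
        grid = [(a, bf * a, cf * a, df * a)
                for a in (20, 25, 30, 40, 60)
                for bf, cf, df in ((1, 1, 10), (2, 1, 20), (1, 2, 20),
                                   (2, 2, 50))]
        assert len(grid) == 20
        for cells in grid:
            table = ContingencyTable(*cells)
            ic, _, ic025 = bcpnn_ic(table)
            mc_mean, mc_q = _mc_ic(table, 10**6, rng)
            assert ic == pytest.approx(mc_mean, abs=0.05)
            assert ic025 == pytest.approx(mc_q, abs=0.05)

    def test_converges_to_point_ic_at_scale(self):
        base = np.array([10, 90, 100, 9900])
        point = math.log2(10 * 10100 / (100 * 110))
        gaps = []
        for k in (10, 100, 1000):
            ic, _, _ = bcpnn_ic(ContingencyTable(*(base * k)))
            gaps.append(abs(ic - point))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 5e-3


class TestMgps:
    def test_single_gamma_prior_recovery(self):
        rng = np.random.default_rng(7)
        E = rng.uniform(0.5, 20, 5000)
        lam = rng.gamma(2.0, 1 / 4.0, 5000)
        a = rng.poisson(lam * E)
        h = mgps_fit(a, E)
        mean = h.mix_p * h.alpha1 / h.beta1 + (1 - h.mix_p) * h.alpha2 / h.beta2
        assert abs(mean - 0.5) / 0.5 < 0.2

    def test_null_grid_concentrates_at_one(self):
        rng = np.random.default_rng(3)
        E = rng.uniform(1, 30, 2000)
        a = np.round(E)
        h = mgps_fit(a, E)
        mean = h.mix_p * h.alpha1 / h.beta1 + (1 - h.mix_p) * h.alpha2 / h.beta2
        assert 0.8 <= mean <= 1.25

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        E = rng.uniform(0.5, 5, 200)
        a = rng.poisson(E)
        h1 = mgps_fit(a, E)
        perm = rng.permutation(200)
        h2 = mgps_fit(a[perm], E[perm])
        assert h1.loglik == pytest.approx(h2.loglik, abs=1e-6)

    def test_too_few_cells_is_error(self):
        with pytest.raises(ValueError):
            mgps_fit(np.ones(5), np.ones(5))

    def test_ebgm_digamma_closed_form(self):
        """Single-component prior Gamma(1,1), a=10, E=1: posterior is
        Gamma(11, rate 2), so EBGM = exp(psi(11) - ln 2) and EBGM05 is the
        5% gamma quantile -- both checked against scipy directly."""
        h = disprop.MgpsHyperparams(1.0, 1.0, 1.0, 1.0, 0.5, 0.0)
        ebgm, ebgm05 = mgps_ebgm(10, 1.0, h)
        assert ebgm == pytest.approx(math.exp(special.digamma(11) - math.log(2)))
        assert ebgm == pytest.approx(5.25, abs=0.005)
        assert ebgm05 == pytest.approx(
            stats.gamma.ppf(0.05, 11, scale=0.5), abs=1e-6)

    def test_point_mass_prior_pins_ebgm_at_one(self):
        h = disprop.MgpsHyperparams(1e4, 1e4, 1e4, 1e4, 0.5, 0.0)
        for a in (0, 1, 10, 100):
            ebgm, _ = mgps_ebgm(a, 1.0, h)
            assert 0.99 <= ebgm <= 1.01

    def test_ebgm05_below_ebgm_on_grid(self):
        h = disprop.MgpsHyperparams(0.5, 0.1, 2.0, 2.0, 0.2, 0.0)
        for a in range(0, 60, 3):
            for E in np.linspace(0.5, 40, 20):
                ebgm, ebgm05 = mgps_ebgm(float(a), float(E), h)
                assert ebgm05 < ebgm

    def test_ebgm_monotone_in_a_and_shrinks(self):
        rng = np.random.default_rng(7)
        E = rng.uniform(0.5, 20, 2000)
        lam = rng.gamma(2.0, 1 / 4.0, 2000)
        a = rng.poisson(lam * E)
        h = mgps_fit(a, E)
        prev = 0.0
        for count in range(0, 30):
            ebgm, _ = mgps_ebgm(count, 4.0, h)
            assert ebgm >= prev
            prev = ebgm
        # shrinkage toward 1 for an elevated cell
        ebgm, _ = mgps_ebgm(12, 4.0, h)
        assert 1 < ebgm < 12 / 4.0


class TestCriteria:
    def test_reference_row_with_small_count(self):
        flags = evaluate_criteria(3, 6.05, 1.95, 6.05, 12.64, -0.1, 1.95)
        assert flags == {"ror_pos": True, "prr_pos": True,
                         "bcpnn_pos": False, "mgps_pos": False}

    def test_below_three_cases_all_false(self):
        flags = evaluate_criteria(2, 100.0, 50.0, 100.0, 500.0, 3.0, 30.0)
        assert not any(flags.values())

    def test_exact_thresholds_are_negative(self):
        flags = evaluate_criteria(10, 1.0, 1.0, 1.9, 3.9, 0.0, 2.0)
        assert not any(flags.values())

    def test_prr_threshold_inclusive(self):
        flags = evaluate_criteria(10, 3.0, 2.0, 2.0, 4.0, 0.5, 2.5)
        assert flags["prr_pos"] and flags["ror_pos"]
        assert flags["bcpnn_pos"] and flags["mgps_pos"]
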