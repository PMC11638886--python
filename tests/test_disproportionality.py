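"""Disproportionality statistics against independent oracles.

Closed-form hand evaluations check ROR/PRR/chi-square; Monte-Carlo samples
of the stated posteriors check the Bayesian interval bounds; simulation
checks empirical-Bayes prior recovery and shrinkage.
"""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignal.cohort import ContingencyTable, all_pairs_2x2
from pvsignal.disproportionality import (
    MgpsPrior,
    SignalCriteria,
    SignalStats,
    _bh_adjust,
    chi2_stat,
    compute_signal_stats,
    ebgm_mgps,
    evaluate_signal,
    fit_mgps_prior,
    flag_ime,
    ic_bcpnn,
    prr,
    ror,
    screen_soc,
)

Z = 1.959963984540054


def oracle_ror(a, b, c, d):
    """Independent closed-form evaluation of ROR and its Wald CI."""
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z * se), est * math.exp(Z * se)


def oracle_prr(a, b, c, d):
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, est * math.exp(-Z * se), est * math.exp(Z * se)


def oracle_chi2(a, b, c, d):
    """Pearson chi-square summed cell by cell from expected counts."""
    n = a + b + c + d
    total = 0.0
    for obs, r, col in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)):
        e = r * col / n
        total += (obs - e) ** 2 / e
    return total


class TestRor:
    def test_balanced_table_is_unity_with_symmetric_ci(self):
        r = ror((5, 5, 5, 5))
        assert r.estimate == pytest.approx(1.0)
        assert r.lo95 * r.hi95 == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        r = ror((10, 90, 100, 9900))
        est, lo, hi = oracle_ror(10, 90, 100, 9900)
        assert r.estimate == pytest.approx(11.0)
        assert (r.lo95, r.hi95) == pytest.approx((lo, hi))
        assert (r.lo95, r.hi95) == pytest.approx((5.56, 21.77), abs=0.01)

    def test_zero_cell_is_undefined_marker(self):
        r = ror((0, 10, 10, 100))
        assert not r.defined and math.isnan(r.lo95)

    def test_haldane_correction_by_flag(self):
        r = ror((0, 10, 10, 100), haldane=True)
        assert r.defined
        assert r.estimate == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))


class TestPrr:
    def test_independence_gives_unity_and_zero_chi2(self):
        p = prr((10, 90, 100, 900))  # a/(a+b) = c/(c+d) = 0.1
        assert p.estimate == pytest.approx(1.0)
        assert p.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        p = prr((10, 90, 100, 9900))
        est, lo, hi = oracle_prr(10, 90, 100, 9900)
        assert p.estimate == pytest.approx(10.0)
        assert (p.lo95, p.hi95) == pytest.approx((lo, hi))
        assert p.chi2 == pytest.approx(oracle_chi2(10, 90, 100, 9900))
        # cross-check chi-square against the library contingency test
        assert p.chi2 == pytest.approx(
            stats.chi2_contingency(np.array([[10, 90], [100, 9900]]), correction=False)[0]
        )

    def test_comparator_zero_is_undefined(self):
        assert not prr((3, 0, 0, 10)).defined

    def test_yates_flag_reduces_chi2(self):
        assert chi2_stat((10, 90, 100, 9900), yates=True) < chi2_stat((10, 90, 100, 9900))


class TestIcBcpnn:
    def test_point_identity_when_observed_equals_expected(self):
        # a = 10 with margins making E = 10 exactly: a+b=100, a+c=100, N=1000
        ic = ic_bcpnn((10, 90, 90, 810))
        assert ic.ic == pytest.approx(0.0)

    def test_direct_evaluation(self):
        t = ContingencyTable(a=10, b=0, c=0, d=0, drug="d", pt="p")
        # construct E=2 through a raw tuple instead: margins (a+b)(a+c)/N = 2
        ic = ic_bcpnn((10, 10, 10, 990))  # E = 20*20/1020 = 0.392...
        e = 20 * 20 / 1020
        assert ic.ic == pytest.approx(math.log2(10.5 / (e + 0.5)))

    def test_lower_bound_matches_monte_carlo_quantile(self, rng):
        for a, e in [(1, 0.5), (10, 2.0), (100, 50.0), (3, 3.0)]:
            draws = rng.gamma(a + 0.5, 1.0 / (e + 0.5), size=1_000_000)
            mc = math.log2(np.quantile(draws, 0.025))
            ic025 = math.log2(stats.gamma.ppf(0.025, a + 0.5, scale=1 / (e + 0.5)))
            assert ic025 == pytest.approx(mc, abs=0.02)

    def test_ic025_below_ic(self):
        for cells in [(10, 10, 10, 990), (3, 100, 5, 5000), (50, 50, 50, 50)]:
            ic = ic_bcpnn(cells)
            assert ic.ic025 < ic.ic


class TestMgps:
    PRIOR = MgpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p_mix=1 / 3)

    def test_single_gamma_closed_form(self):
        # both components Gamma(1,1) and E ~ 0: posterior is the prior and
        # EBGM = exp(psi(1)) = exp(-euler_gamma)
        prior = MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        eb = ebgm_mgps((0, 1, 1, 10**9), prior)  # E ~ 2e-9
        assert eb.ebgm == pytest.approx(math.exp(special.digamma(1.0)), rel=1e-6)
        assert eb.ebgm == pytest.approx(0.5615, abs=1e-4)

    def test_shrinkage_vanishes_for_large_counts(self):
        from pvsignal.disproportionality import ebgm_from_ae

        a, e = 100_000, 10.0
        eb = ebgm_from_ae(a, e, self.PRIOR)
        assert eb.ebgm == pytest.approx(a / e, rel=0.02)

    def test_ebgm05_matches_monte_carlo_quantile(self, rng):
        from pvsignal.disproportionality import _posterior_mixture, ebgm_from_ae

        for a, e in [(1, 0.5), (5, 1.0), (50, 10.0), (200, 40.0)]:
            shapes, rates, w = _posterior_mixture(float(a), float(e), self.PRIOR)
            comp = rng.choice(2, p=w, size=1_000_000)
            draws = rng.gamma(shapes[comp], 1.0 / rates[comp])
            mc = float(np.quantile(draws, 0.05))
            assert ebgm_from_ae(a, e, self.PRIOR).ebgm05 == pytest.approx(mc, rel=0.01)

    def test_prior_recovery_from_simulation(self, rng):
        n = 20_000
        e = 10 ** rng.uniform(-1, 2, n)
        comp = rng.random(n) < 1 / 3
        lam = np.where(comp, rng.gamma(0.2, 1 / 0.1, n), rng.gamma(2.0, 1 / 4.0, n))
        a = rng.poisson(lam * e)
        prior = fit_mgps_prior(a, e, seed=0)
        assert prior.converged
        assert prior.alpha1 == pytest.approx(0.2, rel=0.25)
        assert prior.beta1 == pytest.approx(0.1, rel=0.25)
        assert prior.alpha2 == pytest.approx(2.0, rel=0.25)
        assert prior.beta2 == pytest.approx(4.0, rel=0.25)
        assert prior.p_mix == pytest.approx(1 / 3, abs=0.05)

    def test_single_component_data_collapses_mixture(self):
        rng = np.random.default_rng(7)
        n = 20_000
        e = 10 ** rng.uniform(-1, 2, n)
        lam = rng.gamma(2.0, 1 / 4.0, n)
        a = rng.poisson(lam * e)
        prior = fit_mgps_prior(a, e, seed=0)
        assert min(prior.p_mix, 1 - prior.p_mix) <= 0.05

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError):
            fit_mgps_prior(np.array([1.0]), np.array([1.0]))

    def test_invalid_prior_rejected(self):
        bad = MgpsPrior(-1.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            ebgm_mgps((5, 5, 5, 5), bad)

    def test_shrinkage_toward_null_with_null_fitted_prior(self, rng):
        # prior fitted on pure-null pairs (a ~ Poisson(E)) pulls every
        # estimate toward lambda = 1
        n = 20_000
        e = 10 ** rng.uniform(-0.5, 2, n)
        a = rng.poisson(e)
        prior = fit_mgps_prior(a, e, seed=1)
        from pvsignal.disproportionality import ebgm_from_ae

        # shrinkage is a statement about tables from the population the
        # prior was fitted to, so test tables follow the same null law
        checked = 0
        while checked < 1000:
            ee = float(10 ** rng.uniform(-0.5, 2))
            aa = int(rng.poisson(ee))
            if aa < 1:
                continue
            checked += 1
            ebgm = ebgm_from_ae(aa, ee, prior).ebgm
            # slack covers the posterior geometric-mean offset
            # (~ -1/(2(alpha+a))) and the fitted prior's components sitting
            # slightly off lambda = 1
            slack = 1.0 / (2 * aa) + 0.02
            assert abs(math.log(ebgm)) <= abs(math.log(aa / ee)) + slack


class TestSignalEvaluation:
    def _stats(self, **kw):
        base = dict(
            drug="d", pt="p", n=10, expected=2.0, ror=3.0, ror_lo95=1.5, ror_hi95=6.0,
            prr=2.9, prr_lo95=1.4, prr_hi95=5.8, chi2=12.0, ic=1.2, ic025=0.4,
            ebgm=2.8, ebgm05=2.1,
        )
        base.update(kw)
        return SignalStats(**base)

    def test_signal_rule_from_reported_pair(self):
        s = self._stats(n=135, ror=1.31, ror_lo95=1.1, ror_hi95=1.55)
        is_sig, _ = evaluate_signal(s)
        assert is_sig

    def test_report_count_rule(self):
        s = self._stats(n=2, ror_lo95=8.0)
        assert not evaluate_signal(s)[0]

    def test_lower_bound_rule(self):
        s = self._stats(n=50, ror_lo95=0.99)
        assert not evaluate_signal(s)[0]

    def test_four_algorithm_concordance(self):
        s = self._stats()
        _, met = evaluate_signal(s)
        assert met == {"ROR", "PRR", "BCPNN", "MGPS"}

    def test_undefined_markers_fail_their_rule(self):
        s = self._stats(ror_lo95=float("nan"), ic025=float("nan"), ebgm05=float("nan"))
        is_sig, met = evaluate_signal(s)
        assert not is_sig and met == {"PRR"}

    def test_thresholds_overridable(self):
        s = self._stats(ebgm05=1.5)
        _, met = evaluate_signal(s, SignalCriteria(ebgm05_threshold=1.2))
        assert "MGPS" in met


class TestAlgebraicProperties:
    def test_prr_between_unity_and_ror_on_random_tables(self, rng):
        # ROR/PRR = (1 + a/b)/(1 + c/d): PRR <= ROR iff a/b >= c/d, i.e. the
        # PRR always lies between 1 and the ROR
        for _ in range(2000):
            a, b, c, d = rng.integers(1, 500, size=4)
            r, p = ror((a, b, c, d)), prr((a, b, c, d))
            if r.estimate >= 1:
                assert 1 - 1e-12 <= p.estimate <= r.estimate * (1 + 1e-12)
            else:
                assert r.estimate * (1 - 1e-12) <= p.estimate <= 1 + 1e-12

    def test_interval_ordering_on_fixture_pairs(self, analytic):
        pairs = all_pairs_2x2(analytic)
        prior = fit_mgps_prior(pairs["a"].to_numpy(float), pairs["expected"].to_numpy(float))
        sample = pairs.loc[pairs["a"] >= 3].sample(30, random_state=1)
        for row in sample.itertuples(index=False):
            t = ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d), row.drug, row.pt)
            s = compute_signal_stats(t, prior)
            assert s.ic025 < s.ic
            assert s.ebgm05 < s.ebgm
            if not math.isnan(s.ror):
                assert s.ror_lo95 <= s.ror <= s.ror_hi95
            if not math.isnan(s.prr):
                assert s.prr_lo95 <= s.prr <= s.prr_hi95


class TestScreening:
    def test_bh_matches_hand_computed_step_up(self):
        adj = _bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        adj2 = _bh_adjust(np.array([0.005, 0.04, 0.03, 0.9]))
        # step-up: sorted p*(m/rank) with monotonicity from the largest down
        assert adj2 == pytest.approx([0.02, 0.053333333, 0.053333333, 0.9])

    def test_bh_monotone_and_at_least_raw(self, rng):
        p = rng.random(100)
        adj = _bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_exclusion_absent_from_signals_present_in_volcano(self, analytic):
        from pvsignal.synthetic import default_pt_soc_map

        volcano, signals = screen_soc(
            analytic,
            "duloxetine",
            default_pt_soc_map(),
            soc="Reproductive system and breast disorders",
            exclusions=["Erectile dysfunction"],
        )
        assert "Erectile dysfunction" in set(volcano["pt"])
        assert "Erectile dysfunction" not in set(signals["pt"])

    def test_injected_pair_has_smallest_fdr_p(self, analytic):
        from pvsignal.synthetic import default_pt_soc_map

        volcano, signals = screen_soc(
            analytic,
            "duloxetine",
            default_pt_soc_map(),
            soc="Reproductive system and breast disorders",
        )
        best = volcano.loc[volcano["p_fdr"].idxmin(), "pt"]
        # the strongest injected duloxetine signal in the default scenario
        assert best in {"Sexual dysfunction", "Erectile dysfunction"}
        assert "Sexual dysfunction" in set(signals["pt"])

    def test_volcano_sorted_by_count_descending(self, analytic):
        from pvsignal.synthetic import default_pt_soc_map

        volcano, _ = screen_soc(analytic, "venlafaxine", default_pt_soc_map())
        assert (np.diff(volcano["n"]) <= 0).all()

    def test_empty_soc_gives_empty_tables(self, analytic):
        volcano, signals = screen_soc(analytic, "duloxetine", {}, soc="Nonexistent SOC")
        assert volcano.empty and signals.empty


class TestFlagIme:
    def test_exact_match(self):
        assert flag_ime("Erectile dysfunction", ["Erectile dysfunction"])

    def test_case_insensitive(self):
        assert flag_ime("ERECTILE DYSFUNCTION", ["erectile dysfunction"])

    def test_empty_list(self):
        assert not flag_ime("Erectile dysfunction", [])
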