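from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from catcad.bank import Bank, ItemParams, ItemSpec, ResponseMatrix
from catcad.bifactor import (
    EmptyBankError,
    EstimationOptions,
    LatentState,
    bank_information,
    category_probs,
    eap_score,
    filter_items,
    fit_bifactor,
    fit_unidimensional,
    item_information,
    lr_test,
    marginal_loglik,
    standardized_loadings,
)
from catcad.synthetic import gen_bank, gen_responses

from oracles import dense_eap, dense_marginal_loglik


def _uncalibrated(bank: Bank) -> Bank:
    return bank.with_params({})


def _simulate_binary_pair(n: int, seed: int) -> tuple[ResponseMatrix, Bank]:
    rng = np.random.default_rng(seed)
    items = [ItemSpec("i1", "s1", 2), ItemSpec("i2", "s1", 2)]
    bank = Bank(items=items, params={}, subdomains=("s1",))
    theta = rng.standard_normal(n)
    from scipy.special import expit

    p1 = expit(1.2 * theta - 0.3)
    p2 = expit(0.8 * theta + 0.4)
    codes = np.column_stack(
        [(rng.random(n) < p1).astype(int), (rng.random(n) < p2).astype(int)]
    )
    rm = ResponseMatrix(codes, [f"p{i}" for i in range(n)], ["i1", "i2"])
    return rm, bank


class TestCategoryProbs:
    def test_sum_to_one(self):
        p = ItemParams(1.4, 0.6, (-1.0, 0.2, 1.5))
        th = np.linspace(-4, 4, 23)
        probs = category_probs(p.a0, p.ag, p.thresholds, th[:, None], th[None, :])
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)


class TestFitOracles:
    def test_binary_pair_loglik_matches_dense_grid(self):
        responses, bank = _simulate_binary_pair(200, seed=7)
        res = fit_bifactor(responses, bank, EstimationOptions(tol=1e-8))
        oracle = dense_marginal_loglik(responses, res.bank, n_grid=1601)
        assert res.loglik == pytest.approx(oracle, rel=1e-6)

    def test_binary_pair_loglik_matches_pattern_sum(self):
        # with 2 binary items the marginal likelihood is a sum over the
        # 4 response patterns weighted by their observed counts
        responses, bank = _simulate_binary_pair(150, seed=11)
        res = fit_unidimensional(responses, bank, EstimationOptions(tol=1e-8))
        grid = np.linspace(-9, 9, 4001)
        phi = np.exp(-0.5 * grid**2) / np.sqrt(2 * np.pi)
        from scipy.special import expit

        p1 = res.bank.params["i1"]
        p2 = res.bank.params["i2"]
        total = 0.0
        for y1 in (0, 1):
            for y2 in (0, 1):
                count = int(
                    np.sum((responses.codes[:, 0] == y1) & (responses.codes[:, 1] == y2))
                )
                q1 = expit(p1.a0 * grid - p1.thresholds[0])
                q2 = expit(p2.a0 * grid - p2.thresholds[0])
                like = (q1 if y1 else 1 - q1) * (q2 if y2 else 1 - q2)
                total += count * np.log(np.trapezoid(like * phi, grid))
        assert res.loglik == pytest.approx(total, rel=1e-6)

    def test_mixed_bank_loglik_matches_dense_grid(self, mixed_bank):
        truth_bank = mixed_bank
        rng = np.random.default_rng(3)
        # simulate from the bifactor model with two subdomains
        n = 150
        theta = rng.standard_normal((n, 3))
        sub_index = {"s1": 1, "s2": 2}
        cols = []
        for spec in truth_bank.items:
            p = truth_bank.params[spec.item_id]
            probs = category_probs(
                p.a0, p.ag, p.thresholds, theta[:, 0], theta[:, sub_index[spec.subdomain]]
            )
            u = rng.random((n, 1))
            cols.append((u > np.cumsum(probs, axis=1)).sum(axis=1))
        codes = np.column_stack(cols)
        rm = ResponseMatrix(codes, [f"p{i}" for i in range(n)], truth_bank.item_ids)
        res = fit_bifactor(rm, _uncalibrated(truth_bank), EstimationOptions(tol=1e-7))
        assert res.n_group_slopes == 5
        oracle = dense_marginal_loglik(rm, res.bank, n_grid=1201)
        assert res.loglik == pytest.approx(oracle, rel=2e-6)

    def test_em_trace_is_monotone(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=150, seed=55)
        res = fit_bifactor(
            resp, _uncalibrated(fixture_truth.bank), EstimationOptions(quadrature_points=11)
        )
        trace = np.array(res.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1])))

    def test_null_group_slopes_shrink_and_lr_small(self):
        hits = 0
        for seed in (101, 102, 103):
            truth = gen_bank(
                n_items=12,
                subdomain_sizes={"s1": 6, "s2": 6},
                group_loading_range=(0.0, 0.0),
                seed=seed,
            )
            resp = gen_responses(truth, n_persons=500, seed=seed + 10)
            opts = EstimationOptions(quadrature_points=11, tol=1e-6)
            full = fit_bifactor(resp, _uncalibrated(truth.bank), opts)
            red = fit_unidimensional(resp, _uncalibrated(truth.bank), opts)
            test = lr_test(full, red)
            assert np.abs(full.loadings["lambdag"]).mean() < 0.25
            if test.chi2 < chi2_dist.ppf(0.95, test.df):
                hits += 1
        assert hits >= 2  # null should rarely be rejected


class TestNesting:
    def test_bifactor_dominates_unidimensional(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=120, seed=91)
        opts = EstimationOptions(quadrature_points=11)
        full = fit_bifactor(resp, _uncalibrated(fixture_truth.bank), opts)
        red = fit_unidimensional(resp, _uncalibrated(fixture_truth.bank), opts)
        assert full.loglik >= red.loglik - 1e-6

    def test_single_subdomain_bank_pins_group_slopes(self):
        truth = gen_bank(n_items=6, subdomain_sizes={"only": 6}, seed=5)
        resp = gen_responses(truth, n_persons=200, seed=6)
        opts = EstimationOptions(quadrature_points=15)
        full = fit_bifactor(resp, _uncalibrated(truth.bank), opts)
        red = fit_unidimensional(resp, _uncalibrated(truth.bank), opts)
        assert full.n_group_slopes == 0
        for iid in truth.bank.item_ids:
            assert full.bank.params[iid].ag == 0.0
            assert full.bank.params[iid].a0 == pytest.approx(
                red.bank.params[iid].a0, abs=1e-6
            )


class TestLrTest:
    def test_identity_gives_zero(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=100, seed=31)
        res = fit_bifactor(
            resp, _uncalibrated(fixture_truth.bank), EstimationOptions(quadrature_points=7)
        )
        out = lr_test(res, res)
        assert out.chi2 == 0.0
        assert out.df == 0
        assert out.p == 1.0

    def test_df_counts_freed_group_slopes(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=100, seed=32)
        opts = EstimationOptions(quadrature_points=7, max_iter=30)
        full = fit_bifactor(resp, _uncalibrated(fixture_truth.bank), opts)
        red = fit_unidimensional(resp, _uncalibrated(fixture_truth.bank), opts)
        assert lr_test(full, red).df == len(fixture_truth.bank)

    def test_rejects_different_data(self, fixture_truth):
        opts = EstimationOptions(quadrature_points=7, max_iter=20)
        r1 = gen_responses(fixture_truth, n_persons=80, seed=33)
        r2 = gen_responses(fixture_truth, n_persons=80, seed=34)
        full = fit_bifactor(r1, _uncalibrated(fixture_truth.bank), opts)
        red = fit_unidimensional(r2, _uncalibrated(fixture_truth.bank), opts)
        with pytest.raises(ValueError, match="different data"):
            lr_test(full, red)


class TestLoadings:
    def test_zero_slopes(self):
        lam0, lamg = standardized_loadings(ItemParams(0.0, 0.0, (0.5,)))
        assert lam0 == 0.0 and lamg == 0.0

    def test_unit_slope_closed_form(self):
        lam0, _ = standardized_loadings(ItemParams(1.0, 0.0, (0.5,)))
        assert lam0 == pytest.approx(1 / np.sqrt(2))

    def test_monotone_in_a0(self):
        vals = [
            standardized_loadings(ItemParams(a, 0.7, (0.0,)))[0]
            for a in np.linspace(0.1, 5, 25)
        ]
        assert np.all(np.diff(vals) > 0)


@pytest.fixture(scope="module")
def calib(fixture_truth):
    resp = gen_responses(fixture_truth, n_persons=250, seed=77)
    return fit_bifactor(
        resp,
        fixture_truth.bank.with_params({}),
        EstimationOptions(quadrature_points=11),
    )


class TestFilter:

    def test_vacuous_filter_keeps_all(self, calib):
        bank, report = filter_items(calib, min_loading=0.0)
        assert len(bank) == len(calib.bank)
        assert report.empty

    def test_impossible_threshold_errors(self, calib):
        with pytest.raises(EmptyBankError):
            filter_items(calib, min_loading=1.01)

    def test_report_lists_removed(self, calib):
        cut = float(calib.loadings["lambda0"].median())
        bank, report = filter_items(calib, min_loading=cut)
        assert len(bank) + len(report) == len(calib.bank)
        assert set(report.index) == set(calib.loadings.index) - set(bank.item_ids)
        assert (report["lambda0"] < cut).all()


class TestEap:
    def test_empty_returns_prior(self, mixed_bank):
        state = eap_score({}, mixed_bank)
        assert state.theta == pytest.approx(0.0, abs=1e-9)
        assert state.se == pytest.approx(1.0, abs=1e-6)

    def test_one_binary_item_matches_dense_oracle(self):
        bank = Bank(
            items=[ItemSpec("i1", "s1", 2)],
            params={"i1": ItemParams(1.5, 0.0, (0.0,))},
            subdomains=("s1",),
        )
        state = eap_score({"i1": 1}, bank)
        mean, sd = dense_eap({"i1": 1}, bank)
        assert state.theta == pytest.approx(mean, abs=1e-4)
        assert state.se == pytest.approx(sd, abs=1e-4)

    @pytest.mark.parametrize("marginalize", [True, False])
    def test_small_bank_matches_dense_oracle(self, mixed_bank, marginalize):
        answers = {"a1": 1, "a2": 2, "a3": 0, "b1": 1, "b2": 3}
        state = eap_score(answers, mixed_bank, marginalize_groups=marginalize)
        if marginalize:
            mean, sd = dense_eap(answers, mixed_bank)
        else:
            flat = mixed_bank.with_params(
                {
                    k: ItemParams(p.a0, 0.0, p.thresholds)
                    for k, p in mixed_bank.params.items()
                }
            )
            mean, sd = dense_eap(answers, flat)
        assert state.theta == pytest.approx(mean, abs=1e-4)
        assert state.se == pytest.approx(sd, abs=1e-4)

    def test_informative_item_reduces_expected_variance(self, mixed_bank):
        answers = {"a1": 1, "b1": 2}
        base = eap_score(answers, mixed_bank)
        # predictive category distribution of the candidate item given the
        # current posterior, by dense integration
        grid = np.linspace(-9, 9, 2001)
        from oracles import _norm_pdf, dense_person_likelihood

        post = dense_person_likelihood(answers, mixed_bank, grid) * _norm_pdf(grid)
        post /= np.trapezoid(post, grid)
        p = mixed_bank.params["a3"]
        expected_var = 0.0
        for k in range(4):
            marg = category_probs(p.a0, 0.0, p.thresholds, grid)[:, k]
            # a3 shares subdomain s1 with answered a1: integrate its group
            # factor at the prior for the predictive weight approximation
            tg, wg = np.polynomial.hermite.hermgauss(31)
            tg, wg = tg * np.sqrt(2), wg / np.sqrt(np.pi)
            marg = category_probs(
                p.a0, p.ag, p.thresholds, grid[:, None], tg[None, :]
            )[..., k] @ wg
            pk = float(np.trapezoid(post * marg, grid))
            state_k = eap_score({**answers, "a3": k}, mixed_bank)
            expected_var += pk * state_k.se**2
        assert expected_var <= base.se**2 + 1e-6


class TestInformation:
    def test_zero_slope_zero_information(self):
        p = ItemParams(0.0, 0.8, (-0.5, 0.5))
        th = np.linspace(-4, 4, 17)
        np.testing.assert_allclose(item_information(p, th), 0.0, atol=1e-14)

    def test_binary_closed_form(self):
        from scipy.special import expit

        p = ItemParams(1.7, 0.0, (0.4,))
        for th in (-2.0, -0.3, 0.0, 1.1, 3.0):
            prob = expit(p.a0 * th - p.thresholds[0])
            assert item_information(p, th) == pytest.approx(
                p.a0**2 * prob * (1 - prob), abs=1e-10
            )

    def test_nonnegative_finite_and_peaked_near_thresholds(self):
        p = ItemParams(1.6, 0.5, (-1.0, 0.0, 1.2))
        th = np.linspace(-6, 6, 601)
        info = item_information(p, th)
        assert np.all(info >= 0)
        total = np.trapezoid(info, th)
        assert np.isfinite(total) and total > 0
        peak = th[np.argmax(info)]
        assert -1.5 < peak < 1.7  # inside the thresholds region (slope metric)

    def test_bank_information_matches_per_item(self, mixed_bank):
        theta = 0.7
        series = bank_information(mixed_bank, theta)
        for iid in mixed_bank.item_ids:
            assert series[iid] == pytest.approx(
                item_information(mixed_bank.params[iid], theta), rel=1e-12
            )

    def test_marginal_not_exceeding_conditional(self, mixed_bank):
        # integrating the group factor flattens the response curves
        for iid in mixed_bank.item_ids:
            p = mixed_bank.params[iid]
            cond = item_information(p, 0.0, mode="conditional")
            marg = item_information(p, 0.0, mode="marginal")
            assert marg <= cond + 1e-12


class TestValidationAndEdgeCases:
    def test_rejects_single_item_bank(self):
        bank = Bank(
            items=[ItemSpec("i1", "s1", 2)], params={}, subdomains=("s1",)
        )
        rm = ResponseMatrix(
            np.array([[0], [1], [1]]), ["p1", "p2", "p3"], ["i1"]
        )
        with pytest.raises(ValueError, match="at least 2 items"):
            fit_bifactor(rm, bank)

    def test_rejects_item_with_single_observed_category(self):
        items = [ItemSpec("i1", "s1", 2), ItemSpec("i2", "s1", 2)]
        bank = Bank(items=items, params={}, subdomains=("s1",))
        codes = np.array([[0, 1], [0, 0], [0, 1]])
        rm = ResponseMatrix(codes, ["p1", "p2", "p3"], ["i1", "i2"])
        with pytest.raises(ValueError, match="i1"):
            fit_bifactor(rm, bank)

    def test_collapses_unobserved_category(self):
        rng = np.random.default_rng(8)
        items = [ItemSpec("i1", "s1", 4), ItemSpec("i2", "s1", 3)]
        bank = Bank(items=items, params={}, subdomains=("s1",))
        codes = np.column_stack(
            [
                rng.choice([0, 1, 3], size=120),  # category 2 never observed
                rng.integers(0, 3, size=120),
            ]
        )
        rm = ResponseMatrix(codes, [f"p{i}" for i in range(120)], ["i1", "i2"])
        res = fit_unidimensional(rm, bank, EstimationOptions(max_iter=30))
        assert res.collapsed_categories == {"i1": [2]}
        assert res.bank.item("i1").n_categories == 3

    def test_non_convergence_flagged(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=80, seed=61)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit_bifactor(
                resp,
                _uncalibrated(fixture_truth.bank),
                EstimationOptions(quadrature_points=7, max_iter=2, tol=1e-12),
            )
        assert not res.converged

    def test_missing_responses_ignored(self):
        truth = gen_bank(n_items=8, subdomain_sizes={"s1": 4, "s2": 4}, seed=44)
        resp = gen_responses(truth, n_persons=200, seed=45, missing_rate=0.15)
        res = fit_bifactor(resp, _uncalibrated(truth.bank))
        oracle = dense_marginal_loglik(resp, res.bank, n_grid=801)
        assert res.loglik == pytest.approx(oracle, rel=1e-5)

    def test_latent_state_requires_positive_se(self):
        with pytest.raises(ValueError):
            LatentState(0.0, 0.0)

    def test_marginal_loglik_requires_params(self, fixture_truth):
        resp = gen_responses(fixture_truth, n_persons=50, seed=3)
        with pytest.raises(ValueError, match="parameters"):
            marginal_loglik(resp, fixture_truth.bank.with_params({}))
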