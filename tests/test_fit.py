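import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from cellsignal import (
    BulkExpressionSet,
    FitConfig,
    GeneWeights,
    ReferenceSignalSet,
    aggregate_signals,
    align_genes,
    fit_exposures,
    intercept_only_nll,
    model_mean,
    negative_log_likelihood,
    normalize_exposures,
    poisson_log_constant,
    pseudo_r_squared,
    quantify,
)


def make_bulk(counts, lengths, genes=None, samples=None):
    counts = np.atleast_2d(np.asarray(counts, float).T).T
    m, p = counts.shape
    return BulkExpressionSet(
        fragment_counts=counts,
        effective_lengths=np.asarray(lengths, float),
        gene_ids=pd.Index(genes or [f"g{i}" for i in range(m)]),
        sample_ids=pd.Index(samples or [f"s{i}" for i in range(p)]),
    )


def make_signals(mat, genes=None):
    mat = np.atleast_2d(np.asarray(mat, float).T).T
    return ReferenceSignalSet(
        signals=mat,
        gene_ids=pd.Index(genes or [f"g{i}" for i in range(mat.shape[0])]),
        signal_ids=pd.Index([f"sig{j}" for j in range(mat.shape[1])]),
    )


from oracles import oracle_fractions


class TestAlignGenes:
    def test_identity(self):
        bulk = make_bulk([1, 2, 3], [1, 1, 1])
        sig = make_signals([0.2, 0.3, 0.5])
        b, s, w = align_genes(bulk, sig, min_genes=1)
        np.testing.assert_array_equal(b.fragment_counts, bulk.fragment_counts)
        assert list(s.gene_ids) == list(sig.gene_ids)

    def test_extra_bulk_gene_dropped(self):
        bulk = make_bulk([1, 2, 3, 4], [1, 1, 1, 1], genes=["g0", "g1", "g2", "gX"])
        sig = make_signals([0.2, 0.3, 0.5])
        b, s, _ = align_genes(bulk, sig, min_genes=1)
        assert "gX" not in b.gene_ids
        assert b.n_genes == s.n_genes == 3

    def test_disjoint_errors(self):
        bulk = make_bulk([1, 2], [1, 1], genes=["a", "b"])
        sig = make_signals([0.5, 0.5], genes=["c", "d"])
        with pytest.raises(ValueError, match="genes shared"):
            align_genes(bulk, sig, min_genes=1)


class TestModelMean:
    def test_single_signal_substitution(self):
        sig = make_signals([0.75, 0.25])
        lam = model_mean(np.log([[2.0]]), sig, np.ones((2, 1)), intercept_enabled=False)
        np.testing.assert_allclose(lam[:, 0], [1.5, 0.5])

    def test_intercept_only_flat_times_length(self):
        sig = make_signals(np.zeros((2, 0)))
        lam = model_mean(np.log([[3.0]]), sig, np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(lam[:, 0], [3.0, 6.0])

    def test_linear_in_lengths(self):
        sig = make_signals([0.6, 0.4])
        z = np.log([[1.3], [0.7]])
        l1 = np.array([[1.0], [2.0]])
        np.testing.assert_allclose(
            model_mean(z, sig, 2 * l1), 2 * model_mean(z, sig, l1)
        )


class TestNegativeLogLikelihood:
    def test_substitution(self):
        assert negative_log_likelihood(np.ones(2), np.ones(2)) == pytest.approx(2.0)

    def test_zero_weight_gene_drops_out(self):
        mean = np.array([2.0, 5.0])
        counts = np.array([1.0, 3.0])
        with_w0 = negative_log_likelihood(mean, counts, np.array([1.0, 0.0]))
        removed = negative_log_likelihood(mean[:1], counts[:1], np.array([1.0]))
        assert with_w0 == pytest.approx(removed)

    def test_minimizer_is_observed_count(self):
        # calculus oracle: d/dlam (lam - y log lam) = 0 at lam = y
        y = 7.0
        res = minimize_scalar(
            lambda lam: negative_log_likelihood([lam], [y]), bounds=(0.1, 100), method="bounded"
        )
        assert res.x == pytest.approx(y, rel=1e-4)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            negative_log_likelihood([1.0], [-1.0])
        with pytest.raises(ValueError):
            negative_log_likelihood([1.0], [1.0], np.array([-0.5]))


class TestFitExposures:
    def _noiseless_single(self, seed=0):
        rng = np.random.default_rng(seed)
        m = 120
        profiles = rng.lognormal(0, 1, (m, 2))
        profiles /= profiles.sum(0)
        lengths = rng.integers(200, 5000, m).astype(float)
        y = np.round(1e6 * profiles[:, :1] * lengths[:, None] / (profiles[:, 0] @ lengths))
        bulk = make_bulk(y, lengths)
        return bulk, make_signals(profiles)

    def test_recovers_pure_signal(self):
        bulk, sig = self._noiseless_single()
        res = normalize_exposures(fit_exposures(bulk, sig))
        frac = res.normalized_fractions.iloc[0]
        assert frac["sig0"] >= 0.95
        assert frac["unexplained"] <= 0.05
        # grid-search oracle over (beta_A, beta_0) on the single-signal model
        oracle = oracle_fractions(bulk, make_signals(sig.signals[:, :1]))
        assert oracle[0, 0] >= 0.95

    def test_flat_bulk_goes_to_unexplained(self):
        rng = np.random.default_rng(1)
        m = 100
        profiles = rng.lognormal(0, 1, (m, 2))
        profiles /= profiles.sum(0)
        lengths = np.full(m, 1000.0)
        bulk = make_bulk(np.full((m, 1), 5000.0), lengths)
        res = normalize_exposures(fit_exposures(bulk, make_signals(profiles)))
        assert res.normalized_fractions.iloc[0]["unexplained"] >= 0.95

    def test_two_signal_mixture_recovered(self):
        rng = np.random.default_rng(2)
        m = 150
        profiles = rng.lognormal(0, 1, (m, 2))
        profiles /= profiles.sum(0)
        lengths = rng.integers(200, 5000, m).astype(float)
        mix = profiles @ np.array([0.7, 0.3])
        y = np.round(1e6 * mix * lengths / (mix @ lengths))
        bulk = make_bulk(y, lengths)
        sig = make_signals(profiles)
        res = normalize_exposures(fit_exposures(bulk, sig))
        frac = res.normalized_fractions.iloc[0]
        assert frac["sig0"] == pytest.approx(0.7, abs=0.05)
        assert frac["sig1"] == pytest.approx(0.3, abs=0.05)
        # convex-solver oracle on the 3-parameter problem agrees
        oracle = oracle_fractions(bulk, sig)[0]
        np.testing.assert_allclose(frac[["sig0", "sig1"]], oracle[:2], atol=0.02)

    def test_nll_trace_monotone_and_final_not_above_initial(self):
        bulk, sig = self._noiseless_single(seed=3)
        res = fit_exposures(bulk, sig)
        assert np.all(np.diff(res.nll_trace) <= 0)
        assert res.converged

    def test_scale_invariance(self):
        bulk, sig = self._noiseless_single(seed=4)
        res1 = normalize_exposures(fit_exposures(bulk, sig))
        k = 3.7
        bulk2 = make_bulk(bulk.fragment_counts * k, bulk.effective_lengths[:, 0])
        res2 = normalize_exposures(fit_exposures(bulk2, sig))
        ratio = res2.exposures / res1.exposures
        big = res1.normalized_fractions.iloc[0].to_numpy() > 0.01
        np.testing.assert_allclose(ratio[big, 0], k, rtol=0.05)
        np.testing.assert_allclose(
            res1.normalized_fractions, res2.normalized_fractions, atol=0.01
        )

    def test_unaligned_inputs_rejected(self):
        bulk = make_bulk([1, 2], [1, 1], genes=["a", "b"])
        sig = make_signals([0.5, 0.5], genes=["b", "a"])
        with pytest.raises(ValueError, match="align"):
            fit_exposures(bulk, sig)

    def test_intercept_absorbs_unmatched_population(self):
        # adding counts from a population absent from the reference raises the
        # unexplained fraction, and the intercept model perturbs the matched
        # signal's exposure less than the same model without an intercept
        rng = np.random.default_rng(5)
        m = 200
        profiles = rng.lognormal(0, 1, (m, 2))
        profiles /= profiles.sum(0)
        lengths = np.full(m, 1000.0)
        sig = make_signals(profiles[:, :1])
        depth = 1e6

        def fit_one(mix_b, intercept):
            mix = (1 - mix_b) * profiles[:, 0] + mix_b * profiles[:, 1]
            y = np.round(depth * mix * lengths / (mix @ lengths))
            config = FitConfig(intercept_enabled=intercept)
            res = normalize_exposures(
                fit_exposures(make_bulk(y, lengths), sig, config=config)
            )
            return res

        f0 = fit_one(0.0, True).normalized_fractions.iloc[0]
        f1 = fit_one(0.3, True).normalized_fractions.iloc[0]
        assert f1["unexplained"] > f0["unexplained"] + 0.1
        # no-intercept model must dump the unmatched mass onto the one signal:
        # its raw exposure inflates more than the intercept model's does
        b_int_0 = fit_one(0.0, True).exposures[0, 0]
        b_int_1 = fit_one(0.3, True).exposures[0, 0]
        b_no_1 = fit_one(0.3, False).exposures[0, 0]
        assert b_int_1 - b_int_0 < b_no_1 - b_int_0


class TestNormalizeExposures:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        profiles = rng.lognormal(0, 1, (80, 2))
        profiles /= profiles.sum(0)
        y = rng.poisson(50, (80, 3)).astype(float)
        res = normalize_exposures(
            fit_exposures(make_bulk(y, np.ones(80)), make_signals(profiles))
        )
        np.testing.assert_allclose(
            res.normalized_fractions.sum(axis=1), 1.0, atol=1e-9
        )
        assert (res.normalized_fractions.to_numpy() >= 0).all()

    def test_intercept_disabled_normalizes_over_signals(self):
        rng = np.random.default_rng(7)
        profiles = rng.lognormal(0, 1, (60, 2))
        profiles /= profiles.sum(0)
        y = rng.poisson(40, (60, 2)).astype(float)
        config = FitConfig(intercept_enabled=False)
        res = normalize_exposures(
            fit_exposures(make_bulk(y, np.ones(60)), make_signals(profiles), config=config)
        )
        assert list(res.normalized_fractions.columns) == ["sig0", "sig1"]
        np.testing.assert_allclose(res.normalized_fractions.sum(axis=1), 1.0)

    def test_flat_equivalent_rescaling(self):
        # a pure-flat bulk splits 50:50 between a flat reference signal and
        # the intercept only if the intercept is rescaled to m * beta_0
        m = 50
        flat = np.full((m, 1), 1.0 / m)
        y = np.full((m, 1), 100.0)
        res = normalize_exposures(fit_exposures(make_bulk(y, np.ones(m)), make_signals(flat)))
        frac = res.normalized_fractions.iloc[0]
        assert frac["sig0"] + frac["unexplained"] == pytest.approx(1.0)
        assert res.intercept_rescaled[0] == pytest.approx(
            res.intercept_raw[0] * m
        )


class TestInterceptOnly:
    def test_closed_form_example(self):
        bulk = make_bulk([2, 2], [1, 1])
        nll = intercept_only_nll(bulk)
        assert nll[0] == pytest.approx(2 * (2 - 2 * np.log(2)), abs=1e-12)

    def test_all_zero_counts(self):
        bulk = make_bulk([0, 0], [1, 1])
        assert intercept_only_nll(bulk)[0] == pytest.approx(0.0)

    def test_closed_form_matches_grid_and_gradient_fit(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(30, (40, 1)).astype(float)
        lengths = rng.integers(100, 2000, 40).astype(float)
        bulk = make_bulk(y, lengths)
        closed = intercept_only_nll(bulk)[0]
        res = minimize_scalar(
            lambda b: float(np.sum(b * lengths - y[:, 0] * np.log(np.maximum(b * lengths, 1e-10)))),
            bounds=(1e-6, 10), method="bounded",
        )
        assert closed == pytest.approx(res.fun, rel=1e-6)
        # gradient route: fit with an empty signal set, intercept only
        empty = make_signals(np.zeros((40, 0)))
        grad = fit_exposures(bulk, empty)
        assert grad.nll_full[0] == pytest.approx(closed, rel=1e-4)


class TestPseudoRSquared:
    def test_identity_and_arithmetic(self):
        assert pseudo_r_squared([4.0], [4.0])[0] == pytest.approx(0.0)
        assert pseudo_r_squared([2.0], [4.0])[0] == pytest.approx(0.5)

    def test_zero_intercept_nll_is_missing(self):
        with pytest.warns(UserWarning):
            out = pseudo_r_squared([1.0], [0.0])
        assert np.isnan(out[0])

    def test_nested_fit_in_unit_interval(self):
        rng = np.random.default_rng(9)
        profiles = rng.lognormal(0, 1, (100, 3))
        profiles /= profiles.sum(0)
        mix = profiles @ rng.dirichlet(np.ones(3), size=20).T
        lengths = rng.integers(200, 3000, 100).astype(float)
        y = rng.poisson(1e5 * mix * lengths[:, None] / (mix * lengths[:, None]).sum(0))
        bulk = make_bulk(y.astype(float), lengths)
        res = quantify(bulk, make_signals(profiles))
        assert np.all(res.pseudo_r2 >= 0)
        assert np.all(res.pseudo_r2 <= 1)

    def test_full_nll_constant_restores_true_likelihood(self):
        bulk = make_bulk([3, 1], [1, 1])
        const = poisson_log_constant(bulk)
        from scipy.stats import poisson

        exact = -np.log(poisson.pmf(3, 2.0)) - np.log(poisson.pmf(1, 2.0))
        raw = negative_log_likelihood(np.full(2, 2.0), bulk.fragment_counts[:, 0])
        assert raw + const[0] == pytest.approx(exact)


class TestAggregateSignals:
    def _fitted(self):
        rng = np.random.default_rng(10)
        profiles = rng.lognormal(0, 1, (60, 3))
        profiles /= profiles.sum(0)
        y = rng.poisson(60, (60, 2)).astype(float)
        return normalize_exposures(
            fit_exposures(make_bulk(y, np.ones(60)), make_signals(profiles))
        )

    def test_identity_grouping(self):
        res = self._fitted()
        out = aggregate_signals(res, {s: s for s in res.signal_ids})
        np.testing.assert_allclose(
            out[res.normalized_fractions.columns], res.normalized_fractions
        )

    def test_all_in_one_group_conserves_mass(self):
        res = self._fitted()
        out = aggregate_signals(res, {s: "all" for s in res.signal_ids})
        np.testing.assert_allclose(
            out["all"], 1.0 - res.normalized_fractions["unexplained"]
        )

    def test_pairwise_addition(self):
        res = self._fitted()
        out = aggregate_signals(res, {"sig0": "endo", "sig1": "endo", "sig2": "other"})
        np.testing.assert_allclose(
            out["endo"],
            res.normalized_fractions["sig0"] + res.normalized_fractions["sig1"],
        )

    def test_unassigned_signal_errors(self):
        res = self._fitted()
        with pytest.raises(ValueError, match="without a group"):
            aggregate_signals(res, {"sig0": "a"})
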