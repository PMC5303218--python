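"""The variance-components engine: likelihood, ML fit, LRT, heritability,
missingness clustering and the pairwise scan."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2, multivariate_normal

from famassoc.pedigree import kinship
from famassoc.phenotype import PhenotypeTable
from famassoc.relatedness import RelatednessMatrix
from famassoc.simulate import SimulationConfig, simulate_families, simulate_traits
from famassoc.vc import (
    AssocOptions,
    CollinearityError,
    ModelSpec,
    cluster_by_missingness,
    fit_ml,
    heritability,
    loglikelihood,
    lrt_association,
    run_association_scan,
)


def _spec(y, X, ids, predictor=None, covariates=(), response="y"):
    names = ["(intercept)"]
    if predictor:
        names.append(predictor)
    names.extend(covariates)
    return ModelSpec(
        response=response, predictor=predictor, covariates=tuple(covariates),
        individuals=list(ids), y=np.asarray(y, float), X=np.asarray(X, float),
        column_names=tuple(names),
    )


def _identity_rel(n, prefix="i"):
    ids = [f"{prefix}{k}" for k in range(n)]
    return RelatednessMatrix(ids=ids, values=np.eye(n), source="gsm")


class TestLoglikelihood:
    def test_single_founder_standard_normal_at_mean(self):
        rel = _identity_rel(1)
        spec = _spec([1.7], [[1.0]], rel.ids)
        ll = loglikelihood(spec, {"mu": 1.7, "sigma2_a": 0.0, "sigma2_e": 1.0}, rel)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_unrelated_collapses_to_iid_normal(self):
        rng = np.random.default_rng(0)
        n = 12
        rel = _identity_rel(n)
        y = rng.standard_normal(n)
        spec = _spec(y, np.ones((n, 1)), rel.ids)
        theta = {"mu": 0.3, "sigma2_a": 0.7, "sigma2_e": 0.5}
        ll = loglikelihood(spec, theta, rel)
        var = 1.2
        expected = float(
            np.sum(-0.5 * (np.log(2 * np.pi * var) + (y - 0.3) ** 2 / var))
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_family_matches_dense_inverse_oracle(self):
        ped = simulate_families(1)
        rel = kinship(ped)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(8)
        spec = _spec(y, np.ones((8, 1)), rel.ids)
        theta = {"mu": 0.1, "sigma2_a": 0.4, "sigma2_e": 0.6}
        ll = loglikelihood(spec, theta, rel)
        omega = 0.4 * rel.values + 0.6 * np.eye(8)
        resid = y - 0.1
        oracle = (
            -0.5 * (8 * np.log(2 * np.pi) + np.log(np.linalg.det(omega))
                    + resid @ np.linalg.inv(omega) @ resid)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)
        # also agrees with scipy's multivariate normal density
        assert ll == pytest.approx(
            multivariate_normal.logpdf(y, mean=np.full(8, 0.1), cov=omega), abs=1e-8
        )

    def test_degenerate_covariance_rejected(self):
        rel = _identity_rel(3)
        spec = _spec([0.0, 1.0, 2.0], np.ones((3, 1)), rel.ids)
        with pytest.raises(ValueError, match="degenerate"):
            loglikelihood(spec, {"mu": 0.0, "sigma2_a": 0.0, "sigma2_e": 0.0}, rel)


def _brute_force_ml(y, X, K, n_starts=10, seed=0):
    """Derivative-free joint optimization over (fixed effects, log-variances):
    an independent oracle for the profile fit."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    best = -np.inf

    def negll(theta):
        coef = theta[:p]
        s2a, s2e = np.exp(theta[p]), np.exp(theta[p + 1])
        omega = s2a * K + s2e * np.eye(n)
        try:
            return -multivariate_normal.logpdf(y, mean=X @ coef, cov=omega)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    for _ in range(n_starts):
        x0 = np.concatenate([rng.normal(0, 1, p), rng.normal(-1, 1.5, 2)])
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        best = max(best, -res.fun)
    return best


class TestFitML:
    def test_matches_brute_force_joint_optimization(self, small_families):
        ped, rel, responses, predictors = small_families
        spec = ModelSpec.from_tables(
            "resp1", responses, rel, predictor="pred1", predictors=predictors
        )
        # restrict to three families (24 individuals) for the dense oracle
        sub_ids = spec.individuals[:24]
        keep = [spec.individuals.index(i) for i in sub_ids]
        spec_small = _spec(spec.y[keep], spec.X[keep], sub_ids, predictor="pred1")
        fit = fit_ml(spec_small, rel)
        K = rel.subset(sub_ids).values
        oracle = _brute_force_ml(spec_small.y, spec_small.X, K)
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)
        assert fit.loglik >= oracle - 1e-4

    def test_profile_dominates_h_grid(self, small_families):
        ped, rel, responses, predictors = small_families
        spec = ModelSpec.from_tables(
            "resp1", responses, rel, predictor="pred1", predictors=predictors
        )
        fit = fit_ml(spec, rel)
        K = rel.subset(spec.individuals).values
        d, U = np.linalg.eigh(K)
        y_rot, X_rot = U.T @ spec.y, U.T @ spec.X
        n = spec.n
        for h in np.linspace(0, 1, 101):
            w = h * d + (1 - h)
            if w.min() <= 0:
                continue
            sw = 1 / np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X_rot * sw[:, None], y_rot * sw, rcond=None)
            rss = float(np.sum(((y_rot - X_rot @ coef) * sw) ** 2))
            ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(rss / n)
                         + np.log(w).sum() + n)
            assert fit.loglik >= ll - 1e-6

    def test_unrelated_noise_fits_at_the_boundary(self, identity_dataset):
        rel, responses, predictors = identity_dataset
        spec = ModelSpec.from_tables(
            "y", responses, rel, predictor="x0", predictors=predictors
        )
        fit = fit_ml(spec, rel)
        assert fit.h == 0.0
        assert not fit.h2_identifiable
        # beta equals the OLS estimate
        ols = np.linalg.lstsq(spec.X, spec.y, rcond=None)[0][1]
        assert fit.beta == pytest.approx(ols, abs=1e-10)

    def test_h2_invariant_to_affine_response_rescaling(self, small_families):
        ped, rel, responses, predictors = small_families
        spec = ModelSpec.from_tables("resp1", responses, rel)
        fit = fit_ml(spec, rel)
        spec2 = _spec(3.5 * spec.y - 11.0, spec.X, spec.individuals)
        fit2 = fit_ml(spec2, rel)
        assert fit2.h == pytest.approx(fit.h, abs=1e-8)

    def test_rank_deficient_design_names_the_column(self, small_families):
        ped, rel, responses, predictors = small_families
        spec = ModelSpec.from_tables(
            "resp1", responses, rel, predictor="pred1", predictors=predictors
        )
        X = spec.X.copy()
        X[:, 1] = 2.0  # constant predictor, collinear with intercept
        bad = _spec(spec.y, X, spec.individuals, predictor="pred1")
        with pytest.raises(CollinearityError, match="pred1"):
            fit_ml(bad, rel)

    def test_minimum_sample_size_enforced(self):
        rel = _identity_rel(2)
        spec = _spec([0.0, 1.0], np.ones((2, 1)), rel.ids)
        with pytest.raises(ValueError, match="at least 3"):
            fit_ml(spec, rel)


class TestLRT:
    def test_chi_square_critical_value(self):
        assert chi2.sf(3.841459, 1) == pytest.approx(0.05, abs=5e-6)

    def test_null_beta_gives_zero_statistic(self, identity_dataset):
        rel, responses, predictors = identity_dataset
        spec = ModelSpec.from_tables(
            "y", responses, rel, predictor="x0", predictors=predictors
        )
        # orthogonalize the predictor against y: beta-hat exactly 0
        y = spec.y - spec.y.mean()
        x = spec.X[:, 1] - spec.X[:, 1].mean()
        x = x - (x @ y) / (y @ y) * y
        X = np.column_stack([np.ones(spec.n), x])
        alt = fit_ml(_spec(y, X, spec.individuals, predictor="x0"), rel)
        null = fit_ml(_spec(y, np.ones((spec.n, 1)), spec.individuals), rel)
        lrt, p = lrt_association(null, alt)
        assert alt.beta == pytest.approx(0.0, abs=1e-12)
        assert lrt == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_iid_reduction_matches_ols_lrt(self, identity_dataset):
        statsmodels = pytest.importorskip("statsmodels.api")
        rel, responses, predictors = identity_dataset
        for pred in predictors.variables:
            spec = ModelSpec.from_tables(
                "y", responses, rel, predictor=pred, predictors=predictors
            )
            alt = fit_ml(spec, rel)
            null = fit_ml(spec.drop_predictor(), rel)
            lrt, p = lrt_association(null, alt)
            m1 = statsmodels.OLS(spec.y, spec.X).fit()
            m0 = statsmodels.OLS(spec.y, spec.X[:, [0]]).fit()
            lrt_ols = 2 * (m1.llf - m0.llf)
            assert lrt == pytest.approx(lrt_ols, abs=1e-8)
            assert p == pytest.approx(chi2.sf(lrt_ols, 1), abs=1e-6)

    def test_mismatched_individuals_rejected(self, identity_dataset):
        rel, responses, predictors = identity_dataset
        spec = ModelSpec.from_tables(
            "y", responses, rel, predictor="x0", predictors=predictors
        )
        alt = fit_ml(spec, rel)
        short = _spec(spec.y[:-1], np.ones((spec.n - 1, 1)), spec.individuals[:-1])
        null = fit_ml(short, rel)
        with pytest.raises(ValueError, match="different individuals"):
            lrt_association(null, alt)


class TestHeritability:
    def test_unrelated_sample_is_flagged_unidentifiable(self, identity_dataset):
        rel, responses, predictors = identity_dataset
        spec = ModelSpec.from_tables("y", responses, rel)
        h2, lrt, p = heritability(spec, rel)
        assert h2 is None
        assert lrt == 0.0
        assert p == 1.0

    def test_zero_statistic_gives_mixture_mass_half(self, small_families):
        ped, rel, responses, predictors = small_families
        # a trait that is pure noise: fitted sigma2_a typically at boundary
        rng = np.random.default_rng(42)
        noise = PhenotypeTable(
            pd.DataFrame({"noise": rng.standard_normal(rel.n)}, index=rel.ids)
        )
        spec = ModelSpec.from_tables("noise", noise, rel)
        h2, lrt, p = heritability(spec, rel)
        if lrt == 0.0:
            assert p == 0.5
        else:
            assert p == pytest.approx(0.5 * chi2.sf(lrt, 1), abs=1e-12)

    def test_recovers_simulated_heritability_in_expectation(self):
        # 40 replicate traits on 50 families; mean h2-hat near truth
        config = SimulationConfig(n_families=50, h2=0.5, n_responses=40, seed=21)
        ped = simulate_families(config)
        rel = kinship(ped)
        responses, _ = simulate_traits(ped, config)
        ests = []
        for resp in responses.variables:
            spec = ModelSpec.from_tables(resp, responses, rel)
            h2, _, _ = heritability(spec, rel)
            ests.append(h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.06)


class TestMissingnessClustering:
    def test_complete_data_forms_single_cluster(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 5)))
        clusters = cluster_by_missingness(df, np.ones(10, bool))
        assert len(clusters) == 1
        assert clusters[0].predictor_ids == list(df.columns)

    def test_distinct_masks_split_clusters(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((6, 3)),
                          columns=["a", "b", "c"])
        df.loc[0, "a"] = np.nan
        df.loc[0, "b"] = np.nan
        df.loc[3, "c"] = np.nan
        clusters = cluster_by_missingness(df, np.ones(6, bool))
        assert len(clusters) == 2
        by_members = {tuple(c.predictor_ids) for c in clusters}
        assert by_members == {("a", "b"), ("c",)}

    def test_response_mask_is_merged_into_the_key(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((6, 2)),
                          columns=["a", "b"])
        df.loc[1, "a"] = np.nan
        base = np.ones(6, bool)
        base[1] = False  # response missing where a is missing anyway
        clusters = cluster_by_missingness(df, base)
        assert len(clusters) == 1

    def test_scan_identical_with_clustering_on_and_off(self):
        config = SimulationConfig(
            n_families=12, h2=0.3, n_predictors=30, missing_rate=0.05,
            n_shared_masks=4, seed=5,
        )
        ped = simulate_families(config)
        rel = kinship(ped)
        responses, predictors = simulate_traits(ped, config)
        on = run_association_scan(
            responses, predictors, rel,
            options=AssocOptions(family_diagnostics=False),
        )
        off = run_association_scan(
            responses, predictors, rel,
            options=AssocOptions(family_diagnostics=False,
                                 use_missingness_clustering=False),
        )
        assert len(on) == len(off) == 30
        for a, b in zip(on, off):
            assert (a.response, a.predictor) == (b.response, b.predictor)
            # bitwise identical: same decomposition and arithmetic path
            assert a.beta == b.beta
            assert a.lrt == b.lrt
            assert a.p == b.p


class TestScan:
    def test_single_pair_gives_single_result(self, identity_dataset):
        rel, responses, predictors = identity_dataset
        single = PhenotypeTable(predictors.data[["x0"]])
        res = run_association_scan(responses, single, rel,
                                   options=AssocOptions(min_n=10))
        assert len(res) == 1
        assert res[0].response == "y" and res[0].predictor == "x0"

    def test_predictor_order_only_permutes_results(self, small_families):
        ped, rel, responses, predictors = small_families
        opts = AssocOptions(family_diagnostics=False)
        res = run_association_scan(responses, predictors, rel, options=opts)
        flipped = PhenotypeTable(predictors.data[predictors.variables[::-1]])
        res2 = run_association_scan(responses, flipped, rel, options=opts)
        lookup = {r.predictor: r for r in res2}
        for r in res:
            assert lookup[r.predictor].lrt == r.lrt

    def test_constant_predictor_is_skipped_not_fatal(self, small_families):
        ped, rel, responses, predictors = small_families
        df = predictors.data.copy()
        df["flat"] = 1.0
        res = run_association_scan(responses, PhenotypeTable(df), rel,
                                   options=AssocOptions(family_diagnostics=False))
        flat = [r for r in res if r.predictor == "flat"]
        assert len(flat) == 1 and flat[0].skipped

    def test_small_overlap_is_skipped_with_reason(self, small_families):
        ped, rel, responses, predictors = small_families
        df = predictors.data.copy()
        df["rare"] = np.nan
        df.iloc[:5, df.columns.get_loc("rare")] = 1.0 + np.arange(5.0)
        res = run_association_scan(responses, PhenotypeTable(df), rel,
                                   options=AssocOptions(family_diagnostics=False))
        rare = [r for r in res if r.predictor == "rare"][0]
        assert rare.skipped and "below minimum" in rare.skip_reason

    def test_alternative_never_fits_worse_than_null(self, small_families):
        """Likelihood monotonicity: lrt >= 0 on every tested pair."""
        ped, rel, responses, predictors = small_families
        res = run_association_scan(responses, predictors, rel,
                                   options=AssocOptions(family_diagnostics=False))
        assert all(r.lrt >= 0.0 for r in res if not r.skipped)
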