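"""Mixed-model scan: oracles, calibration, invariances, DMR calling."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from dmrclock import (
    MethylomeMatrix,
    RegionEWAS,
    SimulationConfig,
    bonferroni_threshold,
    fit_region_mixed_model,
    simulate_dataset,
)
from dmrclock.ewas import DmrSet

from conftest import make_longevity, make_matrix, make_samples


class TestBonferroni:
    def test_simple_values(self):
        assert bonferroni_threshold(1, 0.05) == 0.05
        assert bonferroni_threshold(10, 0.10) == pytest.approx(0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 1.5)


class TestSingleRegionFit:
    def test_constant_response_is_degenerate(self):
        samples = make_samples(12)
        longevity = make_longevity(samples)
        row = fit_region_mixed_model(np.full(12, 3.7), samples, longevity)
        assert row["beta_age"] == 0 and row["p_age"] == 1.0
        assert row["degenerate"]

    def test_matches_ols_in_zero_group_variance_limit(self):
        """Data with no group effect: REML hits the lambda = 0 boundary and
        the fit reduces exactly to ordinary least squares."""
        samples = make_samples(60, n_groups=6, seed=1)
        longevity = make_longevity(samples)
        med = longevity.stat_for_samples(samples, "median").to_numpy()
        X = np.column_stack(
            [np.ones(60), samples.df["age_days"], samples.df["bw0_g"], med]
        )
        beta_true = np.array([0.5, 0.002, -0.01, 0.0005])
        found = False
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = X @ beta_true + rng.normal(0, 0.1, 60)
            row = fit_region_mixed_model(y, samples, longevity)
            if row["group_var"] == 0:  # boundary case: the stated limit
                found = True
                ols = sm.OLS(y, X).fit()
                np.testing.assert_allclose(
                    [row["beta_age"], row["beta_bw0"], row["beta_ls"]],
                    ols.params[1:], atol=1e-6,
                )
                np.testing.assert_allclose(
                    [row["se_age"], row["se_bw0"], row["se_ls"]],
                    ols.bse[1:], atol=1e-6,
                )
        assert found, "no replicate hit the zero-variance boundary"

    def test_matches_statsmodels_mixedlm(self, small_cohort, small_ewas):
        """Independent mixed-model oracle on a handful of regions."""
        sdf = small_cohort.samples.df.copy()
        sdf["median_ls"] = small_cohort.longevity.stat_for_samples(
            small_cohort.samples, "median"
        ).to_numpy()
        sdf["group"] = small_cohort.samples.group_labels().to_numpy()
        rng = np.random.default_rng(0)
        checked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rid in rng.choice(small_cohort.methylome.region_ids, 12, replace=False):
                sdf["y"] = small_cohort.methylome.df.loc[rid].to_numpy()
                m = smf.mixedlm(
                    "y ~ age_days + bw0_g + median_ls", sdf, groups=sdf["group"]
                ).fit(reml=True)
                if not m.converged:
                    continue
                row = small_ewas.table.loc[rid]
                ours = np.array([row["beta_age"], row["beta_bw0"], row["beta_ls"]])
                theirs = np.array(
                    [m.params["age_days"], m.params["bw0_g"], m.params["median_ls"]]
                )
                ses = np.array([row["se_age"], row["se_bw0"], row["se_ls"]])
                # agree to 0.2% or to a thousandth of a standard error
                assert (
                    np.abs(ours - theirs) <= 2e-3 * np.abs(theirs) + 1e-3 * ses
                ).all(), (rid, ours, theirs)
                # variance components agree with the oracle's REML optimum
                np.testing.assert_allclose(
                    [row["group_var"], row["resid_var"]],
                    [m.cov_re.iloc[0, 0], m.scale], rtol=5e-3, atol=1e-6,
                )
                # SEs follow the GLS convention sqrt(diag((X'V^-1 X)^-1)),
                # recomputed here with dense matrices as an independent oracle
                X = np.column_stack(
                    [np.ones(len(sdf)), sdf["age_days"], sdf["bw0_g"],
                     sdf["median_ls"]]
                )
                _, ginv = np.unique(sdf["group"], return_inverse=True)
                Z = np.eye(ginv.max() + 1)[ginv]
                V = row["resid_var"] * np.eye(len(sdf)) + row["group_var"] * (Z @ Z.T)
                cov = np.linalg.inv(X.T @ np.linalg.solve(V, X))
                np.testing.assert_allclose(
                    [row["se_age"], row["se_bw0"], row["se_ls"]],
                    np.sqrt(np.diag(cov))[1:], rtol=1e-6,
                )
                checked += 1
        assert checked >= 8

    def test_wald_interval_coverage(self):
        """Planted beta_age falls in its 95% Wald CI in >= 93% of replicates."""
        samples = make_samples(40, n_groups=8, seed=2)
        longevity = make_longevity(samples)
        med = longevity.stat_for_samples(samples, "median").to_numpy()
        groups = samples.group_labels().to_numpy()
        _, ginv = np.unique(groups, return_inverse=True)
        beta_age = 0.002
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            u = rng.normal(0, 0.08, 8)
            y = (
                0.5
                + beta_age * samples.df["age_days"].to_numpy()
                + u[ginv]
                + rng.normal(0, 0.05, 40)
            )
            row = fit_region_mixed_model(y, samples, longevity)
            lo = row["beta_age"] - 1.96 * row["se_age"]
            hi = row["beta_age"] + 1.96 * row["se_age"]
            hits += lo <= beta_age <= hi
        assert hits / n_rep >= 0.93

    def test_single_group_rejected(self):
        samples = make_samples(8, n_groups=1)
        longevity = make_longevity(samples)
        with pytest.raises(ValueError, match="group"):
            fit_region_mixed_model(np.random.default_rng(0).normal(size=8),
                                   samples, longevity)


class TestScan:
    def test_null_age_p_uniform(self):
        cfg = SimulationConfig(
            n_regions=400, frac_age_dmr=0.0, frac_bw_dmr=0.0, frac_ls_dmr=0.0,
            ls_aging_coupling_days=0.0, hfd_aging_boost_days=0.0,
        )
        cohort = simulate_dataset(cfg, seed=21)
        res = RegionEWAS(cohort.methylome, cohort.samples, cohort.longevity).fit()
        assert sps.kstest(res.table["p_age"], "uniform").pvalue > 0.01

    def test_duplicated_region_gives_identical_rows(self, small_cohort):
        df = small_cohort.methylome.df.iloc[:5].copy()
        dup = df.iloc[[0]].rename(index={df.index[0]: "copy"})
        mat = MethylomeMatrix(pd.concat([df, dup]))
        res = RegionEWAS(mat, small_cohort.samples, small_cohort.longevity).fit()
        pd.testing.assert_series_equal(
            res.table.iloc[0], res.table.loc["copy"], check_names=False
        )

    def test_region_order_invariance(self, small_cohort, small_ewas):
        shuffled = MethylomeMatrix(
            small_cohort.methylome.df.sample(frac=1, random_state=3)
        )
        res2 = RegionEWAS(
            shuffled, small_cohort.samples, small_cohort.longevity
        ).fit()
        pd.testing.assert_frame_equal(
            res2.table.sort_index(), small_ewas.table.sort_index()
        )

    def test_affine_invariance_of_betas_and_pvalues(self, small_cohort, small_ewas):
        df = small_cohort.methylome.df.copy()
        rid = df.index[7]
        df.loc[rid] = df.loc[rid] + 5.0
        res2 = RegionEWAS(
            MethylomeMatrix(df), small_cohort.samples, small_cohort.longevity
        ).fit()
        for col in ("beta_age", "p_age", "beta_bw0", "p_bw0", "beta_ls", "p_ls"):
            assert res2.table.loc[rid, col] == pytest.approx(
                small_ewas.table.loc[rid, col], abs=1e-8
            )

    def test_planted_age_dmr_recovery(self, small_cohort, small_ewas):
        truth = small_cohort.truth.regions.set_index("region_id")
        planted = set(truth.index[truth["is_age_dmr"]])
        called = set(small_ewas.call_dmrs("age", 1e-4).region_ids)
        assert len(planted & called) / len(planted) >= 0.8

    def test_satterthwaite_p_at_least_wald(self, small_cohort):
        """t-based p-values are never smaller than the normal approximation."""
        sub = MethylomeMatrix(small_cohort.methylome.df.iloc[:30])
        wald = RegionEWAS(sub, small_cohort.samples, small_cohort.longevity).fit()
        satt = RegionEWAS(sub, small_cohort.samples, small_cohort.longevity).fit(
            df_method="satterthwaite"
        )
        assert (satt.table["p_age"] >= wald.table["p_age"] - 1e-12).all()
        np.testing.assert_allclose(
            satt.table["beta_age"], wald.table["beta_age"], atol=1e-12
        )


class TestDmrCalling:
    def _results(self, pvals):
        table = pd.DataFrame(
            {
                "beta_age": [1.0, -2.0, 3.0], "se_age": [0.1] * 3, "p_age": pvals,
                "beta_bw0": [0.0] * 3, "se_bw0": [0.1] * 3, "p_bw0": [1.0] * 3,
                "beta_ls": [0.0] * 3, "se_ls": [0.1] * 3, "p_ls": [1.0] * 3,
                "region_mean": [0.0] * 3, "group_var": [0.0] * 3,
                "resid_var": [1.0] * 3, "converged": [True] * 3,
                "degenerate": [False] * 3,
            },
            index=pd.Index(["rA", "rB", "rC"], name="region_id"),
        )
        from dmrclock.ewas import EwasResults

        return EwasResults(table, n_samples=10, n_groups=3)

    def test_threshold_filtering(self):
        res = self._results([1e-8, 1e-5, 1e-3])
        dmrs = res.call_dmrs("age", 1e-4)
        assert len(dmrs) == 2
        assert dmrs.region_ids == ["rA", "rB"]  # sorted by p
        assert list(dmrs.df["direction"]) == ["+", "-"]

    def test_zero_threshold_empty(self):
        res = self._results([1e-8, 1e-5, 1e-3])
        assert len(res.call_dmrs("age", 0.0)) == 0

    def test_dmrset_invariant_enforced(self):
        with pytest.raises(ValueError, match="threshold"):
            DmrSet(
                trait="age",
                threshold_p=1e-6,
                df=pd.DataFrame(
                    {"region_id": ["r0"], "beta": [1.0], "p": [0.5],
                     "direction": ["+"]}
                ),
            )

    def test_matches_independent_filter(self, small_ewas):
        dmrs = small_ewas.call_dmrs("BW0", 1e-3)
        expected = {
            rid
            for rid, p in small_ewas.table["p_bw0"].items()
            if p <= 1e-3
        }
        assert set(dmrs.region_ids) == expected
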