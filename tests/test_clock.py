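"""DMRmAge clock: scaling identities, acceleration, associations, validation."""

import numpy as np
import pandas as pd
import pytest

from dmrclock import (
    AccelerationResult,
    ClockModel,
    DmrClock,
    MethylomeMatrix,
    RegionEWAS,
    SimulationConfig,
    age_acceleration,
    clock_associations,
    fit_clock,
    predict_age,
    simulate_dataset,
    split_validate,
)
from dmrclock.ewas import DmrSet, EwasResults

from conftest import make_longevity, make_matrix, make_samples


def _toy_clock_inputs(values, weights, ages, n_groups=2):
    """Matrix + DmrSet + EwasResults + SampleTable for a hand-built clock."""
    values = np.asarray(values, float)
    n_regions, n_samples = values.shape
    region_ids = [f"r{i}" for i in range(n_regions)]
    samples = make_samples(n_samples, n_groups=n_groups, ages=ages)
    matrix = make_matrix(values, region_ids=region_ids,
                         sample_ids=samples.sample_ids)
    dmrs = DmrSet(
        trait="age", threshold_p=1e-4,
        df=pd.DataFrame(
            {"region_id": region_ids, "beta": weights,
             "p": [1e-6] * n_regions,
             "direction": ["+" if w >= 0 else "-" for w in weights]}
        ),
    )
    cols = {
        "se_age": 0.1, "p_age": 1e-6,
        "beta_bw0": 0.0, "se_bw0": 0.1, "p_bw0": 1.0,
        "beta_ls": 0.0, "se_ls": 0.1, "p_ls": 1.0,
        "region_mean": 0.0, "group_var": 0.0, "resid_var": 1.0,
    }
    table = pd.DataFrame(cols, index=pd.Index(region_ids, name="region_id"))
    table.insert(0, "beta_age", weights)
    table["converged"] = True
    table["degenerate"] = False
    ewas = EwasResults(table, n_samples=n_samples, n_groups=n_groups)
    return matrix, dmrs, ewas, samples


class TestClockScaling:
    def test_training_endpoints_map_to_age_range(self):
        ages = [181.0, 400.0, 759.0]
        matrix, dmrs, ewas, samples = _toy_clock_inputs(
            [[0.1, 0.5, 0.9]], [1.0], ages
        )
        model = fit_clock(matrix, dmrs, ewas, samples)
        assert model.min_age_days == 181.0
        assert model.age_range_days == 578.0
        pred = predict_age(model, matrix)
        assert pred.min() == pytest.approx(181.0, abs=1e-9)
        assert pred.max() == pytest.approx(759.0, abs=1e-9)

    def test_single_region_weight_one_sum_is_that_region(self):
        values = [[0.3, 0.6, 0.2, 0.8]]
        matrix, dmrs, ewas, samples = _toy_clock_inputs(
            values, [1.0], [200.0, 400.0, 300.0, 700.0]
        )
        model = fit_clock(matrix, dmrs, ewas, samples)
        # prediction ordering must follow that single region's values
        pred = predict_age(model, matrix)
        assert list(np.argsort(pred.to_numpy())) == list(np.argsort(values[0]))

    def test_weight_rescaling_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 8))
        weights = rng.normal(size=5)
        ages = rng.uniform(200, 700, 8)
        matrix, dmrs, ewas, samples = _toy_clock_inputs(values, weights, ages)
        base = predict_age(fit_clock(matrix, dmrs, ewas, samples), matrix)
        for c in (0.01, 3.0, 250.0):
            table2 = ewas.table.copy()
            table2["beta_age"] = weights * c
            ewas2 = EwasResults(table2, ewas.n_samples, ewas.n_groups)
            scaled = predict_age(fit_clock(matrix, dmrs, ewas2, samples), matrix)
            np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_constant_shift_of_weighted_sums_absorbed(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 6))
        weights = np.array([0.5, -1.0, 2.0, 1.5])
        ages = rng.uniform(200, 700, 6)
        matrix, dmrs, ewas, samples = _toy_clock_inputs(values, weights, ages)
        base = predict_age(fit_clock(matrix, dmrs, ewas, samples), matrix)
        # shift one clock region by a constant: every weighted sum moves by
        # weight * constant, which the min/range scaling absorbs
        shifted = values.copy()
        shifted[2] += 7.0
        matrix2 = make_matrix(shifted, region_ids=matrix.region_ids,
                              sample_ids=matrix.sample_ids)
        pred2 = predict_age(fit_clock(matrix2, dmrs, ewas, samples), matrix2)
        np.testing.assert_allclose(pred2, base, atol=1e-6)

    def test_zero_range_rejected(self):
        matrix, dmrs, ewas, samples = _toy_clock_inputs(
            [[0.5, 0.5, 0.5]], [1.0], [200.0, 400.0, 600.0]
        )
        with pytest.raises(ValueError, match="range"):
            fit_clock(matrix, dmrs, ewas, samples)

    def test_missing_region_rejected(self):
        matrix, dmrs, ewas, samples = _toy_clock_inputs(
            [[0.1, 0.5, 0.9]], [1.0], [200.0, 400.0, 600.0]
        )
        model = fit_clock(matrix, dmrs, ewas, samples)
        other = make_matrix([[1.0, 2.0, 3.0]], region_ids=["different"],
                            sample_ids=matrix.sample_ids)
        with pytest.raises(ValueError, match="missing"):
            predict_age(model, other)


class TestAcceleration:
    def test_perfectly_linear_clock_has_zero_residuals(self):
        ages = pd.Series([200.0, 350.0, 500.0, 650.0], index=list("abcd"))
        dmrm = 0.9 * ages + 30
        acc = age_acceleration(dmrm, ages)
        np.testing.assert_allclose(acc.acceleration, 0.0, atol=1e-9)

    def test_hand_computed_residuals(self):
        # ages {1,2,3}, dmrm {1,2,4}: slope 1.5, intercept -2/3
        ages = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        dmrm = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        acc = age_acceleration(dmrm, ages)
        np.testing.assert_allclose(
            acc.acceleration, [1 / 6, -1 / 3, 1 / 6], atol=1e-12
        )

    def test_reference_residuals_sum_to_zero(self):
        rng = np.random.default_rng(2)
        ages = pd.Series(rng.uniform(200, 700, 20),
                         index=[f"s{i}" for i in range(20)])
        dmrm = ages + rng.normal(0, 40, 20)
        ref = list(ages.index[:12])
        acc = age_acceleration(dmrm, ages, reference_ids=ref)
        assert abs(acc.acceleration.loc[ref].sum()) < 1e-6

    def test_constant_ages_rejected(self):
        ages = pd.Series([300.0] * 4, index=list("abcd"))
        dmrm = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            age_acceleration(dmrm, ages)

    def test_small_reference_rejected(self):
        ages = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="reference"):
            age_acceleration(ages, ages, reference_ids=["a", "b"])


class TestAssociations:
    def test_zero_acceleration_is_flagged_undefined(self):
        samples = make_samples(12, n_groups=3)
        longevity = make_longevity(samples)
        df = pd.DataFrame(
            {"dmrm_age_days": samples.df["age_days"].to_numpy(),
             "acceleration_days": np.zeros(12)},
            index=samples.df["sample_id"].to_numpy(),
        )
        acc = AccelerationResult(df=df, slope=1.0, intercept=0.0,
                                 reference_ids=tuple(df.index))
        table = clock_associations(acc, samples, longevity)
        pear = table[table["method"] == "pearson"]
        assert pear["estimate"].isna().all()

    def test_planted_lifespan_coupling_gives_negative_correlation(
        self, small_cohort, small_ewas
    ):
        dmrs = small_ewas.call_dmrs("age", 1e-4)
        fitted = DmrClock(
            small_cohort.methylome, dmrs, small_ewas,
            small_cohort.samples, small_cohort.longevity,
        ).fit()
        table = fitted.associations().set_index(["analysis", "subset"])
        row = table.loc[("acc_vs_max_lifespan", "all")]
        assert row["estimate"] < 0

    def test_hfd_acceleration_higher_in_matched_strains(
        self, small_cohort, small_ewas
    ):
        dmrs = small_ewas.call_dmrs("age", 1e-4)
        fitted = DmrClock(
            small_cohort.methylome, dmrs, small_ewas,
            small_cohort.samples, small_cohort.longevity,
        ).fit()
        table = fitted.associations().set_index("analysis")
        assert table.loc["acc_hfd_vs_cd", "estimate"] > 0

    def test_null_aging_coupling_is_calibrated(self):
        """Without planted life-span-coupled aging rates, the
        acceleration/life-span correlation is rarely significant."""
        n_sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_regions=300, frac_age_dmr=0.05,
                ls_aging_coupling_days=0.0, hfd_aging_boost_days=0.0,
            )
            cohort = simulate_dataset(cfg, seed=100 + seed)
            res = RegionEWAS(
                cohort.methylome, cohort.samples, cohort.longevity
            ).fit()
            dmrs = res.call_dmrs("age", 1e-4)
            if len(dmrs) == 0:
                continue
            fitted = DmrClock(
                cohort.methylome, dmrs, res, cohort.samples, cohort.longevity
            ).fit()
            table = fitted.associations().set_index(["analysis", "subset"])
            p = table.loc[("acc_vs_max_lifespan", "all"), "p"]
            n_sig += p < 0.05
        assert n_sig <= 3


class TestSplitValidation:
    def test_deterministic_under_seed(self, small_cohort):
        kws = dict(n_train=55, rng=None)
        a = split_validate(
            small_cohort.methylome, small_cohort.samples, small_cohort.longevity,
            n_train=55, rng=np.random.default_rng(77),
        )
        b = split_validate(
            small_cohort.methylome, small_cohort.samples, small_cohort.longevity,
            n_train=55, rng=np.random.default_rng(77),
        )
        assert a.train_ids == b.train_ids
        assert a.test_age_r.estimate == b.test_age_r.estimate
        pd.testing.assert_frame_equal(a.test_associations, b.test_associations)

    def test_heldout_age_correlation_recovered(self, small_cohort):
        rep = split_validate(
            small_cohort.methylome, small_cohort.samples, small_cohort.longevity,
            n_train=55, rng=np.random.default_rng(8),
        )
        assert rep.test_age_r.estimate >= 0.8

    def test_scaling_constants_use_training_split_only(self, small_cohort):
        rep = split_validate(
            small_cohort.methylome, small_cohort.samples, small_cohort.longevity,
            n_train=55, rng=np.random.default_rng(9),
        )
        train_pred = rep.dmrm_age.loc[list(rep.train_ids)]
        m = rep.clock
        # recompute the constants from the train split alone
        assert train_pred.min() == pytest.approx(m.min_age_days, abs=1e-9)
        assert train_pred.max() == pytest.approx(
            m.min_age_days + m.age_range_days, abs=1e-9
        )
        sums = (
            m.weights @ small_cohort.methylome.df.loc[list(m.region_ids),
                                                      list(rep.train_ids)].to_numpy()
        )
        assert m.min_weighted_sum == pytest.approx(sums.min(), abs=1e-12)
        assert m.weighted_sum_range == pytest.approx(np.ptp(sums), abs=1e-12)

    def test_too_small_test_split_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_validate(
                small_cohort.methylome, small_cohort.samples,
                small_cohort.longevity, n_train=68,
                rng=np.random.default_rng(1),
            )
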