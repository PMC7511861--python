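"""The age-DMR weighted-average epigenetic clock (DMRmAge).

Each training sample's weighted sum S_i = sum_j beta_age_j * m_ij (the
age-DMR methylation values weighed by their age regression coefficients) is
affinely rescaled onto the training cohort's chronological age range:

    DMRmAge_i = (S_i - min S) * age.range / range(S) + min.age

where min S and range(S) are taken over the training samples and age.range
/ min.age are the training cohort's chronological age span. The map absorbs
any positive rescaling of the weights or constant shift of the sums, so the
"weighted average" needs no normalization. Age acceleration (DMRmAge-acc)
is the residual of DMRmAge regressed on chronological age over a reference
(training) subset: positive values mean epigenetically older than expected.

``split_validate`` reruns the whole pipeline — EWAS, age-DMR calling, clock
fit and residual line — on a random training subset and evaluates the
predictions on the held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LongevityTable, MethylomeMatrix, SampleTable
from .ewas import DmrSet, EwasResults, RegionEWAS
from .stats import TestResult, ols_partial_f, paired_t, pearson_with_p, welch_t

__all__ = [
    "ClockModel",
    "AccelerationResult",
    "DmrClock",
    "ClockResults",
    "ValidationReport",
    "fit_clock",
    "predict_age",
    "age_acceleration",
    "clock_associations",
    "split_validate",
]


@dataclass(frozen=True)
class ClockModel:
    """Fitted clock: regions, weights, and training-derived scaling constants."""

    region_ids: tuple
    weights: np.ndarray
    min_weighted_sum: float
    weighted_sum_range: float
    min_age_days: float
    age_range_days: float
    training_sample_ids: tuple

    def __post_init__(self):
        if len(self.region_ids) == 0:
            raise ValueError("clock needs at least one region")
        if self.weighted_sum_range <= 0:
            raise ValueError("weighted-sum range must be > 0")


def _weighted_sums(model_regions, weights, matrix: MethylomeMatrix) -> pd.Series:
    missing = [r for r in model_regions if r not in matrix.df.index]
    if missing:
        raise ValueError(f"clock regions missing from matrix: {missing[:5]}")
    sub = matrix.df.loc[list(model_regions)]
    return pd.Series(weights @ sub.to_numpy(), index=matrix.sample_ids)


def fit_clock(
    matrix: MethylomeMatrix,
    age_dmrs: DmrSet,
    ewas: EwasResults,
    samples: SampleTable,
    training_ids=None,
) -> ClockModel:
    """Build the clock from age-DMRs and their EWAS age coefficients.

    Scaling constants (min/range of the weighted sums, min/range of age)
    come from the training samples only (default: all samples).
    """
    if age_dmrs.trait != "age":
        raise ValueError("clock must be built from age-DMRs")
    region_ids = tuple(age_dmrs.region_ids)
    weights = ewas.table.loc[list(region_ids), "beta_age"].to_numpy()
    train = list(training_ids) if training_ids is not None else samples.sample_ids
    missing = set(train) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"training samples missing from matrix: {sorted(missing)[:5]}")
    S = _weighted_sums(region_ids, weights, matrix).loc[train]
    ages = samples.df.set_index("sample_id").loc[train, "age_days"].astype(float)
    if len(train) < 2 or np.ptp(ages) == 0:
        raise ValueError("need >= 2 training samples with distinct ages")
    s_range = float(S.max() - S.min())
    if s_range <= 0:
        raise ValueError("zero weighted-sum range over training samples")
    return ClockModel(
        region_ids=region_ids,
        weights=weights,
        min_weighted_sum=float(S.min()),
        weighted_sum_range=s_range,
        min_age_days=float(ages.min()),
        age_range_days=float(ages.max() - ages.min()),
        training_sample_ids=tuple(train),
    )


def predict_age(model: ClockModel, matrix: MethylomeMatrix) -> pd.Series:
    """Apply the stored affine map; training predictions span exactly
    [min.age, min.age + age.range], new samples may fall outside."""
    S = _weighted_sums(model.region_ids, model.weights, matrix)
    return (
        (S - model.min_weighted_sum) * model.age_range_days / model.weighted_sum_range
        + model.min_age_days
    ).rename("dmrm_age_days")


@dataclass(frozen=True)
class AccelerationResult:
    """Per-sample DMRmAge and its residual from the reference age regression."""

    df: pd.DataFrame  # index sample_id; columns dmrm_age_days, acceleration_days
    slope: float
    intercept: float
    reference_ids: tuple

    @property
    def acceleration(self) -> pd.Series:
        return self.df["acceleration_days"]


def age_acceleration(
    dmrm_age: pd.Series, ages: pd.Series, reference_ids=None
) -> AccelerationResult:
    """Residuals of DMRmAge on chronological age.

    The regression line is fitted over ``reference_ids`` (default: all
    samples); residuals are then computed for every sample from that line,
    so held-out samples are scored against the reference cohort's trend.
    """
    dmrm_age = pd.Series(dmrm_age).astype(float)
    ages = pd.Series(ages).astype(float).loc[dmrm_age.index]
    ref = list(reference_ids) if reference_ids is not None else list(dmrm_age.index)
    if len(ref) < 3:
        raise ValueError("reference subset must have >= 3 samples")
    x = ages.loc[ref].to_numpy()
    y = dmrm_age.loc[ref].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("constant ages: acceleration undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = dmrm_age - (slope * ages + intercept)
    out = pd.DataFrame(
        {"dmrm_age_days": dmrm_age, "acceleration_days": resid}
    )
    return AccelerationResult(
        df=out, slope=float(slope), intercept=float(intercept), reference_ids=tuple(ref)
    )


def _safe_pearson(x, y) -> TestResult:
    try:
        return pearson_with_p(x, y)
    except ValueError:
        return TestResult(statistic=np.nan, p_value=np.nan, estimate=np.nan, df=np.nan)


def clock_associations(
    acc: AccelerationResult,
    samples: SampleTable,
    longevity: LongevityTable,
    lifespan_stat: str = "max",
    diet_test: str = "welch",
) -> pd.DataFrame:
    """Associations of age acceleration with life span, weight and diet.

    Rows: Pearson r of acceleration against the strain-by-diet group's
    ``lifespan_stat`` life span, BW0 and final weight (overall and CD-only);
    a diet comparison restricted to strains carrying both diets (Welch by
    default, strain-paired on request); and a multivariable regression of
    acceleration on life span + BW0 + diet with a partial F per term.
    """
    sdf = samples.df.set_index("sample_id").loc[acc.df.index]
    sdf.index.name = "sample_id"
    a = acc.acceleration.to_numpy()
    sub_samples = SampleTable(sdf.reset_index())
    ls = longevity.stat_for_samples(sub_samples, lifespan_stat).to_numpy()
    rows = []
    _trait_vals = {
        f"{lifespan_stat}_lifespan": ls,
        "bw0": sdf["bw0_g"].to_numpy(float),
        "final_weight": sdf["final_weight_g"].to_numpy(float),
    }
    masks = {"all": np.ones(len(sdf), bool), "CD": (sdf["diet"] == "CD").to_numpy()}
    for subset, mask in masks.items():
        for trait, vals in _trait_vals.items():
            res = (
                _safe_pearson(a[mask], vals[mask])
                if mask.sum() >= 3
                else TestResult(np.nan, np.nan, np.nan, np.nan)
            )
            rows.append(
                dict(analysis=f"acc_vs_{trait}", subset=subset, method="pearson",
                     estimate=res.estimate, statistic=res.statistic,
                     p=res.p_value, n=int(mask.sum()))
            )

    # diet effect within strains represented on both diets
    both = sdf.groupby("strain")["diet"].nunique()
    matched = sdf["strain"].isin(both.index[both == 2]).to_numpy()
    hfd = matched & (sdf["diet"] == "HFD").to_numpy()
    cd = matched & (sdf["diet"] == "CD").to_numpy()
    if hfd.sum() >= 2 and cd.sum() >= 2:
        if diet_test == "paired":
            per = pd.DataFrame({"strain": sdf["strain"], "diet": sdf["diet"], "acc": a})
            per = per[matched].groupby(["strain", "diet"])["acc"].mean().unstack()
            res = paired_t(per["HFD"].to_numpy(), per["CD"].to_numpy())
            n_used = len(per)
        else:
            res = welch_t(a[hfd], a[cd])
            n_used = int(hfd.sum() + cd.sum())
        rows.append(
            dict(analysis="acc_hfd_vs_cd", subset="matched_strains",
                 method=diet_test, estimate=res.estimate,
                 statistic=res.statistic, p=res.p_value, n=n_used)
        )

    # multivariable: acceleration ~ lifespan + BW0 + diet
    if np.ptp(a) > 0:
        design = pd.DataFrame(
            {
                "lifespan": ls,
                "bw0": sdf["bw0_g"].to_numpy(float),
                "diet": sdf["diet"].to_numpy(),
            }
        )
        for term in ("lifespan", "bw0", "diet"):
            try:
                res = ols_partial_f(a, design, term)
                df_num, df_den = res.df
                rows.append(
                    dict(analysis=f"multivar_{term}", subset="all",
                         method=f"partial_F({df_num:g},{df_den:g})",
                         estimate=res.estimate, statistic=res.statistic,
                         p=res.p_value, n=len(a))
                )
            except ValueError:
                rows.append(
                    dict(analysis=f"multivar_{term}", subset="all",
                         method="partial_F", estimate=np.nan,
                         statistic=np.nan, p=np.nan, n=len(a))
                )
    return pd.DataFrame(rows)


class DmrClock:
    """Model object pairing a methylome with age-DMRs to build the clock."""

    def __init__(
        self,
        methylome: MethylomeMatrix,
        age_dmrs: DmrSet,
        ewas: EwasResults,
        samples: SampleTable,
        longevity: LongevityTable | None = None,
    ):
        self.methylome = methylome
        self.age_dmrs = age_dmrs
        self.ewas = ewas
        self.samples = samples
        self.longevity = longevity

    def fit(self, training_ids=None) -> "ClockResults":
        model = fit_clock(
            self.methylome, self.age_dmrs, self.ewas, self.samples, training_ids
        )
        dmrm = predict_age(model, self.methylome)
        ages = self.samples.df.set_index("sample_id")["age_days"].loc[dmrm.index]
        acc = age_acceleration(dmrm, ages, reference_ids=model.training_sample_ids)
        return ClockResults(model=model, acceleration=acc, clock_obj=self)


@dataclass
class ClockResults:
    """Fitted clock with per-sample DMRmAge and acceleration."""

    model: ClockModel
    acceleration: AccelerationResult
    clock_obj: DmrClock

    @property
    def dmrm_age(self) -> pd.Series:
        return self.acceleration.df["dmrm_age_days"]

    def age_correlation(self) -> TestResult:
        ages = (
            self.clock_obj.samples.df.set_index("sample_id")["age_days"]
            .loc[self.dmrm_age.index]
            .to_numpy(float)
        )
        return _safe_pearson(self.dmrm_age.to_numpy(), ages)

    def associations(self, **kws) -> pd.DataFrame:
        if self.clock_obj.longevity is None:
            raise ValueError("no longevity table attached")
        return clock_associations(
            self.acceleration, self.clock_obj.samples, self.clock_obj.longevity, **kws
        )

    def summary(self) -> str:
        r = self.age_correlation()
        m = self.model
        return "\n".join(
            [
                "DMRmAge clock (weighted-average of age-DMRs, affinely scaled)",
                f"  regions: {len(m.region_ids)}   training samples: "
                f"{len(m.training_sample_ids)}",
                f"  min.age = {m.min_age_days:.0f} d   age.range = "
                f"{m.age_range_days:.0f} d",
                f"  r(DMRmAge, age) = {r.estimate:.3f} (p = {r.p_value:.2g}, "
                f"n = {len(self.dmrm_age)})",
            ]
        )


@dataclass
class ValidationReport:
    """Train/test subsample validation of the full EWAS + clock pipeline."""

    train_ids: tuple
    test_ids: tuple
    n_age_dmrs: int
    clock: ClockModel
    dmrm_age: pd.Series
    acceleration: AccelerationResult
    train_age_r: TestResult
    test_age_r: TestResult
    train_associations: pd.DataFrame
    test_associations: pd.DataFrame

    def summary(self) -> str:
        return "\n".join(
            [
                "Subsample validation",
                f"  train n = {len(self.train_ids)}   test n = {len(self.test_ids)}"
                f"   age-DMRs refit on train: {self.n_age_dmrs}",
                f"  r(DMRmAge, age): train = {self.train_age_r.estimate:.3f}, "
                f"test = {self.test_age_r.estimate:.3f}",
            ]
        )


def split_validate(
    matrix: MethylomeMatrix,
    samples: SampleTable,
    longevity: LongevityTable,
    n_train: int = 55,
    suggestive_p: float = 1e-4,
    sex_filter: str | None = "F",
    rng: np.random.Generator | None = None,
    lifespan_stat: str = "max",
) -> ValidationReport:
    """Refit the whole pipeline on a random training split, test on the rest.

    Training samples are drawn without replacement from the sex-filtered
    pool (default females only, so any males land in the test set, as do the
    unfilled female slots). EWAS, age-DMR calling at ``suggestive_p``, clock
    scaling and the acceleration regression line all use the training split
    only; predictions and residuals are then computed for every sample.
    """
    rng = rng or np.random.default_rng()
    sdf = samples.df
    eligible = (
        sdf.loc[sdf["sex"] == sex_filter, "sample_id"]
        if sex_filter
        else sdf["sample_id"]
    )
    eligible = list(eligible)
    if n_train >= len(sdf):
        raise ValueError("n_train must leave a test set")
    if n_train > len(eligible):
        raise ValueError(f"only {len(eligible)} eligible samples for n_train={n_train}")
    train = sorted(rng.choice(eligible, size=n_train, replace=False))
    test = sorted(set(sdf["sample_id"]) - set(train))
    if len(test) < 3:
        raise ValueError("test split must have >= 3 samples")

    train_samples = samples.subset(train)
    train_matrix = MethylomeMatrix(matrix.df[train])
    ewas = RegionEWAS(train_matrix, train_samples, longevity).fit()
    age_dmrs = ewas.call_dmrs("age", suggestive_p)
    if len(age_dmrs) == 0:
        raise ValueError("no age-DMRs at the suggestive threshold in the train split")
    model = fit_clock(matrix, age_dmrs, ewas, samples, training_ids=train)
    dmrm = predict_age(model, matrix)
    ages = sdf.set_index("sample_id")["age_days"].astype(float).loc[dmrm.index]
    acc = age_acceleration(dmrm, ages, reference_ids=train)

    def split_report(ids):
        ids = list(ids)
        sub = samples.subset(ids)
        age_r = _safe_pearson(
            dmrm.loc[ids].to_numpy(), ages.loc[ids].to_numpy()
        )
        sub_acc = AccelerationResult(
            df=acc.df.loc[ids], slope=acc.slope, intercept=acc.intercept,
            reference_ids=acc.reference_ids,
        )
        assoc = clock_associations(sub_acc, sub, longevity, lifespan_stat=lifespan_stat)
        return age_r, assoc

    train_age_r, train_assoc = split_report(train)
    test_age_r, test_assoc = split_report(test)
    return ValidationReport(
        train_ids=tuple(train),
        test_ids=tuple(test),
        n_age_dmrs=len(age_dmrs),
        clock=model,
        dmrm_age=dmrm,
        acceleration=acc,
        train_age_r=train_age_r,
        test_age_r=test_age_r,
        train_associations=train_assoc,
        test_associations=test_assoc,
    )
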