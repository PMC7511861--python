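"""Synthetic BXD-like cohort generator with known ground truth.

Emulates the structure of a recombinant-inbred liver methylome study:
~69 samples across 17 strain-by-diet groups (control chow vs high-fat
diet), collection ages spanning 181-759 days, strain-dependent life spans
with an HFD penalty, baseline body weight (BW0) correlated with age at
weighing and negatively coupled to strain life span, a region x sample
logRPKM matrix with planted age-, BW0- and life-span-DMRs on top of
strain-by-diet random intercepts, and matched transcript expression for a
subset of samples with configurable cis-correlation signs.

The generative model per region j and sample i is

    y_ij = mu_j + b_age_j * bioage_i + b_bw_j * BW0_i + b_ls_j * medLS_g(i)
           + u_g(i)j + e_ij,   u ~ N(0, tau^2),  e ~ N(0, sigma^2)

where bioage_i = age_i + accel_g(i) lets strain-by-diet groups age
epigenetically faster or slower: accel_g is negative in long-lived groups
(scaled by ``ls_aging_coupling_days`` per SD of group median life span) and
boosted by ``hfd_aging_boost_days`` on HFD. Planted age-DMRs gain
methylation preferentially in CpG-dense, lowly methylated bins; BW0-DMRs
are predominantly hypomethylated with higher weight. Every non-DMR region
has all three coefficients exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    LongevityTable,
    MethylomeMatrix,
    RegionSet,
    SampleTable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_regions",
    "simulate_cohort",
    "simulate_methylome",
    "simulate_expression",
    "simulate_dataset",
]

# Default per-group biospecimen sizes: 12 CD groups then 5 HFD groups
# (strains 4-8 carry both diets), totalling 69 samples.
_DEFAULT_CD_SIZES = (5, 5, 8, 3, 3, 6, 4, 4, 3, 7, 3, 4)
_DEFAULT_HFD_SIZES = (3, 3, 2, 3, 3)
_DEFAULT_HFD_STRAINS = (3, 4, 5, 6, 7)  # indices into the strain list


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study cohort."""

    # cohort structure
    n_strains: int = 12
    samples_per_cd_group: tuple = _DEFAULT_CD_SIZES
    samples_per_hfd_group: tuple = _DEFAULT_HFD_SIZES
    hfd_strain_indices: tuple = _DEFAULT_HFD_STRAINS
    include_males: bool = False
    n_males: int = 3

    # regions
    n_regions: int = 10_000
    frac_variant_regions: float = 0.17
    frac_cpg_island: float = 0.20
    island_cpg_mean: float = 15.0
    background_cpg_mean: float = 2.0

    # planted DMRs (disjoint sets)
    frac_age_dmr: float = 0.01
    frac_bw_dmr: float = 0.01
    frac_ls_dmr: float = 0.006
    beta_age_range: tuple = (0.0010, 0.0020)   # logRPKM per day
    beta_bw_range: tuple = (0.015, 0.030)      # logRPKM per gram
    beta_ls_range: tuple = (0.0008, 0.0016)    # logRPKM per day of median LS
    age_sign_cpg_weight: float = 1.5
    age_sign_meth_weight: float = 1.5
    bw_negative_prob: float = 0.75
    ls_positive_prob: float = 0.59

    # variance components
    tau: float = 0.10    # strain-by-diet random-intercept SD
    sigma: float = 0.15  # residual SD

    # ages and life spans (days)
    age_range_days: tuple = (181.0, 759.0)
    base_lifespan_days: float = 700.0
    strain_lifespan_sd: float = 150.0
    hfd_lifespan_penalty_days: float = 85.0
    within_group_lifespan_sd: float = 130.0
    longevity_n_per_group: int = 13

    # body weight (grams)
    bw0_base_g: float = 18.0
    strain_bw_sd_g: float = 2.5
    bw0_age_mean_days: float = 134.0
    bw0_age_sd_days: float = 81.0
    bw0_age_slope_g_per_day: float = 0.03
    bw0_noise_sd_g: float = 1.5
    bw_lifespan_coupling_g_per_day: float = -0.012
    cd_weight_gain_g: float = 6.0
    hfd_weight_gain_g: float = 15.0
    final_weight_noise_sd_g: float = 3.0
    liver_weight_mean_g: float = 1.22
    hfd_liver_gain_g: float = 0.07
    liver_weight_sd_g: float = 0.2

    # group-level epigenetic aging offsets (days of biological age)
    ls_aging_coupling_days: float = 30.0
    hfd_aging_boost_days: float = 40.0

    # baseline methylation
    mu_base: float = 1.0
    mu_cpg_slope: float = -0.04
    mu_sd: float = 0.30

    # matched expression
    n_expression_samples: int = 52
    cis_strength: float = 0.8
    n_null_transcripts: int = 200
    cis_sign_age: str | int = "match"
    cis_sign_bw: str | int = "match"
    cis_sign_ls: str | int = -1

    def validate(self) -> None:
        fracs = [
            self.frac_variant_regions,
            self.frac_cpg_island,
            self.frac_age_dmr,
            self.frac_bw_dmr,
            self.frac_ls_dmr,
            self.bw_negative_prob,
            self.ls_positive_prob,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions/probabilities must be in [0, 1]")
        if self.frac_age_dmr + self.frac_bw_dmr + self.frac_ls_dmr > 1:
            raise ValueError("DMR fractions sum above 1")
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_regions < 100:
            raise ValueError("n_regions must be >= 100")
        if len(self.samples_per_hfd_group) != len(self.hfd_strain_indices):
            raise ValueError("one HFD group size per HFD strain index")
        if len(self.samples_per_cd_group) != self.n_strains:
            raise ValueError("one CD group size per strain")
        if max(self.hfd_strain_indices, default=-1) >= self.n_strains:
            raise ValueError("hfd_strain_indices out of range")


@dataclass
class GroundTruth:
    """Planted truth: per-region coefficients and per-group parameters.

    ``regions``: region_id, beta_age, beta_bw, beta_ls, is_age_dmr,
    is_bw_dmr, is_ls_dmr, mu. ``groups``: group, strain, diet,
    true_mean_lifespan, accel_days. ``intercepts``: group x region random
    intercepts (DataFrame, groups as rows).
    """

    regions: pd.DataFrame
    groups: pd.DataFrame
    intercepts: pd.DataFrame | None = None

    def __post_init__(self):
        r = self.regions
        for trait, flag in (("age", "is_age_dmr"), ("bw", "is_bw_dmr"), ("ls", "is_ls_dmr")):
            if ((r[f"beta_{trait}"] != 0) != r[flag]).any():
                raise ValueError(f"{flag} inconsistent with nonzero beta_{trait}")


_FEATURE_CATS = ("promoter", "exon", "intron", "UTR", "intergenic", "rRNA", "LTR")
_BACKGROUND_PROBS = (0.05, 0.10, 0.28, 0.05, 0.42, 0.02, 0.08)
_ISLAND_GENIC_PROBS = (0.50, 0.30, 0.05, 0.15, 0.0, 0.0, 0.0)


def simulate_regions(config: SimulationConfig, rng: np.random.Generator) -> RegionSet:
    """Draw 150-bp bins with CpG counts, variants and feature labels."""
    config.validate()
    R = config.n_regions
    chroms = np.array([f"chr{c}" for c in rng.integers(1, 20, size=R)])
    # sequential non-overlapping placement per chromosome
    start = np.zeros(R, dtype=int)
    offsets: dict[str, int] = {}
    for i, ch in enumerate(chroms):
        pos = offsets.get(ch, 0)
        start[i] = pos
        offsets[ch] = pos + 300
    is_island = rng.random(R) < config.frac_cpg_island
    cpg = np.where(
        is_island,
        rng.poisson(config.island_cpg_mean, R),
        rng.poisson(config.background_cpg_mean, R),
    ).astype(int)
    has_variant = rng.random(R) < config.frac_variant_regions
    variant_count = np.where(has_variant, 1 + rng.poisson(1.0, R), 0).astype(int)

    cats = np.empty(R, dtype=object)
    bg = rng.choice(len(_FEATURE_CATS), size=R, p=_BACKGROUND_PROBS)
    isl = rng.choice(len(_FEATURE_CATS), size=R, p=_ISLAND_GENIC_PROBS)
    for i in range(R):
        cats[i] = _FEATURE_CATS[isl[i] if is_island[i] else bg[i]]

    rows = []
    for i in range(R):
        labels = {cats[i]}
        if is_island[i]:
            labels.add("cpg_island")
        genic = cats[i] in ("promoter", "exon", "intron", "UTR")
        rows.append(
            {
                "region_id": f"r{i:06d}",
                "chrom": chroms[i],
                "start": int(start[i]),
                "end": int(start[i]) + 150,
                "cpg_count": int(cpg[i]),
                "variant_count": int(variant_count[i]),
                "feature_labels": frozenset(labels),
                "gene_id": f"g{i:06d}" if genic else None,
            }
        )
    return RegionSet(pd.DataFrame(rows))


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[SampleTable, LongevityTable]:
    """Draw per-animal covariates and the parallel longevity cohort."""
    config.validate()
    strains = [f"S{k:02d}" for k in range(1, config.n_strains + 1)]
    strain_z = rng.standard_normal(config.n_strains)
    strain_ls = config.base_lifespan_days + config.strain_lifespan_sd * strain_z
    strain_ls = np.maximum(strain_ls, 200.0)
    strain_bw = (
        config.bw0_base_g
        + config.strain_bw_sd_g * rng.standard_normal(config.n_strains)
        + config.bw_lifespan_coupling_g_per_day
        * (strain_ls - config.base_lifespan_days)
    )

    groups: list[tuple[int, str, int]] = []  # (strain idx, diet, n samples)
    for s, n in enumerate(config.samples_per_cd_group):
        groups.append((s, "CD", int(n)))
    for s, n in zip(config.hfd_strain_indices, config.samples_per_hfd_group):
        groups.append((int(s), "HFD", int(n)))

    lo_rows, sample_rows = [], []
    age_lo, age_hi = config.age_range_days
    for s, diet, n in groups:
        mean_ls = strain_ls[s] - (
            config.hfd_lifespan_penalty_days if diet == "HFD" else 0.0
        )
        deaths = mean_ls + config.within_group_lifespan_sd * rng.standard_normal(
            config.longevity_n_per_group
        )
        deaths = np.maximum(deaths, 30.0)
        for d in deaths:
            lo_rows.append({"strain": strains[s], "diet": diet, "lifespan_days": float(d)})
        for k in range(n):
            age = float(rng.uniform(age_lo, age_hi))
            bw0_age = float(
                np.clip(
                    rng.normal(config.bw0_age_mean_days, config.bw0_age_sd_days),
                    21.0,
                    age - 30.0,
                )
            )
            bw0 = float(
                strain_bw[s]
                + config.bw0_age_slope_g_per_day * bw0_age
                + rng.normal(0.0, config.bw0_noise_sd_g)
            )
            gain = config.hfd_weight_gain_g if diet == "HFD" else config.cd_weight_gain_g
            final = float(bw0 + gain + rng.normal(0.0, config.final_weight_noise_sd_g))
            liver = float(
                config.liver_weight_mean_g
                + (config.hfd_liver_gain_g if diet == "HFD" else 0.0)
                + rng.normal(0.0, config.liver_weight_sd_g)
            )
            sample_rows.append(
                {
                    "sample_id": f"{strains[s]}_{diet}_{k}",
                    "strain": strains[s],
                    "diet": diet,
                    "sex": "F",
                    "age_days": round(age, 1),
                    "bw0_g": round(max(bw0, 5.0), 2),
                    "bw0_age_days": round(bw0_age, 1),
                    "final_weight_g": round(max(final, 6.0), 2),
                    "liver_weight_g": round(max(liver, 0.3), 3),
                    "days_on_hfd": int(round(age - bw0_age)) if diet == "HFD" else 0,
                }
            )
    samples = pd.DataFrame(sample_rows)
    if config.include_males and config.n_males > 0:
        idx = rng.choice(len(samples), size=min(config.n_males, len(samples)), replace=False)
        samples.loc[samples.index[idx], "sex"] = "M"
    return SampleTable(samples), LongevityTable(pd.DataFrame(lo_rows))


def _signed_betas_age(config, cpg, mu, idx, rng):
    """Magnitudes from the configured range; P(+) rises with CpG density and
    falls with baseline methylation (the island hypermethylation pattern)."""
    mag = rng.uniform(*config.beta_age_range, size=len(idx))
    z_cpg = (cpg[idx] - cpg.mean()) / max(cpg.std(), 1e-12)
    z_mu = (mu[idx] - mu.mean()) / max(mu.std(), 1e-12)
    logit = config.age_sign_cpg_weight * z_cpg - config.age_sign_meth_weight * z_mu
    p_pos = 1.0 / (1.0 + np.exp(-logit))
    sign = np.where(rng.random(len(idx)) < p_pos, 1.0, -1.0)
    return sign * mag


def simulate_methylome(
    regions: RegionSet,
    samples: SampleTable,
    longevity: LongevityTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[MethylomeMatrix, GroundTruth]:
    """Generate the region x sample logRPKM matrix plus its ground truth."""
    config.validate()
    R = len(regions)
    n = len(samples)
    cpg = regions.df["cpg_count"].to_numpy(float)
    mu = config.mu_base + config.mu_cpg_slope * cpg + rng.normal(0, config.mu_sd, R)

    perm = rng.permutation(R)
    n_age = int(round(config.frac_age_dmr * R))
    n_bw = int(round(config.frac_bw_dmr * R))
    n_ls = int(round(config.frac_ls_dmr * R))
    idx_age = perm[:n_age]
    idx_bw = perm[n_age : n_age + n_bw]
    idx_ls = perm[n_age + n_bw : n_age + n_bw + n_ls]

    beta_age = np.zeros(R)
    beta_bw = np.zeros(R)
    beta_ls = np.zeros(R)
    beta_age[idx_age] = _signed_betas_age(config, cpg, mu, idx_age, rng)
    sign_bw = np.where(rng.random(n_bw) < config.bw_negative_prob, -1.0, 1.0)
    beta_bw[idx_bw] = sign_bw * rng.uniform(*config.beta_bw_range, size=n_bw)
    sign_ls = np.where(rng.random(n_ls) < config.ls_positive_prob, 1.0, -1.0)
    beta_ls[idx_ls] = sign_ls * rng.uniform(*config.beta_ls_range, size=n_ls)

    labels = samples.group_labels()
    uniq, ginv = np.unique(labels.to_numpy(), return_inverse=True)
    med_ls = longevity.stat_for_samples(samples, "median").to_numpy()
    group_med = np.array(
        [med_ls[ginv == g][0] for g in range(len(uniq))]
    )
    z_ls = (group_med - group_med.mean()) / max(group_med.std(), 1e-12)
    is_hfd_group = np.array([g.endswith(":HFD") for g in uniq])
    accel = (
        -config.ls_aging_coupling_days * z_ls
        + config.hfd_aging_boost_days * is_hfd_group
    )

    age = samples.df["age_days"].to_numpy(float)
    bw0 = samples.df["bw0_g"].to_numpy(float)
    bio_age = age + accel[ginv]

    u = rng.normal(0.0, config.tau, size=(len(uniq), R))
    eps = rng.normal(0.0, config.sigma, size=(R, n))
    # covariates enter centred so mu_j is each region's expected mean
    # methylation (an intercept reparametrization; coefficients unchanged)
    Y = (
        mu[:, None]
        + beta_age[:, None] * (bio_age - bio_age.mean())[None, :]
        + beta_bw[:, None] * (bw0 - bw0.mean())[None, :]
        + beta_ls[:, None] * (med_ls - med_ls.mean())[None, :]
        + u[ginv].T
        + eps
    )
    matrix = MethylomeMatrix(
        pd.DataFrame(Y, index=regions.region_ids, columns=samples.sample_ids)
    )
    truth_regions = pd.DataFrame(
        {
            "region_id": regions.region_ids,
            "beta_age": beta_age,
            "beta_bw": beta_bw,
            "beta_ls": beta_ls,
            "is_age_dmr": beta_age != 0,
            "is_bw_dmr": beta_bw != 0,
            "is_ls_dmr": beta_ls != 0,
            "mu": mu,
        }
    )
    truth_groups = pd.DataFrame(
        {
            "group": uniq,
            "strain": [g.split(":")[0] for g in uniq],
            "diet": [g.split(":")[1] for g in uniq],
            "true_median_lifespan": group_med,
            "accel_days": accel,
        }
    )
    intercepts = pd.DataFrame(u, index=uniq, columns=regions.region_ids)
    return matrix, GroundTruth(truth_regions, truth_groups, intercepts)


def _cis_sign(setting, true_beta: float) -> float:
    if setting == "match":
        return 1.0 if true_beta >= 0 else -1.0
    return float(setting)


def simulate_expression(
    methylome: MethylomeMatrix,
    regions: RegionSet,
    ground_truth: GroundTruth,
    samples: SampleTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Matched transcripts: cis-coupled to each DMR's methylation.

    Transcript = cis_sign * cis_strength * z(methylation) +
    sqrt(1 - cis_strength^2) * noise over the expression subsample; genes for
    non-DMR regions (``n_null_transcripts`` of them) are pure noise.
    """
    config.validate()
    n_expr = min(config.n_expression_samples, len(samples))
    expr_samples = sorted(
        rng.choice(methylome.sample_ids, size=n_expr, replace=False)
    )
    truth = ground_truth.regions.set_index("region_id")
    gene_of = dict(zip(regions.df["region_id"], regions.df["gene_id"]))

    meth = methylome.df[expr_samples]
    rows, tids = [], []

    def add_transcript(rid: str, sign: float) -> None:
        gene = gene_of.get(rid)
        if gene is None:
            return
        m = meth.loc[rid].to_numpy()
        z = (m - m.mean()) / max(m.std(), 1e-12)
        noise = rng.standard_normal(n_expr)
        a = config.cis_strength
        rows.append(sign * a * z + np.sqrt(max(1 - a * a, 0.0)) * noise)
        tids.append(gene)

    for rid in truth.index[truth["is_age_dmr"]]:
        add_transcript(rid, _cis_sign(config.cis_sign_age, truth.at[rid, "beta_age"]))
    for rid in truth.index[truth["is_bw_dmr"]]:
        add_transcript(rid, _cis_sign(config.cis_sign_bw, truth.at[rid, "beta_bw"]))
    for rid in truth.index[truth["is_ls_dmr"]]:
        add_transcript(rid, _cis_sign(config.cis_sign_ls, truth.at[rid, "beta_ls"]))

    null_pool = [
        rid
        for rid in truth.index[
            ~(truth["is_age_dmr"] | truth["is_bw_dmr"] | truth["is_ls_dmr"])
        ]
        if gene_of.get(rid) is not None
    ]
    n_null = min(config.n_null_transcripts, len(null_pool))
    if n_null:
        for rid in rng.choice(null_pool, size=n_null, replace=False):
            gene = gene_of[rid]
            rows.append(rng.standard_normal(n_expr))
            tids.append(gene)

    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows), index=tids, columns=expr_samples)
    )


@dataclass
class SyntheticCohort:
    """Everything one run of the generator produces."""

    config: SimulationConfig
    regions: RegionSet
    samples: SampleTable
    longevity: LongevityTable
    methylome: MethylomeMatrix
    expression: ExpressionMatrix
    truth: GroundTruth


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """One-call generation of a full synthetic cohort (deterministic in seed)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    regions = simulate_regions(config, rng)
    samples, longevity = simulate_cohort(config, rng)
    methylome, truth = simulate_methylome(regions, samples, longevity, config, rng)
    expression = simulate_expression(methylome, regions, truth, samples, config, rng)
    return SyntheticCohort(config, regions, samples, longevity, methylome, expression, truth)
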