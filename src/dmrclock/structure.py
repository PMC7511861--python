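"""Methylome-wide structure: PCA, PC-trait screening, global means, outliers.

PCA treats samples as observations and regions as features, centring each
region across samples (no scaling), so the variance fractions are
interpretable shares of total methylome variance. Strain identity dominates
the top components in these cohorts; the screen then asks which components
track age, weight, diet or strain life span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import LongevityTable, MethylomeMatrix, RegionSet, SampleTable
from .stats import pearson_with_p, welch_t

__all__ = [
    "PcaResult",
    "run_pca",
    "pc_trait_screen",
    "global_mean_methylation",
    "flag_pca_outliers",
]


@dataclass(frozen=True)
class PcaResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame          # samples x components, columns PC1..PCk
    variance_fraction: np.ndarray
    n_components: int

    def __post_init__(self):
        vf = self.variance_fraction
        if np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def run_pca(matrix: MethylomeMatrix, n_components: int) -> PcaResult:
    """Region-centred, unscaled PCA of samples."""
    X = matrix.values.T  # samples x regions
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, regions)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        n_components=n_components,
    )


_WEIGHT_TRAITS = {
    "age": "age_days",
    "bw0": "bw0_g",
    "final_weight": "final_weight_g",
    "liver_weight": "liver_weight_g",
}


def pc_trait_screen(
    pca: PcaResult,
    samples: SampleTable,
    longevity: LongevityTable,
    n_pcs: int | None = None,
    diet: str | None = None,
    exclude_strains: tuple = (),
) -> pd.DataFrame:
    """Correlate each top PC with every trait; Welch t for diet.

    Traits: age, BW0, final weight, liver weight (skipped when absent), and
    the strain-level mean/median/min/max life span. Optionally restricted to
    one diet or with strains (e.g. F1 hybrids) excluded.
    """
    n_pcs = n_pcs or pca.n_components
    df = samples.df.set_index("sample_id")
    keep = pd.Series(True, index=df.index)
    if diet is not None:
        keep &= df["diet"] == diet
    if exclude_strains:
        keep &= ~df["strain"].isin(exclude_strains)
    df = df[keep]
    scores = pca.scores.loc[df.index]

    traits: dict[str, np.ndarray] = {}
    for name, col in _WEIGHT_TRAITS.items():
        vals = df[col].to_numpy(float)
        if np.isnan(vals).any():
            continue
        traits[name] = vals
    ls_stats = longevity.group_stats().set_index("group")
    groups = (df["strain"].astype(str) + ":" + df["diet"].astype(str)).to_numpy()
    for stat in LongevityTable.GROUP_STATS:
        traits[f"{stat}_lifespan"] = ls_stats.loc[groups, stat].to_numpy(float)

    rows = []
    for k in range(n_pcs):
        pc = scores.iloc[:, k].to_numpy()
        for name, vals in traits.items():
            try:
                res = pearson_with_p(pc, vals)
                rows.append(
                    dict(pc=f"PC{k + 1}", trait=name, method="pearson",
                         estimate=res.estimate, statistic=res.statistic,
                         p=res.p_value, n=len(vals))
                )
            except ValueError:
                rows.append(
                    dict(pc=f"PC{k + 1}", trait=name, method="pearson",
                         estimate=np.nan, statistic=np.nan, p=np.nan, n=len(vals))
                )
        if diet is None and df["diet"].nunique() == 2:
            a = pc[(df["diet"] == "HFD").to_numpy()]
            b = pc[(df["diet"] == "CD").to_numpy()]
            res = welch_t(a, b)
            rows.append(
                dict(pc=f"PC{k + 1}", trait="diet", method="welch_t",
                     estimate=res.estimate, statistic=res.statistic,
                     p=res.p_value, n=len(pc))
            )
    return pd.DataFrame(rows)


def global_mean_methylation(
    matrix: MethylomeMatrix, regions: RegionSet
) -> pd.DataFrame:
    """Per-sample mean methylation over genic and intergenic bins."""
    genic = regions.genic_mask()
    genic = genic.reindex(matrix.region_ids)
    if genic.isna().any():
        raise ValueError("matrix contains regions absent from the RegionSet")
    gmask = genic.to_numpy(bool)
    if gmask.all() or not gmask.any():
        raise ValueError("need at least one genic and one intergenic region")
    vals = matrix.values
    return pd.DataFrame(
        {
            "genic_mean": vals[gmask].mean(axis=0),
            "intergenic_mean": vals[~gmask].mean(axis=0),
        },
        index=matrix.sample_ids,
    )


def flag_pca_outliers(
    pca: PcaResult, samples: SampleTable, k_sd: float = 6.0
) -> list[str]:
    """Samples far from their strain centroid in (PC1, PC2).

    A sample is flagged when its Euclidean distance to its strain's centroid
    (component-wise median, so one gross outlier cannot drag it) exceeds
    ``k_sd`` times the cohort's median within-strain distance. Purely
    advisory; strains with fewer than two samples are never flagged.
    """
    xy = pca.scores[["PC1", "PC2"]]
    strain = samples.df.set_index("sample_id")["strain"].loc[xy.index]
    dist = pd.Series(np.nan, index=xy.index)
    for s, sub in xy.groupby(strain.to_numpy()):
        if len(sub) < 2:
            continue
        centroid = sub.median(axis=0)
        dist.loc[sub.index] = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
    valid = dist.dropna()
    if valid.empty:
        return []
    cutoff = k_sd * float(valid.median())
    return sorted(valid.index[valid > cutoff])
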