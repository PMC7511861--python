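import numpy as np
import pandas as pd
import pytest

from dmrclock import (
    LongevityTable,
    MethylomeMatrix,
    RegionSet,
    SampleTable,
    RegionEWAS,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_cohort():
    """600-region default-structure cohort used by several module tests."""
    return simulate_dataset(SimulationConfig(n_regions=600), seed=11)


@pytest.fixture(scope="session")
def small_ewas(small_cohort):
    return RegionEWAS(
        small_cohort.methylome, small_cohort.samples, small_cohort.longevity
    ).fit()


def make_regions(n=4, cpg=None, variants=None, labels=None, genes=None):
    """Hand-built RegionSet with n bins on one chromosome."""
    cpg = cpg if cpg is not None else [1] * n
    variants = variants if variants is not None else [0] * n
    labels = labels if labels is not None else [frozenset({"intron"})] * n
    if genes is None:
        genes = [f"g{i}" if set(labels[i]) & {"promoter", "exon", "intron", "UTR"} else None
                 for i in range(n)]
    return RegionSet(
        pd.DataFrame(
            {
                "region_id": [f"r{i}" for i in range(n)],
                "chrom": ["chr1"] * n,
                "start": [300 * i for i in range(n)],
                "end": [300 * i + 150 for i in range(n)],
                "cpg_count": cpg,
                "variant_count": variants,
                "feature_labels": labels,
                "gene_id": genes,
            }
        )
    )


def make_samples(n=12, n_groups=4, ages=None, seed=0):
    """Minimal SampleTable: n samples split over n_groups CD strains."""
    rng = np.random.default_rng(seed)
    ages = ages if ages is not None else rng.uniform(200, 700, n)
    strains = [f"S{i % n_groups}" for i in range(n)]
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"m{i}" for i in range(n)],
                "strain": strains,
                "diet": ["CD"] * n,
                "sex": ["F"] * n,
                "age_days": ages,
                "bw0_g": rng.uniform(15, 30, n),
                "bw0_age_days": [100.0] * n,
                "final_weight_g": rng.uniform(20, 40, n),
                "liver_weight_g": [1.2] * n,
                "days_on_hfd": [0] * n,
            }
        )
    )


def make_longevity(samples, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, diet), _ in samples.df.groupby(["strain", "diet"]):
        base = rng.uniform(400, 900)
        for _ in range(5):
            rows.append(
                {"strain": strain, "diet": diet,
                 "lifespan_days": float(base + rng.normal(0, 50))}
            )
    return LongevityTable(pd.DataFrame(rows))


def make_matrix(values, region_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    region_ids = region_ids or [f"r{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"m{j}" for j in range(values.shape[1])]
    return MethylomeMatrix(pd.DataFrame(values, index=region_ids, columns=sample_ids))
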