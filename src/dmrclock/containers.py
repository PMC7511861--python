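"""Domain containers for region-level methylome analysis.

Everything is a thin, validated wrapper around a :class:`pandas.DataFrame`.
The containers check the structural invariants once at construction so the
downstream statistics can assume clean inputs:

* :class:`RegionSet` — non-overlapping 150-bp genomic bins with CpG counts,
  segregating-variant counts and gene-feature annotations;
* :class:`MethylomeMatrix` / :class:`ExpressionMatrix` — finite, log-scale
  region (or transcript) × sample grids;
* :class:`SampleTable` — per-animal covariates (strain, diet, ages, weights);
* :class:`LongevityTable` — per strain-by-diet ages at natural death, from
  which the group life-span statistics (mean/median/min/max) derive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "MethylomeMatrix",
    "ExpressionMatrix",
    "SampleTable",
    "LongevityTable",
    "ValidationError",
    "REGION_LENGTH_BP",
    "FEATURE_LABELS",
    "GENE_FEATURES",
]

#: fixed bin length of the region quantification scheme
REGION_LENGTH_BP = 150

#: recognised annotation labels for a bin
FEATURE_LABELS = frozenset(
    {"promoter", "exon", "intron", "UTR", "cpg_island", "intergenic", "rRNA", "LTR"}
)

#: labels that make a bin "genic"
GENE_FEATURES = frozenset({"promoter", "exon", "intron", "UTR"})


class ValidationError(ValueError):
    """An input violated a structural invariant of a container."""


def _check_unique(values: Iterable, what: str) -> None:
    values = list(values)
    if len(set(values)) != len(values):
        seen, dups = set(), []
        for v in values:
            if v in seen:
                dups.append(v)
            seen.add(v)
        raise ValidationError(f"duplicate {what}: {sorted(set(map(str, dups)))[:5]}")


@dataclass(frozen=True)
class RegionSet:
    """A set of fixed-length genomic bins with CpG and annotation metadata.

    ``df`` columns: region_id, chrom, start, end, cpg_count, variant_count,
    feature_labels (frozenset of strings), gene_id (str or None).
    Coordinates are 0-based half-open.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = [
            "region_id",
            "chrom",
            "start",
            "end",
            "cpg_count",
            "variant_count",
            "feature_labels",
            "gene_id",
        ]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"RegionSet missing columns: {missing}")
        df = self.df
        _check_unique(df["region_id"], "region_id")
        lengths = df["end"].to_numpy() - df["start"].to_numpy()
        bad = df.loc[lengths != REGION_LENGTH_BP, "region_id"]
        if len(bad):
            raise ValidationError(
                f"bins must be exactly {REGION_LENGTH_BP} bp; offending bins: "
                f"{list(bad[:5])}"
            )
        if (df["cpg_count"].to_numpy() < 0).any() or (
            df["variant_count"].to_numpy() < 0
        ).any():
            raise ValidationError("cpg_count and variant_count must be >= 0")
        for rid, labels, gene in zip(df["region_id"], df["feature_labels"], df["gene_id"]):
            unknown = set(labels) - FEATURE_LABELS
            if unknown:
                raise ValidationError(f"bin {rid}: unknown feature labels {unknown}")
            if "intergenic" in labels and labels & GENE_FEATURES:
                raise ValidationError(
                    f"bin {rid}: intergenic bin carries gene feature labels"
                )
            has_gene_feature = bool(labels & GENE_FEATURES)
            if gene is not None and not has_gene_feature:
                raise ValidationError(
                    f"bin {rid}: gene_id present without a gene feature label"
                )
        self._check_overlap(df)

    @staticmethod
    def _check_overlap(df: pd.DataFrame) -> None:
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            starts = s["start"].to_numpy()
            ends = s["end"].to_numpy()
            clash = starts[1:] < ends[:-1]
            if clash.any():
                i = int(np.argmax(clash))
                a, b = s["region_id"].iloc[i], s["region_id"].iloc[i + 1]
                raise ValidationError(
                    f"overlapping bins on {chrom}: {a!r} and {b!r}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def region_ids(self) -> list[str]:
        return list(self.df["region_id"])

    def genic_mask(self) -> pd.Series:
        """True where a bin carries at least one gene feature label."""
        mask = self.df["feature_labels"].map(lambda s: bool(set(s) & GENE_FEATURES))
        return pd.Series(mask.to_numpy(), index=self.df["region_id"].to_numpy())

    def subset(self, region_ids: Iterable[str]) -> "RegionSet":
        wanted = set(region_ids)
        return RegionSet(self.df[self.df["region_id"].isin(wanted)].reset_index(drop=True))


class _Matrix:
    """Finite feature × sample grid keyed by unique string ids."""

    _feature_name = "feature"

    def __init__(self, df: pd.DataFrame):
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at {self._feature_name} {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        _check_unique(df.index, f"{self._feature_name} id")
        _check_unique(df.columns, "sample id")
        self.df = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}({len(self.df)} {self._feature_name}s x "
            f"{self.df.shape[1]} samples)"
        )


class MethylomeMatrix(_Matrix):
    """Region × sample log-scale normalized methylation coverage (logRPKM)."""

    _feature_name = "region"

    @property
    def region_ids(self) -> list[str]:
        return list(self.df.index)


class ExpressionMatrix(_Matrix):
    """Transcript × sample log-scale abundance."""

    _feature_name = "transcript"

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.df.index)


@dataclass(frozen=True)
class SampleTable:
    """Per-animal covariates.

    ``df`` columns: sample_id, strain, diet (CD/HFD), sex (F/M), age_days,
    bw0_g, bw0_age_days, final_weight_g, liver_weight_g (may be NaN),
    days_on_hfd.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = [
            "sample_id",
            "strain",
            "diet",
            "sex",
            "age_days",
            "bw0_g",
            "bw0_age_days",
            "final_weight_g",
            "liver_weight_g",
            "days_on_hfd",
        ]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"SampleTable missing columns: {missing}")
        df = self.df
        _check_unique(df["sample_id"], "sample_id")
        if not df["diet"].isin(["CD", "HFD"]).all():
            raise ValidationError("diet must be CD or HFD")
        if not df["sex"].isin(["F", "M"]).all():
            raise ValidationError("sex must be F or M")
        if ((df["bw0_age_days"] < 0) | (df["age_days"] <= df["bw0_age_days"])).any():
            raise ValidationError("need age_days > bw0_age_days >= 0 for every sample")
        on_cd = df["diet"] == "CD"
        if (df.loc[on_cd, "days_on_hfd"] != 0).any():
            raise ValidationError("days_on_hfd must be 0 for CD samples")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_labels(self) -> pd.Series:
        """Strain-by-diet grouping factor, indexed by sample_id."""
        lab = self.df["strain"].astype(str) + ":" + self.df["diet"].astype(str)
        return pd.Series(lab.to_numpy(), index=self.df["sample_id"].to_numpy())

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        wanted = set(sample_ids)
        return SampleTable(
            self.df[self.df["sample_id"].isin(wanted)].reset_index(drop=True)
        )


@dataclass(frozen=True)
class LongevityTable:
    """Ages at natural death per strain-by-diet group (long format).

    ``df`` columns: strain, diet, lifespan_days (one row per animal).
    """

    df: pd.DataFrame

    GROUP_STATS = ("mean", "median", "min", "max")

    def __post_init__(self) -> None:
        required = ["strain", "diet", "lifespan_days"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"LongevityTable missing columns: {missing}")
        if (self.df["lifespan_days"].to_numpy() <= 0).any():
            raise ValidationError("life spans must be > 0")
        if not self.df["diet"].isin(["CD", "HFD"]).all():
            raise ValidationError("diet must be CD or HFD")

    def group_stats(self) -> pd.DataFrame:
        """Mean/median/min/max life span per strain-by-diet group."""
        g = self.df.groupby(["strain", "diet"], sort=False)["lifespan_days"]
        out = g.agg(list(self.GROUP_STATS)).reset_index()
        out["group"] = out["strain"].astype(str) + ":" + out["diet"].astype(str)
        return out

    def stat_for_samples(self, samples: SampleTable, stat: str = "median") -> pd.Series:
        """Attach a group life-span statistic to every sample.

        Raises if a sample's strain-by-diet group has no longevity data.
        """
        if stat not in self.GROUP_STATS:
            raise ValueError(f"stat must be one of {self.GROUP_STATS}")
        stats = self.group_stats().set_index("group")[stat]
        groups = samples.group_labels()
        missing = sorted(set(groups) - set(stats.index))
        if missing:
            raise ValidationError(f"no longevity data for groups: {missing}")
        return pd.Series(stats.loc[groups].to_numpy(), index=groups.index)
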