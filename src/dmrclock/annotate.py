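"""DMR characterization: direction tallies, feature enrichment, profiles.

The tally reproduces the direction x genic/intergenic x variant breakdown
for each trait's DMR set. Enrichment is one-sided hypergeometric against
the retained region background (upper tail = enrichment, lower = depletion).
Coefficient profiles quantify how a DMR set's regression coefficients track
local CpG density and mean methylation — the signature that age-gained
methylation concentrates in CpG-dense, lowly methylated bins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import RegionSet, GENE_FEATURES, FEATURE_LABELS
from .ewas import DmrSet, EwasResults
from .stats import hypergeometric_tail, hypergeometric_lower_tail, pearson_with_p

__all__ = [
    "DmrTally",
    "EnrichmentResult",
    "tally_dmrs",
    "feature_enrichment",
    "coefficient_profiles",
]


@dataclass(frozen=True)
class DmrTally:
    """Counts and percentages of a DMR set by direction and annotation.

    Percentages are 100 * count / n_total. When the set is empty every
    percentage is reported as 0 with ``empty=True``.
    """

    trait: str
    n_total: int
    n_positive: int
    n_negative: int
    n_genic_pos: int
    n_genic_neg: int
    n_intergenic_pos: int
    n_intergenic_neg: int
    n_variant: int
    empty: bool = False

    def __post_init__(self):
        if self.n_positive + self.n_negative != self.n_total:
            raise ValueError("positive + negative must equal total")

    def _pct(self, k: int) -> float:
        return 100.0 * k / self.n_total if self.n_total else 0.0

    @property
    def pct_positive(self) -> float:
        return self._pct(self.n_positive)

    @property
    def pct_negative(self) -> float:
        return self._pct(self.n_negative)

    @property
    def pct_genic_pos(self) -> float:
        return self._pct(self.n_genic_pos)

    @property
    def pct_genic_neg(self) -> float:
        return self._pct(self.n_genic_neg)

    @property
    def pct_intergenic_pos(self) -> float:
        return self._pct(self.n_intergenic_pos)

    @property
    def pct_intergenic_neg(self) -> float:
        return self._pct(self.n_intergenic_neg)

    @property
    def pct_variant(self) -> float:
        return self._pct(self.n_variant)

    @classmethod
    def from_counts(
        cls,
        trait: str,
        n_positive: int,
        n_negative: int,
        n_genic_pos: int = 0,
        n_genic_neg: int = 0,
        n_intergenic_pos: int = 0,
        n_intergenic_neg: int = 0,
        n_variant: int = 0,
    ) -> "DmrTally":
        """Build a tally directly from printed counts."""
        total = n_positive + n_negative
        return cls(
            trait=trait,
            n_total=total,
            n_positive=n_positive,
            n_negative=n_negative,
            n_genic_pos=n_genic_pos,
            n_genic_neg=n_genic_neg,
            n_intergenic_pos=n_intergenic_pos,
            n_intergenic_neg=n_intergenic_neg,
            n_variant=n_variant,
            empty=total == 0,
        )

    def to_row(self) -> dict:
        row = asdict(self)
        for name in (
            "pct_positive", "pct_negative", "pct_genic_pos", "pct_genic_neg",
            "pct_intergenic_pos", "pct_intergenic_neg", "pct_variant",
        ):
            row[name] = getattr(self, name)
        return row


def tally_dmrs(dmrs: DmrSet, regions: RegionSet) -> DmrTally:
    """Direction x genic/intergenic x variant tally for one DMR set."""
    rdf = regions.df.set_index("region_id")
    missing = [r for r in dmrs.region_ids if r not in rdf.index]
    if missing:
        raise ValueError(f"DMR regions missing from RegionSet: {missing[:5]}")
    if len(dmrs) == 0:
        return DmrTally(dmrs.trait, 0, 0, 0, 0, 0, 0, 0, 0, empty=True)
    sub = rdf.loc[dmrs.region_ids]
    genic = sub["feature_labels"].map(lambda s: bool(set(s) & GENE_FEATURES)).to_numpy()
    variant = (sub["variant_count"].to_numpy() > 0)
    pos = (dmrs.df["direction"] == "+").to_numpy()
    return DmrTally(
        trait=dmrs.trait,
        n_total=len(dmrs),
        n_positive=int(pos.sum()),
        n_negative=int((~pos).sum()),
        n_genic_pos=int((pos & genic).sum()),
        n_genic_neg=int((~pos & genic).sum()),
        n_intergenic_pos=int((pos & ~genic).sum()),
        n_intergenic_neg=int((~pos & ~genic).sum()),
        n_variant=int(variant.sum()),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric contingency: a DMR set against one category."""

    category: str
    k_in_dmrs: int
    n_dmrs: int
    K_in_background: int
    N_background: int
    p_enrich: float
    p_deplete: float

    def __post_init__(self):
        ok = (
            0 <= self.k_in_dmrs <= self.n_dmrs <= self.N_background
            and self.k_in_dmrs <= self.K_in_background <= self.N_background
        )
        if not ok:
            raise ValueError("incoherent enrichment counts")


def feature_enrichment(
    dmrs: DmrSet, regions: RegionSet, categories: tuple | None = None
) -> list[EnrichmentResult]:
    """Enrichment/depletion of each feature class (and variant-containing
    bins) among the DMRs, against the full retained RegionSet background.

    A bin with several labels contributes to each label's contingency
    independently.
    """
    rdf = regions.df.set_index("region_id")
    dmr_ids = [r for r in dmrs.region_ids if r in rdf.index]
    if len(dmr_ids) != len(dmrs.region_ids):
        raise ValueError("DMR regions missing from RegionSet")
    N = len(rdf)
    n = len(dmr_ids)
    sub = rdf.loc[dmr_ids] if n else rdf.iloc[:0]
    if categories is None:
        categories = tuple(sorted(FEATURE_LABELS)) + ("variant_containing",)
    out = []
    for cat in categories:
        if cat == "variant_containing":
            K = int((rdf["variant_count"] > 0).sum())
            k = int((sub["variant_count"] > 0).sum()) if n else 0
        else:
            K = int(rdf["feature_labels"].map(lambda s: cat in s).sum())
            k = int(sub["feature_labels"].map(lambda s: cat in s).sum()) if n else 0
        out.append(
            EnrichmentResult(
                category=cat,
                k_in_dmrs=k,
                n_dmrs=n,
                K_in_background=K,
                N_background=N,
                p_enrich=hypergeometric_tail(N, K, n, k),
                p_deplete=hypergeometric_lower_tail(N, K, n, k),
            )
        )
    return out


def coefficient_profiles(
    dmrs: DmrSet, ewas: EwasResults, regions: RegionSet
) -> pd.DataFrame:
    """Relate DMR coefficients to CpG density and mean methylation.

    Rows: overall, positive-direction, negative-direction. Columns: Pearson
    r (and p) of beta against cpg_count and against region mean methylation,
    plus group means of both covariates. Undefined correlations (constant
    input or fewer than 3 regions) are reported as NaN with ``defined``
    False.
    """
    rdf = regions.df.set_index("region_id")
    missing = [r for r in dmrs.region_ids if r not in rdf.index]
    if missing:
        raise ValueError(f"DMR regions missing from RegionSet: {missing[:5]}")
    tab = ewas.table
    missing = [r for r in dmrs.region_ids if r not in tab.index]
    if missing:
        raise ValueError(f"DMR regions missing from EWAS results: {missing[:5]}")

    df = pd.DataFrame(
        {
            "beta": dmrs.df.set_index("region_id")["beta"],
            "cpg": rdf.loc[dmrs.region_ids, "cpg_count"].astype(float),
            "mean_meth": tab.loc[dmrs.region_ids, "region_mean"],
            "direction": dmrs.df.set_index("region_id")["direction"],
        }
    )

    def summarize(name: str, sub: pd.DataFrame) -> dict:
        row = {
            "subset": name,
            "n": len(sub),
            "mean_cpg": sub["cpg"].mean() if len(sub) else np.nan,
            "mean_meth": sub["mean_meth"].mean() if len(sub) else np.nan,
        }
        for var in ("cpg", "mean_meth"):
            try:
                res = pearson_with_p(sub["beta"].to_numpy(), sub[var].to_numpy())
                row[f"r_beta_{var}"], row[f"p_beta_{var}"] = res.estimate, res.p_value
                row[f"defined_{var}"] = True
            except ValueError:
                row[f"r_beta_{var}"], row[f"p_beta_{var}"] = np.nan, np.nan
                row[f"defined_{var}"] = False
        return row

    rows = [
        summarize("all", df),
        summarize("positive", df[df["direction"] == "+"]),
        summarize("negative", df[df["direction"] == "-"]),
    ]
    return pd.DataFrame(rows)
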