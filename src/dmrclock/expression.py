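"""Cis DMR-transcript correlations and quadrant classification.

DMRs are paired to transcripts of their cognate gene (by gene_id); for each
pair the methylation-expression Pearson r and the transcript-trait r are
computed over the samples shared between the two assays, with nominal
significance at |r| >= critical_r(alpha, n_shared). The quadrant label
combines the DMR's trait direction with the two correlation signs — the
axes of the usual DMR-vs-expression scatter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    LongevityTable,
    MethylomeMatrix,
    RegionSet,
    SampleTable,
)
from .ewas import DmrSet
from .stats import critical_r, pearson_with_p

__all__ = ["pair_dmrs_to_transcripts", "cis_correlations"]

logger = logging.getLogger(__name__)


def pair_dmrs_to_transcripts(
    dmrs: DmrSet, regions: RegionSet, expr: ExpressionMatrix
) -> tuple[list[tuple[str, str]], list[str]]:
    """Match each DMR to a transcript of its cognate gene.

    A transcript matches when its id equals the region's gene_id (or its
    prefix before a '.', so versioned transcript ids of one gene pair too).
    With several candidates the most variable transcript is used. Returns
    (pairs, unpaired_region_ids).
    """
    gene_of = dict(zip(regions.df["region_id"], regions.df["gene_id"]))
    by_gene: dict[str, list[str]] = {}
    for tid in expr.transcript_ids:
        by_gene.setdefault(str(tid).split(".")[0], []).append(tid)
    variances = expr.df.var(axis=1)

    pairs, unpaired = [], []
    for rid in dmrs.region_ids:
        if rid not in gene_of:
            raise ValueError(f"DMR region {rid!r} missing from RegionSet")
        gene = gene_of[rid]
        candidates = by_gene.get(gene, []) if gene is not None else []
        if not candidates:
            unpaired.append(rid)
            continue
        if len(candidates) > 1:
            best = variances.loc[candidates].idxmax()
            logger.info(
                "gene %s has %d transcripts; using most variable (%s)",
                gene, len(candidates), best,
            )
        else:
            best = candidates[0]
        pairs.append((rid, best))
    return pairs, unpaired


_TRAIT_OF_DMR = {"age": "age_days", "BW0": "bw0_g", "LS": None}


def cis_correlations(
    dmrs: DmrSet,
    pairs: list[tuple[str, str]],
    methylome: MethylomeMatrix,
    expr: ExpressionMatrix,
    samples: SampleTable,
    longevity: LongevityTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair methylation-expression and expression-trait correlations.

    Computed on the intersection of the two assays' samples. The trait for
    the transcript correlation follows the DMR set's trait: age at
    collection, BW0, or the strain-by-diet group's median life span.
    Columns include the |r| threshold used, a ``significant`` flag, and for
    significant pairs a quadrant label ``<dmr dir>/<sign r_meth_expr>/<sign
    r_expr_trait>``.
    """
    shared = [s for s in methylome.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples shared between methylome and expression")
    r_star = critical_r(alpha, len(shared))

    sdf = samples.df.set_index("sample_id")
    if dmrs.trait == "LS":
        trait_vals = longevity.stat_for_samples(samples, "median")
    else:
        trait_vals = sdf[_TRAIT_OF_DMR[dmrs.trait]].astype(float)
    trait_vals = trait_vals.loc[shared].to_numpy()

    direction = dmrs.df.set_index("region_id")["direction"]
    rows = []
    for rid, tid in pairs:
        m = methylome.df.loc[rid, shared].to_numpy()
        e = expr.df.loc[tid, shared].to_numpy()
        try:
            me = pearson_with_p(m, e)
            et = pearson_with_p(e, trait_vals)
        except ValueError:
            rows.append(
                dict(region_id=rid, transcript_id=tid, r_meth_expr=np.nan,
                     p_meth_expr=np.nan, r_expr_trait=np.nan, p_expr_trait=np.nan,
                     dmr_direction=direction.get(rid, "?"), n=len(shared),
                     r_threshold=r_star, significant=False, quadrant="")
            )
            continue
        sig = abs(me.estimate) >= r_star
        quadrant = (
            f"{direction[rid]}/{'+' if me.estimate >= 0 else '-'}"
            f"/{'+' if et.estimate >= 0 else '-'}"
            if sig
            else ""
        )
        rows.append(
            dict(region_id=rid, transcript_id=tid,
                 r_meth_expr=me.estimate, p_meth_expr=me.p_value,
                 r_expr_trait=et.estimate, p_expr_trait=et.p_value,
                 dmr_direction=direction[rid], n=len(shared),
                 r_threshold=r_star, significant=sig, quadrant=quadrant)
        )
    return pd.DataFrame(rows)
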