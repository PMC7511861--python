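"""Tab-separated readers and writers for every container, plus logRPKM.

All files are plain TSV with a header row. Readers validate on load and raise
:class:`~dmrclock.containers.ValidationError` (structure) or
:class:`ParseError` (malformed cells, with coordinates) so a bad input fails
loudly rather than propagating NaNs into the statistics.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    LongevityTable,
    MethylomeMatrix,
    RegionSet,
    SampleTable,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_region_table",
    "write_region_table",
    "read_matrix",
    "write_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_longevity_table",
    "write_longevity_table",
    "log_rpkm",
]


class ParseError(ValueError):
    """A file cell could not be parsed; the message names the location."""


_REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_id",
    "cpg_count",
    "variant_count",
    "feature_labels",
    "gene_id",
]


def read_region_table(path: str | Path) -> RegionSet:
    """Read a BED-like TSV of 150-bp bins into a :class:`RegionSet`."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REGION_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # 1 = header
        try:
            start = int(row.start)
            end = int(row.end)
            cpg = int(row.cpg_count)
            var = int(row.variant_count)
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
        labels = frozenset(s for s in str(row.feature_labels).split(";") if s)
        gene = row.gene_id if row.gene_id else None
        rows.append(
            {
                "region_id": row.region_id,
                "chrom": row.chrom,
                "start": start,
                "end": end,
                "cpg_count": cpg,
                "variant_count": var,
                "feature_labels": labels,
                "gene_id": gene,
            }
        )
    if not rows:
        raise ParseError(f"{path}: empty region table")
    return RegionSet(pd.DataFrame(rows))


def write_region_table(regions: RegionSet, path: str | Path) -> None:
    df = regions.df.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "region_id": df["region_id"],
            "cpg_count": df["cpg_count"],
            "variant_count": df["variant_count"],
            "feature_labels": df["feature_labels"].map(
                lambda s: ";".join(sorted(s))
            ),
            "gene_id": df["gene_id"].map(lambda g: "" if g is None else g),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _read_grid(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need an id column plus at least one sample column")
    id_col = raw.columns[0]
    ids = raw[id_col].tolist()
    data = np.empty((len(raw), raw.shape[1] - 1))
    for j, col in enumerate(raw.columns[1:]):
        for i, cell in enumerate(raw[col]):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {ids[i]!r}, column {col!r}: "
                    f"{cell!r}"
                ) from None
            if not math.isfinite(v):
                raise ParseError(
                    f"{path}: non-finite value at row {ids[i]!r}, column {col!r}"
                )
            data[i, j] = v
    return pd.DataFrame(data, index=pd.Index(ids, name=id_col), columns=raw.columns[1:])


def read_matrix(path: str | Path, kind: str = "methylome") -> MethylomeMatrix | ExpressionMatrix:
    """Read a feature × sample TSV (first column = feature id)."""
    df = _read_grid(path)
    if kind == "methylome":
        return MethylomeMatrix(df)
    if kind == "expression":
        return ExpressionMatrix(df)
    raise ValueError("kind must be 'methylome' or 'expression'")


def write_matrix(matrix: MethylomeMatrix | ExpressionMatrix, path: str | Path) -> None:
    name = "region_id" if isinstance(matrix, MethylomeMatrix) else "transcript_id"
    df = matrix.df.copy()
    df.index.name = name
    df.to_csv(path, sep="\t", float_format="%.10g")


_SAMPLE_NUMERIC = [
    "age_days",
    "bw0_g",
    "bw0_age_days",
    "final_weight_g",
    "liver_weight_g",
    "days_on_hfd",
]


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _SAMPLE_NUMERIC:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
        try:
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
        except ValueError as exc:
            raise ParseError(f"{path}: column {col!r}: {exc}") from None
    for col in ("age_days", "bw0_g", "bw0_age_days", "final_weight_g", "days_on_hfd"):
        if df[col].isna().any():
            raise ParseError(f"{path}: missing values in required column {col!r}")
    df["days_on_hfd"] = df["days_on_hfd"].astype(int)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_longevity_table(path: str | Path) -> LongevityTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "lifespan_days" not in df.columns:
        raise ParseError(f"{path}: missing column 'lifespan_days'")
    try:
        df["lifespan_days"] = pd.to_numeric(df["lifespan_days"])
    except ValueError as exc:
        raise ParseError(f"{path}: column 'lifespan_days': {exc}") from None
    return LongevityTable(df)


def write_longevity_table(longevity: LongevityTable, path: str | Path) -> None:
    longevity.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def log_rpkm(
    counts: np.ndarray,
    library_sizes: np.ndarray,
    region_length_bp: int = 150,
    offset: float = 1.0,
    region_ids=None,
    sample_ids=None,
) -> MethylomeMatrix:
    """Reads-per-kilobase-per-million on a log10 scale.

    value = log10(count / (region_length_bp/1000 * library_size/1e6) + offset).

    ``counts`` is region × sample; ``library_sizes`` is per-sample total
    mapped reads. The offset is a pseudocount on the RPKM scale (default 1,
    so a zero count maps to 0); downstream inference is affine-invariant per
    region, so the base/offset choice only sets the coefficient scale.
    """
    counts = np.asarray(counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a region x sample grid")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    if library_sizes.shape != (counts.shape[1],):
        raise ValueError("library_sizes must have one entry per sample")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    if offset < 0 or (offset == 0 and (counts == 0).any()):
        raise ValueError("offset must be positive (or counts all > 0)")
    rpkm = counts / (region_length_bp / 1000.0 * library_sizes / 1e6)
    values = np.log10(rpkm + offset)
    if region_ids is None:
        region_ids = [f"r{i}" for i in range(counts.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(counts.shape[1])]
    return MethylomeMatrix(pd.DataFrame(values, index=region_ids, columns=sample_ids))
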