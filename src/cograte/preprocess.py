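"""Layer filtering and assembly ahead of feature selection.

Three steps: the near-zero-variance filter (caret's ``nearZeroVar``
semantics: a feature is dropped when its most-common/second-most-common
frequency ratio exceeds 19 *and* fewer than 10% of its values are distinct,
or when it is constant), promoter-methylation aggregation (mean CpG ratio in
a +-1000 bp window around each TSS, dropping genes not covered in every
sample), and the complete-case sample intersection across layers that the
downstream shadow-feature selection requires (it tolerates no missing
values).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NZVParams",
    "near_zero_var_filter",
    "read_tss_bed",
    "aggregate_promoter_methylation",
    "intersect_complete_samples",
]


@dataclass
class NZVParams:
    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 10.0  # percent

    def __post_init__(self) -> None:
        if self.freq_cut <= 1:
            raise ValueError("freq_cut must exceed 1")
        if not 0 < self.unique_cut < 100:
            raise ValueError("unique_cut must lie in (0, 100)")


def near_zero_var_filter(
    matrix: pd.DataFrame, params: NZVParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop near-zero-variance features from a feature x sample matrix.

    Returns (retained matrix, report) where the report holds freq_ratio,
    percent_unique and the removal flag per feature.  A single distinct value
    gives an infinite frequency ratio (always removed).
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    params = params or NZVParams()
    n = matrix.shape[1]
    freq_ratio = np.empty(len(matrix))
    pct_unique = np.empty(len(matrix))
    for i, (_fid, row) in enumerate(matrix.iterrows()):
        counts = row.value_counts().to_numpy()
        if len(counts) == 1:
            freq_ratio[i] = np.inf
        else:
            freq_ratio[i] = counts[0] / counts[1]
        pct_unique[i] = 100.0 * len(counts) / n
    removed = (freq_ratio > params.freq_cut) & (pct_unique < params.unique_cut)
    removed |= ~np.isfinite(freq_ratio)  # constant features always go
    report = pd.DataFrame(
        {"freq_ratio": freq_ratio, "percent_unique": pct_unique, "removed": removed},
        index=matrix.index,
    )
    return matrix.loc[~removed], report


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a TSS BED (0-based half-open) into chrom/start/end/name/strand."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: BED line needs 6 fields (through strand)")
        chrom, start, end, name, _score, strand = parts[:6]
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
        rows.append((chrom, start_i, end_i, name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def aggregate_promoter_methylation(
    cpg: pd.DataFrame, tss: pd.DataFrame, window: int = 1000
) -> pd.DataFrame:
    """Mean CpG methylation ratio per promoter window, per sample.

    ``cpg`` columns: chrom, pos (0-based), then one column per sample;
    ``tss`` as from :func:`read_tss_bed`.  The window is the symmetric
    [TSS - window, TSS + window) interval in genome coordinates for both
    strands (for '-' genes the TSS is ``end - 1``).  Genes with no covered
    CpG in *any* sample are dropped cohort-wide, since the downstream
    selection admits no missing values.
    """
    meta_cols = [c for c in ("chrom", "pos", "strand") if c in cpg.columns]
    if "chrom" not in meta_cols or "pos" not in meta_cols:
        raise ValueError("cpg table needs 'chrom' and 'pos' columns")
    sample_cols = [c for c in cpg.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError("cpg table has no sample columns")

    out = {}
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpg.groupby("chrom")}
    for row in tss.itertuples(index=False):
        tss_pos = row.start if row.strand == "+" else row.end - 1
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, tss_pos - window, side="left")
        hi = np.searchsorted(pos, tss_pos + window, side="left")
        if hi <= lo:
            continue
        vals = sub.iloc[lo:hi][sample_cols]
        means = vals.mean(axis=0, skipna=True)
        covered = vals.notna().any(axis=0)
        if not covered.all():
            continue  # gene not covered in every sample: discarded cohort-wide
        out[row.name] = means
    result = pd.DataFrame.from_dict(out, orient="index")
    if not result.empty:
        result = result[sample_cols]
    return result


def intersect_complete_samples(
    layers: dict[str, pd.DataFrame], rank: pd.Series
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Restrict all layers and the rank vector to their common samples.

    Output column order is identical (sorted) across layers.  Features still
    carrying missing values on the common samples are dropped, mirroring the
    cohort-wide discarding of incompletely covered promoters.
    """
    if not layers:
        raise ValueError("at least one layer required")
    common: set[str] = set(rank.index)
    for df in layers.values():
        common &= set(df.columns)
    if not common:
        raise ValueError("no sample is present in every layer and the rank table")
    order = sorted(common)
    aligned = {}
    for name, df in layers.items():
        sub = df[order]
        sub = sub.loc[sub.notna().all(axis=1)]
        aligned[name] = sub
    return aligned, rank.loc[order]
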