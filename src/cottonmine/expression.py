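"""Transcriptome mining: RPKM normalization and the decile-dispersion screen.

A gene whose expression is controlled by a segregating expression QTL (eQTL)
shows a bimodal, violin-shaped distribution across a recombinant inbred line
(RIL) population: one mode per allele class.  Rather than fitting mixture
models, the screen used here summarizes each gene by the mean RPKM of its
lowest and highest deciles of RILs (p10, p90) and a percent-standard-deviation
statistic (pcSD) built from them; genes with pcSD > 45 whose top decile
exceeds 3 RPKM are flagged as candidate bimodal, fiber-expressed genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cottonmine.errors import InsufficientDataError

PCSD_MIN_DEFAULT = 45.0
P90_MIN_DEFAULT = 3.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene lengths and a timepoint label.

    ``values`` is a DataFrame indexed by gene id with one column per sample
    (RIL); entries are nonnegative RPKM (or raw counts before normalization).
    ``gene_length_bp`` is indexed like ``values`` and is required for RPKM
    normalization.  ``sample_meta`` optionally carries per-sample covariates
    such as planting year.
    """

    values: pd.DataFrame
    gene_length_bp: pd.Series
    timepoint: str = ""
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        self.gene_length_bp = self.gene_length_bp.reindex(self.values.index)
        if (self.gene_length_bp.dropna() < 1).any():
            raise ValueError("gene_length_bp must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class DispersionRecord:
    """Per-gene decile summary and bimodality-filter flags."""

    gene_id: str
    p10: float
    p90: float
    pcsd: float
    n_samples: int
    passes_pcsd: bool | None = None
    passes_expression: bool | None = None


@dataclass
class OneWayAnovaResult:
    """Fixed-effects one-way ANOVA summary."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def rpkm(
    counts: pd.DataFrame,
    gene_length_bp: pd.Series,
    per_sample_total_mapped: pd.Series | Sequence[float],
    timepoint: str = "",
) -> ExpressionMatrix:
    """Normalize raw read counts to reads per kilobase per million mapped reads.

    RPKM = count / (gene length in kb) / (total mapped reads in millions).
    """
    totals = pd.Series(per_sample_total_mapped, index=counts.columns, dtype=float)
    if (totals <= 0).any():
        raise ValueError("per-sample total mapped reads must be > 0")
    lengths = pd.Series(gene_length_bp, dtype=float).reindex(counts.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every gene needs a length >= 1 bp")
    values = counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(values=values, gene_length_bp=lengths, timepoint=timepoint)


def decile_stats(
    values: Sequence[float] | np.ndarray,
    gene_id: str = "",
    method: str = "decile",
) -> DispersionRecord:
    """Summarize one gene's expression across samples by decile means.

    Sorts the non-missing values; the lowest decile is the floor(n/10)
    smallest values (at least one), the top decile the floor(n/10) largest;
    p10 and p90 are their means.  The default pcSD is the percent population
    standard deviation of the two decile means relative to their mean,
    100*(p90-p10)/(p90+p10), which lies in [0, 100] for nonnegative input
    and is defined as 0 when both deciles are 0.  ``method="cv"`` instead
    returns the percent coefficient of variation across all samples,
    100*SD/mean (population SD).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n < 10:
        raise InsufficientDataError(
            f"decile statistics need >= 10 values, got {n} for {gene_id or 'gene'}"
        )
    k = max(1, n // 10)
    arr = np.sort(arr, kind="stable")
    p10 = float(arr[:k].mean())
    p90 = float(arr[-k:].mean())
    if method == "decile":
        # ratio first so p10 == 0 yields exactly 100
        pcsd = 0.0 if (p90 + p10) == 0 else 100.0 * ((p90 - p10) / (p90 + p10))
    elif method == "cv":
        mu = float(arr.mean())
        pcsd = 0.0 if mu == 0 else 100.0 * float(arr.std(ddof=0)) / mu
    else:
        raise ValueError(f"unknown pcsd method {method!r}")
    return DispersionRecord(gene_id=gene_id, p10=p10, p90=p90, pcsd=pcsd, n_samples=n)


def dispersion_table(matrix: ExpressionMatrix, method: str = "decile") -> list[DispersionRecord]:
    """Compute a DispersionRecord for every gene of an expression matrix."""
    return [
        decile_stats(row, gene_id=str(gid), method=method)
        for gid, row in zip(matrix.values.index, matrix.values.to_numpy())
    ]


def bimodal_filter(
    records: Iterable[DispersionRecord],
    pcsd_min: float = PCSD_MIN_DEFAULT,
    p90_min: float = P90_MIN_DEFAULT,
) -> set[str]:
    """Flag genes with high-dispersion, fiber-expressed profiles.

    A gene passes when pcSD is strictly greater than ``pcsd_min`` (default
    45%) AND its top-decile mean is strictly greater than ``p90_min``
    (default 3 RPKM).  Both flags are stored on each record; the set of
    passing gene ids is returned.
    """
    passing: set[str] = set()
    for rec in records:
        rec.passes_pcsd = rec.pcsd > pcsd_min
        rec.passes_expression = rec.p90 > p90_min
        if rec.passes_pcsd and rec.passes_expression:
            passing.add(rec.gene_id)
    return passing


def rank_by_pcsd(records: Iterable[DispersionRecord]) -> list[DispersionRecord]:
    """Order genes by descending pcSD; ties by descending p90, then gene id."""
    return sorted(records, key=lambda r: (-r.pcsd, -r.p90, r.gene_id))


def log_transform(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise natural log(RPKM + 1), the scale used for violin plots."""
    arr = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) else values
    if (np.asarray(arr) < 0).any():
        raise ValueError("log transform requires nonnegative input")
    return np.log1p(arr) if not isinstance(values, pd.DataFrame) else np.log1p(values)


def year_effect_anova(
    values: Sequence[float] | np.ndarray,
    year_labels: Sequence,
) -> OneWayAnovaResult:
    """One-way fixed-effects ANOVA of expression (or any response) on year.

    Used to confirm that planting year does not drive a gene's expression
    variability before pooling RILs grown in different years.  Computed
    directly from between-/within-group sums of squares; the p value comes
    from the F distribution.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(year_labels)
    if y.shape != labels.shape:
        raise ValueError("values and year_labels must align")
    groups = [y[labels == lev] for lev in pd.unique(labels)]
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 year groups")
    if any(g.size < 2 for g in groups):
        raise InsufficientDataError("every year group needs >= 2 samples")
    grand = y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = y.size - len(groups)
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return OneWayAnovaResult(
        f_statistic=float(f_stat), df_between=df_between, df_within=df_within, p_value=p
    )


def dispersion_frame(records: Iterable[DispersionRecord]) -> pd.DataFrame:
    """Tabulate dispersion records (gene_id, p10, p90, pcsd, flags, n)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "p10": r.p10,
            "p90": r.p90,
            "pcsd": r.pcsd,
            "passes_pcsd": r.passes_pcsd,
            "passes_expression": r.passes_expression,
            "n_samples": r.n_samples,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def read_dispersion_tsv(path) -> list[DispersionRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DispersionRecord(
                gene_id=str(row.gene_id),
                p10=float(row.p10),
                p90=float(row.p90),
                pcsd=float(row.pcsd),
                n_samples=int(row.n_samples),
                passes_pcsd=bool(row.passes_pcsd) if "passes_pcsd" in df.columns else None,
                passes_expression=(
                    bool(row.passes_expression) if "passes_expression" in df.columns else None
                ),
            )
        )
    return records


def write_dispersion_tsv(records: Iterable[DispersionRecord], path) -> None:
    dispersion_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path, lengths_path=None, timepoint: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV (gene_id index) plus optional lengths TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        lengths = pd.Series(1.0, index=values.index)
    return ExpressionMatrix(values=values, gene_length_bp=lengths, timepoint=timepoint)
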