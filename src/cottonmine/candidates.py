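"""Candidate-gene integration: combine the evidence streams into one table.

The mining approach scores each gene on up to five binary evidence flags:
a consequential DNA variant in the germplasm (HIGH/MODERATE impact with a
homozygous-ALT carrier), expression in fiber tissue (top-decile mean above
3 RPKM at either timepoint), bimodal expression across the RIL population at
each of the two timepoints, membership in a supplied gene family of
literature candidates, and overlap with a mapped QTL interval.  Genes are
ranked by evidence count.  The flammability screen is the family-restricted
variant: family members bimodal at BOTH timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cottonmine.errors import FormatError
from cottonmine.expression import (
    P90_MIN_DEFAULT,
    PCSD_MIN_DEFAULT,
    DispersionRecord,
    bimodal_filter,
)


@dataclass(frozen=True)
class QtlInterval:
    """A mapped trait interval, 1-based inclusive bp coordinates."""

    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"QTL {self.trait}: start ({self.start}) > end ({self.end})")


def genes_in_interval(gene_coords: pd.DataFrame, interval: QtlInterval) -> set[str]:
    """Genes whose [start, end] intersects the interval (any overlap, inclusive)."""
    sub = gene_coords[
        (gene_coords["chrom"] == interval.chrom)
        & (gene_coords["start"] <= interval.end)
        & (gene_coords["end"] >= interval.start)
    ]
    return set(sub["gene_id"].astype(str))


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = pd.Index(list(ids))
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {what}: {dups[:5]}")


def annotate_candidates(
    dna_gene_set: set[str],
    dispersion_8: Sequence[DispersionRecord],
    dispersion_16: Sequence[DispersionRecord],
    family_list: Iterable[str] = (),
    gene_coords: pd.DataFrame | None = None,
    qtl_intervals: Sequence[QtlInterval] = (),
    pcsd_min: float = PCSD_MIN_DEFAULT,
    p90_min: float = P90_MIN_DEFAULT,
) -> pd.DataFrame:
    """Build the ranked candidate table over all genes seen in any input.

    Flags: ``has_dna_variant`` (membership in the allele-mining gene set),
    ``fiber_expressed`` (top-decile mean > ``p90_min`` at either timepoint),
    ``bimodal_8dpa``/``bimodal_16dpa`` (dispersion filter per timepoint),
    ``in_family``, and ``qtl_hits`` (comma-joined names of overlapping QTL
    intervals; counts one evidence flag if nonempty).  Rank is by descending
    evidence count, ties by descending max pcSD, then gene id.
    """
    _check_unique([r.gene_id for r in dispersion_8], "8-DPA dispersion table")
    _check_unique([r.gene_id for r in dispersion_16], "16-DPA dispersion table")
    family = set(str(g) for g in family_list)
    bimodal8 = bimodal_filter(dispersion_8, pcsd_min=pcsd_min, p90_min=p90_min)
    bimodal16 = bimodal_filter(dispersion_16, pcsd_min=pcsd_min, p90_min=p90_min)
    p90 = {}
    pcsd = {}
    for rec in list(dispersion_8) + list(dispersion_16):
        p90[rec.gene_id] = max(p90.get(rec.gene_id, 0.0), rec.p90)
        pcsd[rec.gene_id] = max(pcsd.get(rec.gene_id, 0.0), rec.pcsd)

    all_genes = (
        set(dna_gene_set) | set(p90) | family
    )
    qtl_by_gene: dict[str, list[str]] = {}
    if gene_coords is not None:
        _check_unique(gene_coords["gene_id"].astype(str), "gene coordinates")
        for qtl in qtl_intervals:
            for gid in genes_in_interval(gene_coords, qtl):
                qtl_by_gene.setdefault(gid, []).append(qtl.trait)

    rows = []
    for gid in sorted(all_genes):
        flags = {
            "has_dna_variant": gid in dna_gene_set,
            "fiber_expressed": p90.get(gid, 0.0) > p90_min,
            "bimodal_8dpa": gid in bimodal8,
            "bimodal_16dpa": gid in bimodal16,
            "in_family": gid in family,
        }
        hits = sorted(qtl_by_gene.get(gid, []))
        evidence = sum(flags.values()) + bool(hits)
        rows.append(
            {
                "gene_id": gid,
                **flags,
                "qtl_hits": ",".join(hits),
                "max_pcsd": pcsd.get(gid, 0.0),
                "evidence_count": evidence,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["evidence_count", "max_pcsd", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def flammability_screen(
    family_list: Iterable[str],
    dispersion_8: Sequence[DispersionRecord],
    dispersion_16: Sequence[DispersionRecord],
    pcsd_min: float = PCSD_MIN_DEFAULT,
    p90_min: float = P90_MIN_DEFAULT,
) -> set[str]:
    """Family genes with bimodal expression at BOTH 8- and 16-DPA."""
    family = set(str(g) for g in family_list)
    bimodal8 = bimodal_filter(dispersion_8, pcsd_min=pcsd_min, p90_min=p90_min)
    bimodal16 = bimodal_filter(dispersion_16, pcsd_min=pcsd_min, p90_min=p90_min)
    return family & bimodal8 & bimodal16


def read_qtl_tsv(path) -> list[QtlInterval]:
    """Read QTL intervals from a TSV with columns trait, chrom, start, end.

    Coordinates are 1-based inclusive (not BED half-open).
    """
    df = pd.read_csv(path, sep="\t")
    return [
        QtlInterval(
            trait=str(r.trait), chrom=str(r.chrom), start=int(r.start), end=int(r.end)
        )
        for r in df.itertuples(index=False)
    ]
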