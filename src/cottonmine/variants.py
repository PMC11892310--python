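"""Allele mining from SnpEff-annotated VCFs.

The mining chain keeps variants that (i) exceed a quality threshold
(QUAL > 500), (ii) carry at least one annotation whose predicted impact is
HIGH or MODERATE, and (iii) are homozygous for the alternative allele in at
least one line — i.e. the variant is fixed in some inbred line rather than
merely called heterozygous.  Kept variants aggregate to the set of affected
genes; interval subsetting and marker-haplotype counting support the
QTL-region analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from cottonmine.errors import FormatError

logger = logging.getLogger(__name__)

IMPACT_LEVELS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})
DEFAULT_MIN_QUAL = 500.0
DEFAULT_IMPACTS = frozenset({"HIGH", "MODERATE"})

_STATE_BY_DOSAGE = {0: "hom-ref", 1: "het", 2: "hom-alt"}


@dataclass(frozen=True)
class EffectAnnotation:
    """One SnpEff ANN entry (the five leading subfields)."""

    allele: str
    effect_terms: tuple[str, ...]
    impact: str
    gene_name: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise FormatError(f"impact must be one of {sorted(IMPACT_LEVELS)}, got {self.impact!r}")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid call collapsed to state and ALT dosage."""

    state: str  # hom-ref | het | hom-alt | missing
    dosage: int | None  # 0 | 1 | 2 | None

    @classmethod
    def from_alleles(cls, a0: int, a1: int) -> "GenotypeCall":
        # hom-alt requires both alleles equal and non-reference (matches the
        # "1/1:" semantics while generalizing to multi-allelic records)
        if a0 < 0 or a1 < 0:
            return cls("missing", None)
        if a0 == a1:
            return cls("hom-ref", 0) if a0 == 0 else cls("hom-alt", 2)
        return cls("het", 1)


@dataclass
class VariantRecord:
    """One VCF row with its annotations and per-sample calls."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    annotations: list[EffectAnnotation] = field(default_factory=list)
    genotypes: list[GenotypeCall] = field(default_factory=list)
    raw: str | None = None


def _parse_ann_field(ann_value: str, where: str) -> list[EffectAnnotation]:
    annotations = []
    for entry in ann_value.split(","):
        parts = entry.split("|")
        if len(parts) < 5 or parts[2] not in IMPACT_LEVELS:
            logger.warning("skipping malformed ANN subfield at %s: %r", where, entry[:80])
            continue
        annotations.append(
            EffectAnnotation(
                allele=parts[0],
                effect_terms=tuple(parts[1].split("&")) if parts[1] else (),
                impact=parts[2],
                gene_name=parts[3],
                gene_id=parts[4],
            )
        )
    return annotations


def parse_annotated_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Parse a SnpEff-annotated VCF into records plus the ordered sample ids.

    Records are returned in file order.  Both ``/`` and ``|`` genotype
    separators are accepted; records without an ANN key are retained with
    empty annotations; malformed ANN entries are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.open("rb").read(2)
    if head not in (b"##", b"\x1f\x8b"):
        raise FormatError(f"{path} does not look like a VCF (missing ## header)")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad content
        raise FormatError(f"cannot open {path} as VCF: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        ann_value = v.INFO.get("ANN")
        where = f"{v.CHROM}:{v.POS}"
        annotations = _parse_ann_field(ann_value, where) if ann_value else []
        calls = [GenotypeCall.from_alleles(int(g[0]), int(g[1])) for g in v.genotypes]
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=None if v.QUAL is None else float(v.QUAL),
                annotations=annotations,
                genotypes=calls,
                raw=str(v).rstrip("\n"),
            )
        )
    header = vcf.raw_header
    vcf.close()
    parse_annotated_vcf.last_header = header  # kept for filtered-VCF re-emission
    return records, samples


def filter_quality(
    records: Iterable[VariantRecord], min_qual: float = DEFAULT_MIN_QUAL
) -> list[VariantRecord]:
    """Keep records with QUAL strictly greater than ``min_qual``.

    Records with missing QUAL are excluded (and logged); order is preserved.
    """
    kept = []
    n_missing = 0
    for rec in records:
        if rec.qual is None:
            n_missing += 1
            continue
        if rec.qual > min_qual:
            kept.append(rec)
    if n_missing:
        logger.info("filter_quality: excluded %d records with missing QUAL", n_missing)
    return kept


def filter_impact(
    records: Iterable[VariantRecord], impacts: Iterable[str] = DEFAULT_IMPACTS
) -> list[VariantRecord]:
    """Keep records with at least one annotation whose impact is in ``impacts``."""
    impacts = frozenset(impacts)
    unknown = impacts - IMPACT_LEVELS
    if unknown:
        raise ValueError(f"unknown impact levels: {sorted(unknown)}")
    return [r for r in records if any(a.impact in impacts for a in r.annotations)]


def filter_homozygous_alt_present(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep records where at least one sample is homozygous-ALT (1/1)."""
    return [r for r in records if any(g.state == "hom-alt" for g in r.genotypes)]


def genes_affected(records: Iterable[VariantRecord]) -> set[str]:
    """Union of gene ids over HIGH/MODERATE annotations, deduplicated."""
    return {
        a.gene_id
        for r in records
        for a in r.annotations
        if a.impact in DEFAULT_IMPACTS and a.gene_id
    }


def subset_by_interval(
    records: Iterable[VariantRecord], chrom: str, start: int, end: int
) -> list[VariantRecord]:
    """Records on ``chrom`` with start <= pos <= end (1-based inclusive)."""
    if start > end:
        raise ValueError(f"start ({start}) must be <= end ({end})")
    return [r for r in records if r.chrom == chrom and start <= r.pos <= end]


def count_hom_alt(record: VariantRecord) -> tuple[int, int, int, int]:
    """Counts of (hom-alt, het, hom-ref, missing) calls; sums to sample count."""
    states = [g.state for g in record.genotypes]
    return (
        states.count("hom-alt"),
        states.count("het"),
        states.count("hom-ref"),
        states.count("missing"),
    )


@dataclass
class HaplotypeGroups:
    """Distinct complete marker vectors with line assignments."""

    n_haplotypes: int
    groups: dict[tuple, list[str]]
    unassigned: list[str]


def count_haplotypes(marker_matrix: pd.DataFrame) -> HaplotypeGroups:
    """Group lines by identical complete marker vectors.

    ``marker_matrix`` has one row per line, one column per marker.  Lines
    containing any missing call (NaN, None, "", "./." or ".") are reported
    separately as unassigned rather than forming haplotypes of their own.
    """
    if marker_matrix.empty:
        raise ValueError("marker matrix is empty")
    missing_tokens = {"", ".", "./."}
    groups: dict[tuple, list[str]] = {}
    unassigned: list[str] = []
    for line, row in marker_matrix.iterrows():
        vals = row.tolist()
        if any(pd.isna(v) or (isinstance(v, str) and v.strip() in missing_tokens) for v in vals):
            unassigned.append(str(line))
            continue
        groups.setdefault(tuple(vals), []).append(str(line))
    return HaplotypeGroups(n_haplotypes=len(groups), groups=groups, unassigned=unassigned)


def dosage_matrix(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Samples x loci ALT-dosage matrix (-1 for missing), loci keyed CHROM:POS."""
    data = np.full((len(samples), len(records)), -1, dtype=np.int8)
    cols = []
    for j, rec in enumerate(records):
        cols.append(f"{rec.chrom}:{rec.pos}")
        for i, call in enumerate(rec.genotypes):
            if call.dosage is not None:
                data[i, j] = call.dosage
    return pd.DataFrame(data, index=list(samples), columns=cols)


def genotypes_at(
    records: Sequence[VariantRecord], samples: Sequence[str], chrom: str, pos: int
) -> pd.Series:
    """Per-sample ALT dosage at one locus (-1 for missing)."""
    for rec in records:
        if rec.chrom == chrom and rec.pos == pos:
            return pd.Series(
                [(-1 if g.dosage is None else g.dosage) for g in rec.genotypes],
                index=list(samples),
                name=f"{chrom}:{pos}",
                dtype=np.int8,
            )
    raise KeyError(f"no variant at {chrom}:{pos}")
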