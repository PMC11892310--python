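"""Synthetic MAGIC-RIL dataset generator.

Emulates the statistical structure of a multi-parent advanced generation
inter-cross (MAGIC) population of recombinant inbred lines (RILs): each RIL
genome is a mosaic of founder haplotypes with Poisson-distributed crossover
breakpoints and near-complete homozygosity after single-seed descent.  The
breeding design (half-diallele crosses, random intermating, selfing) is not
re-enacted cross-by-cross — downstream analyses depend only on the resulting
genotype and linkage structure, which the mosaic model reproduces directly.

On top of the genotypes the generator simulates:

* fiber transcriptomes at two developmental timepoints, in which a chosen
  fraction of genes carry an expression QTL (eQTL): expression is a gene
  baseline times ``fold**(dosage/2)`` at the driver locus times lognormal
  multiplicative noise, so strong eQTL genes show the bimodal violin-shaped
  distributions the transcriptome-mining screen targets;
* a quantitative fiber phenotype controlled additively by two designated
  driver loci on different chromosomes;
* a SnpEff-style annotated VCF (QUAL, ANN impact classes, per-RIL genotypes)
  whose filter-chain outcome is recorded in a ground-truth manifest.

All randomness flows from ``SimConfig.seed`` through named substreams, so an
identical config yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cottonmine.config import ConfigError, SimConfig
from cottonmine.expression import ExpressionMatrix

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_EFFECT_TERM = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intergenic_region",
}
_CHROM_NAMES = ["A07", "D13", "A03", "D11", "A13", "D04", "A05", "D05", "A12", "D12"]

# substream ids; never reuse across draws so adding a stage cannot shift others
_S_FOUNDERS, _S_RILS, _S_GENES, _S_EQTL, _S_PHENO, _S_VCF = 1, 2, 3, 4, 5, 6
_S_EXPR_BASE, _S_EXPR_NOISE = 10, 20

# Driver variants model the study's designated candidate loci: confirmed,
# high-confidence nonsynonymous SNPs, hence a fixed high QUAL and MODERATE
# impact rather than draws from the background distributions.
DRIVER_QUAL = 999.0


def _chrom_name(i: int) -> str:
    return _CHROM_NAMES[i] if i < len(_CHROM_NAMES) else f"C{i + 1:02d}"


@dataclass(frozen=True)
class FounderPanel:
    """Founder haplotypes (founders x loci, 0=REF 1=ALT) with locus coordinates."""

    haplotypes: np.ndarray
    loci: pd.DataFrame  # columns: chrom, pos (1-based, strictly increasing per chrom)
    founder_ids: list[str]

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.founder_ids), len(self.loci)):
            raise ValueError("haplotype matrix shape does not match founders x loci")
        for _, grp in self.loci.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("locus positions must be unique and increasing per chromosome")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def simulate_founders(config: SimConfig) -> FounderPanel:
    """Draw founder haplotypes over biallelic loci.

    Each founder carries the ALT allele at each locus with probability 0.3;
    any locus left without an ALT carrier is given one (a random founder), so
    every locus segregates or is fixed-ALT relative to the reference.
    """
    if not isinstance(config, SimConfig):
        raise ConfigError("config must be a SimConfig")
    rng = np.random.default_rng([config.seed, _S_FOUNDERS])
    m = config.n_chromosomes * config.loci_per_chromosome
    hap = (rng.random((config.n_founders, m)) < 0.3).astype(np.int8)
    empty = np.flatnonzero(hap.sum(axis=0) == 0)
    if empty.size:
        hap[rng.integers(config.n_founders, size=empty.size), empty] = 1

    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=config.loci_per_chromosome, replace=False)
        ) + 1
        chroms.extend([_chrom_name(c)] * config.loci_per_chromosome)
        positions.extend(int(p) for p in pos)
    loci = pd.DataFrame({"chrom": chroms, "pos": positions})
    founder_ids = [f"Founder{i + 1:02d}" for i in range(config.n_founders)]
    return FounderPanel(haplotypes=hap, loci=loci, founder_ids=founder_ids)


def simulate_rils(panel: FounderPanel, config: SimConfig) -> np.ndarray:
    """Simulate RIL genotypes as founder-haplotype mosaics.

    Per RIL and chromosome the number of crossover breakpoints is
    Poisson(recomb_rate) — the crossovers accumulated over the whole breeding
    design — with a fresh founder drawn per segment; blocks are contiguous in
    coordinate order.  Calls are homozygous for the mosaic allele except that
    each locus independently remains heterozygous with probability
    ``residual_het_rate``.  Returns an (n_rils x n_loci) int8 dosage matrix
    with values 0 (hom-REF), 1 (het), 2 (hom-ALT).
    """
    rng = np.random.default_rng([config.seed, _S_RILS])
    m_per = config.loci_per_chromosome
    geno = np.empty((config.n_rils, panel.n_loci), dtype=np.int8)
    for r in range(config.n_rils):
        for c in range(config.n_chromosomes):
            lo = c * m_per
            n_break = rng.poisson(config.recomb_rate)
            cuts = np.sort(rng.integers(1, m_per, size=n_break)) if m_per > 1 else np.array([], int)
            bounds = np.concatenate(([0], cuts, [m_per]))
            for b in range(len(bounds) - 1):
                founder = rng.integers(config.n_founders)
                seg = slice(lo + bounds[b], lo + bounds[b + 1])
                geno[r, seg] = 2 * panel.haplotypes[founder, seg]
    if config.residual_het_rate > 0:
        het_mask = rng.random(geno.shape) < config.residual_het_rate
        geno[het_mask] = 1
    return geno


def designate_drivers(panel: FounderPanel, config: SimConfig) -> dict[str, int]:
    """Pick the two phenotype driver loci A and D (column indices).

    A sits on the first chromosome, D on the second (or later on the first if
    only one chromosome is simulated).  Each is the locus whose founder ALT
    count is closest to 30% of the panel — an intermediate allele frequency
    that keeps all four two-locus genotype classes populated.
    """
    counts = panel.haplotypes.sum(axis=0)
    target = max(1, round(0.3 * config.n_founders))

    def best_in(idx: np.ndarray) -> int:
        poly = idx[(counts[idx] >= 1) & (counts[idx] <= config.n_founders - 1)]
        pool = poly if poly.size else idx
        return int(pool[np.argmin(np.abs(counts[pool] - target))])

    m_per = config.loci_per_chromosome
    if config.n_chromosomes >= 2:
        idx_a = np.arange(0, m_per)
        idx_d = np.arange(m_per, 2 * m_per)
    else:
        if m_per < 2:
            raise ConfigError("need at least two loci to designate two driver loci")
        half = m_per // 2
        idx_a, idx_d = np.arange(0, half), np.arange(half, m_per)
    return {"A": best_in(idx_a), "D": best_in(idx_d)}


def _gene_table(config: SimConfig) -> pd.DataFrame:
    """Lay out gene models: ids, 1-based inclusive coordinates, lengths."""
    rng = np.random.default_rng([config.seed, _S_GENES])
    per = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per[i] += 1
    rows = []
    g = 0
    for c, n_c in enumerate(per):
        chrom = _chrom_name(c)
        for j in range(n_c):
            length = int(np.clip(rng.lognormal(8.0, 0.6), 200, 20000))
            start = int((j + 0.5) / max(n_c, 1) * (config.chrom_length_bp - length)) + 1
            rows.append(
                {
                    "gene_id": f"Gohir.{chrom}G{(j + 1) * 100:06d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + length - 1,
                    "length_bp": length,
                }
            )
            g += 1
    return pd.DataFrame(rows)


def _nearest_gene(genes: pd.DataFrame, chrom: str, pos: int) -> str:
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        sub = genes
    mid = (sub["start"] + sub["end"]) / 2
    return str(sub.loc[(mid - pos).abs().idxmin(), "gene_id"])


def eqtl_assignment(
    panel: FounderPanel, config: SimConfig, genes: pd.DataFrame | None = None
) -> dict[str, int]:
    """Map eQTL gene ids to driver locus column indices (ground truth).

    Derived from the seed alone, so the same map applies at every timepoint.
    The two phenotype driver loci always drive the genes nearest to them —
    these are the dataset's designated candidate genes; the remaining eQTL
    genes are drawn at random and paired with random polymorphic loci.
    """
    if genes is None:
        genes = _gene_table(config)
    rng = np.random.default_rng([config.seed, _S_EQTL])
    drivers = designate_drivers(panel, config)
    counts = panel.haplotypes.sum(axis=0)
    poly = np.flatnonzero((counts >= 1) & (counts <= config.n_founders - 1))
    if poly.size == 0:
        poly = np.arange(panel.n_loci)

    mapping: dict[str, int] = {}
    for key in ("A", "D"):
        locus = drivers[key]
        chrom, pos = panel.loci.iloc[locus][["chrom", "pos"]]
        mapping[_nearest_gene(genes, chrom, int(pos))] = locus

    n_eqtl = int(round(config.frac_eqtl * config.n_genes))
    others = genes.loc[~genes["gene_id"].isin(mapping), "gene_id"].to_numpy()
    n_more = max(0, n_eqtl - len(mapping))
    if n_more > len(others):
        n_more = len(others)
    chosen = rng.choice(others, size=n_more, replace=False)
    for gid in chosen:
        mapping[str(gid)] = int(rng.choice(poly))
    return mapping


def simulate_expression(
    genotypes: np.ndarray,
    panel: FounderPanel,
    config: SimConfig,
    timepoint: str = "8DPA",
    genes: pd.DataFrame | None = None,
    eqtl_map: dict[str, int] | None = None,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Simulate a genes x RILs RPKM matrix for one developmental timepoint.

    Non-eQTL genes are baseline times noise (unimodal); an eQTL gene's
    expression is multiplied by ``eqtl_fold ** (dosage/2)`` at its driver
    locus, so homozygous-ALT RILs sit a full fold above homozygous-REF ones.
    Noise is multiplicative lognormal with unit mean and CV ``noise_cv``.
    """
    if genes is None:
        genes = _gene_table(config)
    if eqtl_map is None:
        eqtl_map = eqtl_assignment(panel, config, genes)
    tp_index = {"8DPA": 0, "16DPA": 1}.get(timepoint, abs(hash(timepoint)) % 100 + 2)
    base_rng = np.random.default_rng([config.seed, _S_EXPR_BASE + tp_index])
    noise_rng = np.random.default_rng([config.seed, _S_EXPR_NOISE + tp_index])

    n_rils = genotypes.shape[0]
    baseline = base_rng.lognormal(mean=np.log(20.0), sigma=1.0, size=config.n_genes)
    sigma_ln = float(np.sqrt(np.log1p(config.noise_cv**2)))
    noise = noise_rng.lognormal(mean=-(sigma_ln**2) / 2, sigma=sigma_ln, size=(config.n_genes, n_rils))

    values = baseline[:, None] * noise
    gene_ids = genes["gene_id"].to_numpy()
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    dosage_ok = np.where(genotypes < 0, 0, genotypes)  # missing treated as REF
    for gid, locus in eqtl_map.items():
        gi = gene_pos[gid]
        values[gi, :] *= config.eqtl_fold ** (dosage_ok[:, locus] / 2.0)

    ril_ids = [f"RIL{r + 1:03d}" for r in range(n_rils)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=ril_ids)
    lengths = pd.Series(genes["length_bp"].to_numpy(), index=df.index, name="length_bp")
    return ExpressionMatrix(values=df, gene_length_bp=lengths, timepoint=timepoint), eqtl_map


def simulate_phenotype(
    genotypes: np.ndarray,
    config: SimConfig,
    drivers: dict[str, int] | None = None,
    panel: FounderPanel | None = None,
) -> pd.DataFrame:
    """Simulate the fiber trait from the two-locus additive model.

    value = mu + beta_a*I(A hom-ALT) + beta_d*I(D hom-ALT)
            + beta_interact*I(both) + Normal(0, sigma)
    """
    if drivers is None:
        if panel is None:
            raise ConfigError("drivers or panel required to locate the driver loci")
        drivers = designate_drivers(panel, config)
    for key in ("A", "D"):
        if key not in drivers or not 0 <= drivers[key] < genotypes.shape[1]:
            raise ConfigError(f"driver locus {key!r} missing or out of range")
    rng = np.random.default_rng([config.seed, _S_PHENO])
    a_alt = genotypes[:, drivers["A"]] == 2
    d_alt = genotypes[:, drivers["D"]] == 2
    value = (
        config.pheno_mu
        + config.beta_a * a_alt
        + config.beta_d * d_alt
        + config.beta_interact * (a_alt & d_alt)
        + rng.normal(0.0, config.pheno_sigma, size=genotypes.shape[0])
    )
    ril_ids = [f"RIL{r + 1:03d}" for r in range(genotypes.shape[0])]
    return pd.DataFrame({"ril_id": ril_ids, "trait": "STR", "value": value})


@dataclass
class MagicDataset:
    """A complete simulated study: genotypes, transcriptomes, phenotype, VCF fields."""

    config: SimConfig
    panel: FounderPanel
    genotypes: np.ndarray
    ril_ids: list[str]
    genes: pd.DataFrame
    eqtl_map: dict[str, int]
    drivers: dict[str, int]
    expression: dict[str, ExpressionMatrix]
    phenotype: pd.DataFrame
    variants: pd.DataFrame  # chrom,pos,ref,alt,qual,impact,gene_id per locus
    manifest: dict


def _variant_table(
    panel: FounderPanel,
    genotypes: np.ndarray,
    genes: pd.DataFrame,
    drivers: dict[str, int],
    config: SimConfig,
) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, _S_VCF])
    m = panel.n_loci
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    qual = np.round(rng.uniform(0.0, 1000.0, size=m), 2)
    probs = np.array(config.impact_probs, dtype=float)
    impact = rng.choice(IMPACTS, size=m, p=probs / probs.sum())

    gene_ids = []
    for chrom, grp in panel.loci.groupby("chrom", sort=False):
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            sub = genes
        mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
        ids = sub["gene_id"].to_numpy()
        for pos in grp["pos"].to_numpy():
            gene_ids.append(str(ids[np.argmin(np.abs(mids - pos))]))

    df = panel.loci.copy()
    df["ref"] = bases[ref_idx]
    df["alt"] = bases[alt_idx]
    df["qual"] = qual
    df["impact"] = impact
    df["gene_id"] = gene_ids
    # designated candidate loci are confirmed nonsynonymous variants
    for key in ("A", "D"):
        df.loc[drivers[key], "qual"] = DRIVER_QUAL
        df.loc[drivers[key], "impact"] = "MODERATE"
    return df


def _build_manifest(ds_vars: pd.DataFrame, genotypes, panel, genes, eqtl_map, drivers, config):
    """Generator-side bookkeeping of every downstream ground truth.

    Computed directly from the simulation arrays, independently of the VCF
    serialization/parsing path, so it can serve as the oracle for the
    QUAL>500 -> HIGH|MODERATE -> hom-ALT filter chain.
    """
    qual_pass = ds_vars["qual"].to_numpy() > 500.0
    impact_pass = ds_vars["impact"].isin(["HIGH", "MODERATE"]).to_numpy()
    hom_alt_present = (genotypes == 2).any(axis=0)
    chain = qual_pass & impact_pass & hom_alt_present
    chain_genes = sorted(ds_vars.loc[chain, "gene_id"].unique())

    a_alt = genotypes[:, drivers["A"]] == 2
    d_alt = genotypes[:, drivers["D"]] == 2
    a_ref = genotypes[:, drivers["A"]] == 0
    d_ref = genotypes[:, drivers["D"]] == 0
    loci = panel.loci
    driver_info = {
        key: {
            "locus_index": int(drivers[key]),
            "chrom": str(loci.iloc[drivers[key]]["chrom"]),
            "pos": int(loci.iloc[drivers[key]]["pos"]),
            "gene_id": _nearest_gene(genes, str(loci.iloc[drivers[key]]["chrom"]),
                                     int(loci.iloc[drivers[key]]["pos"])),
        }
        for key in ("A", "D")
    }
    return {
        "n_founders": config.n_founders,
        "n_rils": config.n_rils,
        "n_variants": int(len(ds_vars)),
        "n_qual_pass": int(qual_pass.sum()),
        "n_impact_pass": int(impact_pass.sum()),
        "n_hom_alt_present": int(hom_alt_present.sum()),
        "n_chain_records": int(chain.sum()),
        "n_chain_genes": len(chain_genes),
        "chain_genes": chain_genes,
        "eqtl_genes": [
            {
                "gene_id": gid,
                "locus_index": int(locus),
                "chrom": str(loci.iloc[locus]["chrom"]),
                "pos": int(loci.iloc[locus]["pos"]),
            }
            for gid, locus in sorted(eqtl_map.items())
        ],
        "driver_a": driver_info["A"],
        "driver_d": driver_info["D"],
        "class_sizes": {
            "REF/REF": int((a_ref & d_ref).sum()),
            "REF/ALT": int((a_ref & d_alt).sum()),
            "ALT/REF": int((a_alt & d_ref).sum()),
            "ALT/ALT": int((a_alt & d_alt).sum()),
        },
        "het_fraction": float((genotypes == 1).mean()),
    }


def simulate_dataset(config: SimConfig | None = None) -> MagicDataset:
    """Run the full generator: founders, RILs, transcriptomes, phenotype, VCF fields."""
    config = config or SimConfig()
    panel = simulate_founders(config)
    genotypes = simulate_rils(panel, config)
    genes = _gene_table(config)
    drivers = designate_drivers(panel, config)
    eqtl_map = eqtl_assignment(panel, config, genes)
    expr8, _ = simulate_expression(genotypes, panel, config, "8DPA", genes, eqtl_map)
    expr16, _ = simulate_expression(genotypes, panel, config, "16DPA", genes, eqtl_map)
    phenotype = simulate_phenotype(genotypes, config, drivers=drivers)
    variants = _variant_table(panel, genotypes, genes, drivers, config)
    manifest = _build_manifest(variants, genotypes, panel, genes, eqtl_map, drivers, config)
    ril_ids = [f"RIL{r + 1:03d}" for r in range(config.n_rils)]
    return MagicDataset(
        config=config,
        panel=panel,
        genotypes=genotypes,
        ril_ids=ril_ids,
        genes=genes,
        eqtl_map=eqtl_map,
        drivers=drivers,
        expression={"8DPA": expr8, "16DPA": expr16},
        phenotype=phenotype,
        variants=variants,
        manifest=manifest,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(ds: MagicDataset, path: Path) -> None:
    """Serialize the simulated variants as VCF v4.2 with SnpEff-style ANN INFO."""
    lines = ["##fileformat=VCFv4.2", "##source=cottonmine-simulate"]
    for c in range(ds.config.n_chromosomes):
        lines.append(f"##contig=<ID={_chrom_name(c)},length={ds.config.chrom_length_bp}>")
    lines.append(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | "
        "Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | "
        "CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'\">"
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ds.ril_ids))
    for i, row in enumerate(ds.variants.itertuples(index=False)):
        term = _EFFECT_TERM[row.impact]
        ann = (
            f"{row.alt}|{term}|{row.impact}|{row.gene_id}|{row.gene_id}"
            f"|transcript|{row.gene_id}.1|protein_coding||||||||"
        )
        gts = "\t".join(_GT_STR[int(g)] for g in ds.genotypes[:, i])
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{row.qual:g}\t.\t"
            f"ANN={ann}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(ds: MagicDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset to disk; returns the paths written.

    Emits ``variants.vcf``, one expression TSV per timepoint, gene lengths,
    ``phenotype.csv``, gene coordinates, QTL intervals flanking the two
    driver loci (±2 Mb), and the ground-truth ``manifest.json``.
    """
    out = Path(directory)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {"vcf": out / "variants.vcf"}
        write_vcf(ds, paths["vcf"])
        for tp, mat in ds.expression.items():
            p = out / f"expression_{tp}.tsv"
            mat.values.to_csv(p, sep="\t", float_format="%.6g")
            paths[f"expression_{tp}"] = p
        paths["gene_lengths"] = out / "gene_lengths.tsv"
        ds.expression["8DPA"].gene_length_bp.to_frame().to_csv(paths["gene_lengths"], sep="\t")
        paths["phenotype"] = out / "phenotype.csv"
        ds.phenotype.to_csv(paths["phenotype"], index=False, float_format="%.6g")
        paths["gene_coords"] = out / "gene_coords.tsv"
        ds.genes[["gene_id", "chrom", "start", "end"]].to_csv(
            paths["gene_coords"], sep="\t", index=False
        )
        paths["qtl"] = out / "qtl_intervals.tsv"
        qtl_rows = []
        for key in ("A", "D"):
            info = ds.manifest[f"driver_{key.lower()}"]
            qtl_rows.append(
                {
                    "trait": f"STR-q{info['chrom']}",
                    "chrom": info["chrom"],
                    "start": max(1, info["pos"] - 2_000_000),
                    "end": info["pos"] + 2_000_000,
                }
            )
        pd.DataFrame(qtl_rows).to_csv(paths["qtl"], sep="\t", index=False)
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(ds.manifest, indent=1, sort_keys=True) + "\n")
        return paths
    except OSError as exc:
        raise IOError(f"cannot write dataset to {out}: {exc}") from exc
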