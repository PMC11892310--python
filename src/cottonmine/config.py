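"""Configuration for the synthetic MAGIC-RIL dataset generator."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic MAGIC-RIL study.

    Defaults emulate the population the analysis assumes: 11 founder lines,
    550 recombinant inbred lines (RILs), near-complete homozygosity after
    single-seed descent, and fiber transcriptomes in which ~10% of genes
    carry an expression QTL with a strong (5-fold) allelic effect.

    Parameters
    ----------
    n_founders:
        Founder lines of the multi-parent cross.
    n_rils:
        Recombinant inbred lines derived from the founders.
    n_chromosomes, loci_per_chromosome:
        Biallelic variant loci simulated per chromosome.
    recomb_rate:
        Expected crossovers per chromosome accumulated in a RIL's final
        founder mosaic (Poisson), i.e. over all meioses of the breeding
        design, not per single meiosis.
    residual_het_rate:
        Probability that a RIL locus remains heterozygous after inbreeding.
    n_genes:
        Genes in the expression tables.
    frac_eqtl:
        Fraction of genes whose expression is driven by a genotyped locus.
    eqtl_fold:
        Multiplicative expression effect of the homozygous ALT genotype
        (het gets sqrt(fold)); must be >= 1.
    noise_cv:
        Coefficient of variation of the lognormal multiplicative
        expression noise.
    pheno_mu, beta_a, beta_d, beta_interact, pheno_sigma:
        Phenotype model: mu + beta_a*I(A=hom-ALT) + beta_d*I(D=hom-ALT)
        + beta_interact*I(both) + Normal(0, sigma), in trait units
        (defaults are on a fiber-strength-like scale).
    impact_probs:
        Sampling weights of the synthetic SnpEff impact classes
        (HIGH, MODERATE, LOW, MODIFIER).
    seed:
        RNG seed; identical config + seed gives byte-identical outputs.
    """

    n_founders: int = 11
    n_rils: int = 550
    n_chromosomes: int = 2
    loci_per_chromosome: int = 50
    recomb_rate: float = 10.0
    residual_het_rate: float = 0.005
    n_genes: int = 2000
    frac_eqtl: float = 0.10
    eqtl_fold: float = 5.0
    noise_cv: float = 0.2
    pheno_mu: float = 30.0
    beta_a: float = 2.0
    beta_d: float = 1.0
    beta_interact: float = 0.0
    pheno_sigma: float = 1.0
    impact_probs: tuple[float, float, float, float] = (0.05, 0.20, 0.35, 0.40)
    chrom_length_bp: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_rils", "n_chromosomes", "loci_per_chromosome", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not 0.0 <= self.frac_eqtl <= 1.0:
            raise ConfigError(f"frac_eqtl must be in [0, 1], got {self.frac_eqtl}")
        if not 0.0 <= self.residual_het_rate <= 0.05:
            raise ConfigError(
                f"residual_het_rate must be in [0, 0.05], got {self.residual_het_rate}"
            )
        if self.recomb_rate < 0:
            raise ConfigError("recomb_rate must be >= 0")
        if self.eqtl_fold < 1:
            raise ConfigError("eqtl_fold must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.pheno_sigma < 0:
            raise ConfigError("pheno_sigma must be >= 0")
        if len(self.impact_probs) != 4 or min(self.impact_probs) < 0 or sum(self.impact_probs) <= 0:
            raise ConfigError("impact_probs must be four nonnegative weights")

    def replace(self, **kw) -> "SimConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kw)
        return SimConfig(**current)
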