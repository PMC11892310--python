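"""Two-locus epistasis analysis on RIL phenotypes.

RILs are stratified by their genotypes at two candidate loci into the four
homozygous classes (REF/REF, REF/ALT, ALT/REF, ALT/ALT); heterozygous or
missing lines are excluded and counted.  A two-way fixed-effects ANOVA with
main effects and interaction (Type II sums of squares for the unbalanced
design) tests whether the loci act additively, and Welch t-tests compare
each class against the best (highest-mean) class, mirroring how pairwise
significance against the top genotype is usually reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from cottonmine.errors import InsufficientDataError

logger = logging.getLogger(__name__)

CLASS_ORDER = ["REF/REF", "REF/ALT", "ALT/REF", "ALT/ALT"]


@dataclass
class TwoLocusDesign:
    """Retained RILs with homozygous calls at both loci and a phenotype value.

    ``data`` columns: ``A`` and ``D`` ("REF" or "ALT"), ``value`` (trait),
    ``genotype_class`` ("A-state/D-state"), plus one column per candidate
    gene if expression was attached.  ``n_excluded`` tallies why lines were
    dropped.
    """

    data: pd.DataFrame
    n_excluded: dict[str, int] = field(default_factory=dict)
    expression_genes: list[str] = field(default_factory=list)

    def class_sizes(self) -> pd.Series:
        return self.data["genotype_class"].value_counts().reindex(CLASS_ORDER, fill_value=0)


@dataclass
class AnovaResult:
    """Two-way ANOVA term table plus per-class summaries."""

    terms: pd.DataFrame  # index: A, D, A:D, Residual; columns: sum_sq, df, F, p
    groups: pd.DataFrame  # index: genotype class; columns: n, mean, sd


def stratify(
    genotypes_a: pd.Series,
    genotypes_d: pd.Series,
    phenotype: pd.Series,
    expression: pd.DataFrame | None = None,
) -> TwoLocusDesign:
    """Partition RILs into the four homozygous two-locus classes.

    Inputs are aligned on RIL id; genotypes are ALT dosages (0/1/2, negative
    or NaN = missing).  Heterozygous or missing lines are excluded and
    tallied.  ``expression`` (RILs x genes) optionally attaches candidate
    gene expression to each retained RIL.
    """
    ids = genotypes_a.index.intersection(genotypes_d.index).intersection(phenotype.index)
    a = genotypes_a.loc[ids].astype(float)
    d = genotypes_d.loc[ids].astype(float)
    y = phenotype.loc[ids].astype(float)
    het = (a == 1) | (d == 1)
    missing = a.isna() | d.isna() | (a < 0) | (d < 0) | y.isna()
    keep = ~(het | missing)
    n_excluded = {
        "heterozygous": int((het & ~missing).sum()),
        "missing": int(missing.sum()),
        "not_shared": int(
            len(set(genotypes_a.index) | set(genotypes_d.index) | set(phenotype.index)) - len(ids)
        ),
    }
    if keep.sum() == 0:
        raise InsufficientDataError("no RIL with homozygous calls at both loci and a phenotype")
    df = pd.DataFrame(
        {
            "A": np.where(a[keep] == 2, "ALT", "REF"),
            "D": np.where(d[keep] == 2, "ALT", "REF"),
            "value": y[keep],
        },
        index=ids[keep],
    )
    df["genotype_class"] = df["A"] + "/" + df["D"]
    genes: list[str] = []
    if expression is not None:
        for gene in expression.columns:
            df[gene] = expression[gene].reindex(df.index)
            genes.append(str(gene))
    return TwoLocusDesign(data=df, n_excluded=n_excluded, expression_genes=genes)


def _group_table(df: pd.DataFrame, response: str) -> pd.DataFrame:
    rows = []
    for cls in CLASS_ORDER:
        vals = df.loc[df["genotype_class"] == cls, response]
        rows.append(
            {
                "genotype_class": cls,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("genotype_class")


def _two_way_anova(df: pd.DataFrame, response: str) -> pd.DataFrame:
    model = smf.ols(f"Q('{response}') ~ C(A) * C(D)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(A)": "A", "C(D)": "D", "C(A):C(D)": "A:D"},
        columns={"PR(>F)": "p"},
    )
    return table[["sum_sq", "df", "F", "p"]]


def additive_anova(design: TwoLocusDesign, response: str = "value") -> AnovaResult:
    """Two-way ANOVA (A, D, A×D) on the 2×2 homozygous design.

    Unbalanced cell sizes — the rule in RIL data, where the favorable ALT
    class may be a small minority — are handled with Type II sums of
    squares.  Under a purely additive model the interaction sum of squares
    is (numerically) zero.
    """
    sizes = design.class_sizes()
    if (sizes >= 2).sum() < 3:
        raise InsufficientDataError(
            f"need >= 2 RILs in >= 3 of the 4 classes, got sizes {sizes.to_dict()}"
        )
    terms = _two_way_anova(design.data, response)
    groups = _group_table(design.data, response)
    return AnovaResult(terms=terms, groups=groups)


def contrasts_vs_best(
    design: TwoLocusDesign,
    alpha_levels: tuple[float, ...] = (0.01, 0.001),
    response: str = "value",
) -> pd.DataFrame:
    """Welch t-test of every class against the best (highest-mean) class.

    Returns one row per non-best class with t, df, p, and the finest of the
    stated alpha levels the comparison passes (NaN if none).  Singleton
    classes are skipped with a warning.
    """
    groups = _group_table(design.data, response)
    populated = groups[groups["n"] >= 2]
    if populated.empty:
        raise InsufficientDataError("no class with n >= 2")
    best = populated["mean"].idxmax()
    best_vals = design.data.loc[design.data["genotype_class"] == best, response]
    rows = []
    for cls in CLASS_ORDER:
        if cls == best:
            continue
        vals = design.data.loc[design.data["genotype_class"] == cls, response]
        if len(vals) < 2:
            logger.warning("skipping class %s with n=%d < 2", cls, len(vals))
            continue
        t_res = stats.ttest_ind(vals, best_vals, equal_var=False)
        passed = [a for a in sorted(alpha_levels, reverse=True) if t_res.pvalue < a]
        rows.append(
            {
                "genotype_class": cls,
                "best_class": best,
                "n": len(vals),
                "mean_diff": float(vals.mean() - best_vals.mean()),
                "t": float(t_res.statistic),
                "df": float(t_res.df),
                "p": float(t_res.pvalue),
                "alpha_passed": min(passed) if passed else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("genotype_class")


def genotype_expression_summary(design: TwoLocusDesign) -> dict[str, AnovaResult]:
    """Per-class expression summaries and per-gene two-way ANOVA.

    For each attached candidate gene, summarizes expression per genotype
    class and tests (ANOVA on expression) whether the gene responds to its
    own locus only — i.e. whether the other locus or the combination has
    any effect on it.
    """
    if not design.expression_genes:
        raise ValueError("design carries no expression columns")
    out: dict[str, AnovaResult] = {}
    for gene in design.expression_genes:
        sub = design.data.dropna(subset=[gene])
        sub_design = TwoLocusDesign(data=sub, expression_genes=[gene])
        out[gene] = AnovaResult(
            terms=_two_way_anova(sub, gene),
            groups=_group_table(sub, gene),
        )
    return out
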