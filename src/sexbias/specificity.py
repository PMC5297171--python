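"""Sex-specificity classification from cross-sex maximal expression.

Each non-Y gene is summarized by its maximal trimmed-mean expression in each
sex, taken over all tissues of that sex (sex-limited tissues included).  The
ratio of the two maxima places the gene in one of the bands:

* sex-specific — ratio >= 4 with the lower maximum >= 1 RPKM, or ratio >= 2
  when the higher maximum is >= 1 RPKM but the lower is below 1 RPKM;
* moderately sex-specific — ratio in [2, 4) with the lower maximum >= 1 RPKM;
* sex-similar — maxima within 1.1-fold of each other;
* unclassified — anything else (including genes whose higher maximum is
  below 1 RPKM).

Band lower bounds are inclusive.  Significance of a specific call is tested
by comparing samples of the higher sex's maximal tissue against samples of
the other sex's maximal tissue with the population permutation engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import ExpressionMatrix, TissueSexSummary
from .sde import de_probability_population

__all__ = [
    "CATEGORIES",
    "SpecificityCall",
    "max_sex_expression",
    "classify_specificity",
    "specificity_significance",
    "classify_all",
]

WOMEN_SPECIFIC = "women-specific"
MEN_SPECIFIC = "men-specific"
MOD_WOMEN = "moderately-women-specific"
MOD_MEN = "moderately-men-specific"
SEX_SIMILAR = "sex-similar"
UNCLASSIFIED = "unclassified"
CATEGORIES = (WOMEN_SPECIFIC, MOD_WOMEN, MEN_SPECIFIC, MOD_MEN, SEX_SIMILAR, UNCLASSIFIED)

INFORMATIVE_RPKM = 1.0
SPECIFIC_FOLD = 4.0
LOW_EXPR_FOLD = 2.0
SIMILAR_FOLD = 1.1


@dataclass
class SpecificityCall:
    gene: str
    max_w: float
    tissue_w: str
    max_m: float
    tissue_m: str
    ratio: float  # max_w / max_m, inf when max_m == 0
    category: str
    probability: float | None = None


def max_sex_expression(
    summary: TissueSexSummary, gene: str
) -> tuple[float, str, float, str]:
    """Maximal trimmed-mean expression and its tissue, per sex.

    Maxima are taken over every tissue with samples of the given sex,
    sex-limited tissues included.  Ties resolve to the first tissue in
    column order.  Returns ``(max_w, tissue_w, max_m, tissue_m)``.
    """
    if gene not in summary.data.index:
        raise KeyError(f"gene {gene!r} not in summary")
    row = summary.data.loc[gene]
    out = {}
    for sex in ("F", "M"):
        cells = row[[c for c in row.index if c[1] == sex]]
        if cells.empty:
            raise ValueError(f"no tissues with {sex} samples")
        out[sex] = (float(cells.max()), cells.idxmax()[0])
    return out["F"][0], out["F"][1], out["M"][0], out["M"][1]


def classify_specificity(max_w: float, max_m: float) -> str:
    """Assign a sex-specificity category from the two per-sex maxima."""
    if max_w < 0 or max_m < 0:
        raise ValueError("maxima must be non-negative")
    higher, lower = max(max_w, max_m), min(max_w, max_m)
    if higher < INFORMATIVE_RPKM:
        # too lowly expressed in both sexes to support any call
        return UNCLASSIFIED
    women_higher = max_w >= max_m
    ratio = float("inf") if lower == 0 else higher / lower
    if lower >= INFORMATIVE_RPKM and ratio >= SPECIFIC_FOLD:
        return WOMEN_SPECIFIC if women_higher else MEN_SPECIFIC
    if lower < INFORMATIVE_RPKM and ratio >= LOW_EXPR_FOLD:
        return WOMEN_SPECIFIC if women_higher else MEN_SPECIFIC
    if lower >= INFORMATIVE_RPKM and LOW_EXPR_FOLD <= ratio < SPECIFIC_FOLD:
        return MOD_WOMEN if women_higher else MOD_MEN
    if ratio <= SIMILAR_FOLD:
        return SEX_SIMILAR
    return UNCLASSIFIED


def specificity_significance(
    matrix: ExpressionMatrix,
    gene: str,
    tissue_w: str,
    tissue_m: str,
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """DE probability between the two sexes' maximal tissues for one gene.

    Women samples from ``tissue_w`` are compared with men samples from
    ``tissue_m`` using the population permutation engine; both groups must
    have at least three samples.
    """
    w_samples = matrix.select_samples(sex="F", tissue=tissue_w)
    m_samples = matrix.select_samples(sex="M", tissue=tissue_m)
    if len(w_samples) < 3 or len(m_samples) < 3:
        raise ValueError("both maximal tissues need at least 3 samples of the tested sex")
    vals_w = matrix.values.loc[gene, w_samples].to_numpy()
    vals_m = matrix.values.loc[gene, m_samples].to_numpy()
    return de_probability_population(
        vals_w, vals_m, n_perm=n_perm, seed=seed, gene=gene
    ).probability


def classify_all(
    summary: TissueSexSummary,
    matrix: ExpressionMatrix | None = None,
    exclude_genes: set[str] | None = None,
    n_perm: int = 2000,
    seed: int | None = None,
    test_specific: bool = True,
) -> pd.DataFrame:
    """Classify every gene in the summary; optionally test specific calls.

    ``exclude_genes`` removes genes (typically Y-linked ones) before
    classification.  When ``matrix`` is given and ``test_specific`` is True,
    genes in a specific or moderately specific band also get a significance
    probability from :func:`specificity_significance`.
    """
    rows = []
    excl = exclude_genes or set()
    for i, gene in enumerate(g for g in summary.genes if g not in excl):
        max_w, t_w, max_m, t_m = max_sex_expression(summary, gene)
        category = classify_specificity(max_w, max_m)
        ratio = max_w / max_m if max_m > 0 else float("inf")
        prob = None
        if (
            test_specific
            and matrix is not None
            and category in (WOMEN_SPECIFIC, MEN_SPECIFIC, MOD_WOMEN, MOD_MEN)
        ):
            prob = specificity_significance(
                matrix, gene, t_w, t_m, n_perm=n_perm,
                seed=None if seed is None else seed + i,
            )
        rows.append((gene, max_w, t_w, max_m, t_m, ratio, category, prob))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "max_w", "tissue_w", "max_m", "tissue_m",
            "ratio", "category", "probability",
        ],
    ).set_index("gene_id")
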