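"""Sex-differential expression: probability engines, the SDE score, clustering.

Two differential-expression engines provide probabilities in [0, 1]:

* a population engine — a label-permutation test on the absolute difference
  of trimmed means, treating the donor population as biological replicates;
* a multinomial-simulation engine — pseudo-replicates are simulated from a
  multinomial read model around the per-condition trimmed-mean count
  summaries, and a gene's probability is the fraction of the within-condition
  null (|M|, |D|) cloud dominated by its observed fold-change/difference pair.

The engines are complementary: the simulation engine can flag genes whose
expression is driven by a sample subset that a population test averages away.
A gene detected only there is flagged when its simulation probability is at
least 0.8 and exceeds the population probability by at least 0.2.

The SDE score normalizes the expression difference between sexes by the
gene's maximal expression across all tissues:

    SDE = log2((1 + EXPR_w / MAX) / (1 + EXPR_m / MAX))

ranging from 1 (women-exclusive at the gene's maximum) through 0 (equal) to
-1 (men-exclusive).  The score matrix holds zeros for non-significant cells
and is the substrate for medoid-based pattern clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import TissueSexSummary, trimmed_mean, trimmed_mean_rows

__all__ = [
    "DEProbability",
    "de_probability_population",
    "de_probability_population_matrix",
    "noiseq_sim_probability",
    "sde_score",
    "build_sde_matrix",
    "complementary_detection",
    "cluster_sde_patterns",
    "sample_size_correlation",
]

MIN_GROUP = 3
BACKGROUND_CLUSTER = -1


@dataclass(frozen=True)
class DEProbability:
    """A differential-expression probability for one gene in one tissue."""

    probability: float
    engine: str  # "population-permutation" | "multinomial-sim"
    gene: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")


# ---------------------------------------------------------------------------
# population (permutation) engine
# ---------------------------------------------------------------------------

def de_probability_population_matrix(
    values_w: np.ndarray,
    values_m: np.ndarray,
    n_perm: int = 2000,
    seed: int | None = None,
) -> np.ndarray:
    """Vectorized permutation probabilities for many genes at once.

    ``values_w``/``values_m`` are genes x samples arrays for the two groups.
    All genes share the same label permutations, which is what a whole-tissue
    scan does in practice and keeps the cost at one shuffle per permutation.
    Probability = 1 - (r + 1)/(n_perm + 1) with r the number of permutations
    whose absolute trimmed-mean difference reaches the observed one.
    """
    values_w = np.atleast_2d(np.asarray(values_w, dtype=float))
    values_m = np.atleast_2d(np.asarray(values_m, dtype=float))
    n_w, n_m = values_w.shape[1], values_m.shape[1]
    if n_w < MIN_GROUP or n_m < MIN_GROUP:
        raise ValueError(f"each group needs at least {MIN_GROUP} samples")
    if values_w.shape[0] != values_m.shape[0]:
        raise ValueError("group matrices must have the same number of genes")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([values_w, values_m], axis=1)
    n = n_w + n_m
    observed = np.abs(trimmed_mean_rows(values_w) - trimmed_mean_rows(values_m))
    exceed = np.zeros(pooled.shape[0], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        diff = np.abs(
            trimmed_mean_rows(pooled[:, idx[:n_w]]) - trimmed_mean_rows(pooled[:, idx[n_w:]])
        )
        exceed += diff >= observed
    p = (exceed + 1) / (n_perm + 1)
    return 1.0 - p


def de_probability_population(
    values_w: Sequence[float],
    values_m: Sequence[float],
    n_perm: int = 2000,
    seed: int | None = None,
    gene: str | None = None,
    tissue: str | None = None,
) -> DEProbability:
    """Permutation probability that one gene is differentially expressed.

    The statistic is the absolute difference of the two groups' trimmed
    means; labels are shuffled ``n_perm`` times and the empirical p-value
    uses the (r+1)/(n_perm+1) correction.  The returned probability is
    1 - p, on the same scale as the 0.95 significance cutoff.
    """
    prob = de_probability_population_matrix(
        np.asarray(values_w, dtype=float)[None, :],
        np.asarray(values_m, dtype=float)[None, :],
        n_perm=n_perm,
        seed=seed,
    )[0]
    return DEProbability(float(prob), "population-permutation", gene, tissue)


# ---------------------------------------------------------------------------
# multinomial-simulation engine
# ---------------------------------------------------------------------------

def noiseq_sim_probability(
    counts_w: Sequence[float],
    counts_m: Sequence[float],
    library_size: float | None = None,
    n_sim: int = 200,
    seed: int | None = None,
    max_null_points: int = 50_000,
) -> np.ndarray:
    """Simulation probabilities from multinomial pseudo-replicates, per gene.

    ``counts_w``/``counts_m`` are per-gene count summaries (trimmed means of
    raw counts) standing in for one sample per condition.  Reads are assumed
    multinomial with feature probabilities equal to each gene's share of the
    condition's reads; ``n_sim`` pseudo-replicates per condition are drawn at
    ``library_size`` total reads (default: the mean of the two observed
    totals).  For each gene the observed statistics are M = log2 fold change
    and D = absolute difference of CPM-normalized counts (zeros offset by
    0.5); the null cloud pools within-condition replicate pairs across all
    genes, and the probability is the fraction of the null cloud strictly
    dominated by the observed (|M|, |D|).
    """
    w = np.asarray(counts_w, dtype=float)
    m = np.asarray(counts_m, dtype=float)
    if w.ndim != 1 or m.shape != w.shape:
        raise ValueError("count summaries must be 1-D and equal length")
    if (w < 0).any() or (m < 0).any():
        raise ValueError("counts must be non-negative")
    if w.sum() == 0 or m.sum() == 0:
        raise ValueError("all-zero count vector")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    if library_size is None:
        library_size = 0.5 * (w.sum() + m.sum())
    total = int(round(library_size))

    def cpm(x: np.ndarray) -> np.ndarray:
        x = np.where(x == 0, 0.5, x)
        return x / x.sum(axis=-1, keepdims=True) * 1e6

    obs_w, obs_m = cpm(w), cpm(m)
    obs_mstat = np.abs(np.log2(obs_w / obs_m))
    obs_d = np.abs(obs_w - obs_m)

    null_m_parts, null_d_parts = [], []
    for cond in (w, m):
        p = cond / cond.sum()
        sims = rng.multinomial(total, p, size=n_sim).astype(float)
        a, b = cpm(sims[: n_sim // 2]), cpm(sims[n_sim // 2 : 2 * (n_sim // 2)])
        null_m_parts.append(np.abs(np.log2(a / b)).ravel())
        null_d_parts.append(np.abs(a - b).ravel())
    null_m = np.concatenate(null_m_parts)
    null_d = np.concatenate(null_d_parts)
    if null_m.size > max_null_points:
        pick = rng.choice(null_m.size, max_null_points, replace=False)
        null_m, null_d = null_m[pick], null_d[pick]

    # dominance fraction per gene, chunked to bound memory
    probs = np.empty(w.size)
    chunk = max(1, int(2e7) // max(null_m.size, 1))
    for start in range(0, w.size, chunk):
        sl = slice(start, start + chunk)
        dom = (obs_mstat[sl, None] > null_m[None, :]) & (obs_d[sl, None] > null_d[None, :])
        probs[sl] = dom.mean(axis=1)
    return probs


def complementary_detection(prob_sim: float, prob_population: float) -> bool:
    """Flag genes the simulation engine finds that the population engine misses.

    True when the simulation probability is at least 0.8 and the population
    probability is at least 0.2 smaller.
    """
    for p in (prob_sim, prob_population):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    return prob_sim >= 0.8 and prob_population <= prob_sim - 0.2


# ---------------------------------------------------------------------------
# the SDE score and score matrix
# ---------------------------------------------------------------------------

def sde_score(expr_w: float, expr_m: float, max_expr: float) -> float:
    """Normalized sex-differential expression score in [-1, 1].

    ``log2((1 + expr_w/max_expr) / (1 + expr_m/max_expr))`` where
    ``max_expr`` is the gene's maximal expression over all tissues (including
    sex-limited ones).  1 means women-exclusive expression at the gene's
    maximum, -1 the mirror case, 0 equality; sub-maximal tissues yield
    proportionally smaller magnitudes.
    """
    if max_expr <= 0:
        raise ValueError("max_expr must be positive")
    if not (0 <= expr_w <= max_expr) or not (0 <= expr_m <= max_expr):
        raise ValueError("expression values must lie in [0, max_expr]")
    return float(np.log2((1 + expr_w / max_expr) / (1 + expr_m / max_expr)))


def build_sde_matrix(
    summary: TissueSexSummary,
    probabilities: pd.DataFrame,
    cutoff: float = 0.95,
    extra_significant: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genes x common-tissues matrix of SDE scores, zero where non-significant.

    ``probabilities`` is a genes x common-tissues frame of DE probabilities;
    a cell receives its SDE score when the probability reaches ``cutoff``
    (inclusive) or the matching cell of ``extra_significant`` (a boolean
    frame, e.g. complementary-detection flags) is True; otherwise 0.  The
    per-gene maximum is taken over all tissues including sex-limited ones.
    """
    common = summary.common_tissues
    genes = summary.genes
    max_g = summary.data.max(axis=1)
    scores = pd.DataFrame(0.0, index=genes, columns=common)
    for tissue in common:
        sig = pd.Series(False, index=genes)
        if tissue in probabilities.columns:
            sig |= probabilities[tissue].reindex(genes).fillna(0.0) >= cutoff
        if extra_significant is not None and tissue in extra_significant.columns:
            sig |= extra_significant[tissue].reindex(genes).fillna(False).astype(bool)
        if not sig.any():
            continue
        if (tissue, "F") not in summary.data.columns or (tissue, "M") not in summary.data.columns:
            raise KeyError(f"missing summary cell for significant calls in {tissue}")
        w = summary.data[(tissue, "F")]
        m = summary.data[(tissue, "M")]
        with np.errstate(divide="ignore", invalid="ignore"):
            col = np.log2((1 + w / max_g) / (1 + m / max_g))
        col = col.fillna(0.0)  # MAX_g == 0 means no expression anywhere
        scores.loc[sig, tissue] = col[sig]
    return scores


# ---------------------------------------------------------------------------
# pattern clustering and diagnostics
# ---------------------------------------------------------------------------

def cluster_sde_patterns(
    matrix: pd.DataFrame, k: int, seed: int | None = None, max_iter: int = 100
) -> pd.Series:
    """Partition genes around medoids by their SDE score patterns.

    Euclidean k-medoids (random seeded initialization, alternating
    assignment and medoid update until stable).  Rows that are entirely
    zero — genes significant nowhere — are assigned the background cluster
    label ``-1`` and excluded from the partition.
    """
    values = matrix.to_numpy(dtype=float)
    active = np.abs(values).sum(axis=1) > 0
    n_active = int(active.sum())
    if k < 2 or k >= n_active:
        raise ValueError(f"k must satisfy 2 <= k < {n_active} (genes with nonzero scores)")
    x = values[active]
    rng = np.random.default_rng(seed)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    medoids = rng.choice(n_active, size=k, replace=False)
    assign = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        new_assign = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    labels = np.full(matrix.shape[0], BACKGROUND_CLUSTER, dtype=int)
    labels[active] = assign
    return pd.Series(labels, index=matrix.index, name="cluster")


def sample_size_correlation(
    sde_counts: Mapping[str, int],
    sample_sizes: Mapping[str, int],
    exclude: Sequence[str] = (),
) -> float:
    """Pearson correlation between per-tissue sample size and SDE gene count.

    ``exclude`` removes tissues (e.g. an outlier tissue) before computing r.
    Raises when fewer than three tissues remain or either vector is constant.
    """
    tissues = sorted((set(sde_counts) & set(sample_sizes)) - set(exclude))
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues")
    x = np.array([sample_sizes[t] for t in tissues], dtype=float)
    y = np.array([sde_counts[t] for t in tissues], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in sample sizes or SDE counts")
    r, _ = stats.pearsonr(x, y)
    return float(r)
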