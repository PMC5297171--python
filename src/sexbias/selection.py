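"""Coding-substitution enumeration and purifying-selection statistics.

For each transcript every possible single-nucleotide substitution (3 per
coding position) is classified by its protein consequence: synonymous (S),
non-synonymous (NS), stop-gain, stop-loss, or stop-to-stop ("other").  A
deleteriousness labeler partitions possible NS substitutions into deleterious
(DNS) and benign.  Mutation rates are observed/possible counts per consequence
class; the selection signatures are the ratios dDNS/dS and dStop/dS, computed
over gene sets with MAF thresholds (deleterious NS above 0.005, stop-gain
above 0.001), with randomization over same-size random gene sets providing
empirical significance and Fisher's exact test comparing two groups.

Ratios near 1 indicate neutrality; below 1, purifying selection; the weaker
the purifying selection on a gene set, the closer its ratios sit to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

__all__ = [
    "UndefinedRateError",
    "TranscriptModel",
    "VariantRecord",
    "SubstitutionSpectrum",
    "SelectionResult",
    "CONSEQUENCE_CLASSES",
    "annotate_substitution",
    "enumerate_substitutions",
    "enumerate_possible_substitutions",
    "combine_deleteriousness",
    "compute_rate",
    "selection_ratios",
    "maf_bin_distribution",
    "randomization_test",
    "compare_groups_fisher",
]

NUCLEOTIDES = ("A", "C", "G", "T")
CONSEQUENCE_CLASSES = ("S", "NS", "stop-gain", "stop-loss", "other")

#: predictor label vocabularies; keys are the labels each tool may emit and
#: values say whether that label counts as a deleterious call.
PREDICTOR1_LABELS = {"deleterious": True, "tolerated": False}
PREDICTOR2_LABELS = {
    "deleterious": True,
    "probably-damaging": True,
    "possibly-damaging": False,
    "benign": False,
}


class UndefinedRateError(ValueError):
    """Raised when a rate's denominator (possible substitutions) is zero."""


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript: gene id, chromosome class and in-frame CDS."""

    gene_id: str
    chromosome: str  # "autosome" | "X" | "Y" | "PAR1"
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0 or len(self.cds) < 9:
            raise ValueError(f"{self.gene_id}: CDS length must be a multiple of 3, >= 9")
        if not set(self.cds) <= set(NUCLEOTIDES):
            raise ValueError(f"{self.gene_id}: CDS contains non-ACGT characters")
        if self.cds[:3] != "ATG":
            raise ValueError(f"{self.gene_id}: CDS must start with ATG")
        aa = str(Seq(self.cds).translate())
        if aa[-1] != "*":
            raise ValueError(f"{self.gene_id}: CDS must end with a stop codon")
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon")

    def __len__(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class VariantRecord:
    """An observed coding substitution with population frequency and predictor calls."""

    gene_id: str
    cds_pos: int  # 1-based
    ref: str
    alt: str
    maf: float
    consequence: str
    predictor1: str = "tolerated"
    predictor2: str = "benign"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} outside (0, 0.5]")


@dataclass
class SubstitutionSpectrum:
    """Per-gene counts of possible substitutions by consequence class."""

    gene_id: str
    possible: dict[str, int] = field(default_factory=dict)  # S, NS, DNS, stop-gain

    def __getitem__(self, key: str) -> int:
        return self.possible.get(key, 0)


@dataclass
class SelectionResult:
    """Pooled selection statistics for one gene set."""

    set_id: str
    n_genes: int
    d_s_dns: float  # dS at the DNS MAF threshold
    d_dns: float
    d_s_stop: float  # dS at the stop-gain MAF threshold
    d_stop: float
    dns_ratio: float  # dDNS/dS, nan when undefined
    stop_ratio: float  # dStop/dS
    dns_ratio_defined: bool = True
    stop_ratio_defined: bool = True
    dns_p: float | None = None
    stop_p: float | None = None
    random_dns_mean: float | None = None
    random_dns_std: float | None = None
    random_stop_mean: float | None = None
    random_stop_std: float | None = None


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

def _classify_codon_change(ref_codon: str, alt_codon: str) -> str:
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == "*" and alt_aa == "*":
        return "other"
    if ref_aa == "*":
        return "stop-loss"
    if alt_aa == "*":
        return "stop-gain"
    return "S" if ref_aa == alt_aa else "NS"


# consequence of substituting position i (0..2) of `codon` with `alt`,
# precomputed for all 64 codons x 3 positions x 3 alternates
_CODON_SUB_TABLE: dict[tuple[str, int, str], str] = {}
for _codon in ("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)):
    for _i in range(3):
        for _alt in NUCLEOTIDES:
            if _alt == _codon[_i]:
                continue
            _mut = _codon[:_i] + _alt + _codon[_i + 1 :]
            _CODON_SUB_TABLE[(_codon, _i, _alt)] = _classify_codon_change(_codon, _mut)


def annotate_substitution(cds: str, cds_pos: int, ref: str, alt: str) -> str:
    """Protein consequence of a single-nucleotide substitution in a CDS.

    ``cds_pos`` is 1-based.  Raises on a reference mismatch, an out-of-range
    position, or ``ref == alt``.
    """
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"position {cds_pos} outside CDS of length {len(cds)}")
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"invalid alleles {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if cds[cds_pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {cds_pos}: CDS has {cds[cds_pos - 1]}, got {ref}"
        )
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    return _CODON_SUB_TABLE[(codon, within, alt)]


def enumerate_substitutions(cds: str):
    """Yield ``(cds_pos, ref, alt, consequence)`` for all 3L possible substitutions."""
    for pos0, ref in enumerate(cds):
        codon_idx = pos0 // 3
        within = pos0 % 3
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        for alt in NUCLEOTIDES:
            if alt == ref:
                continue
            yield pos0 + 1, ref, alt, _CODON_SUB_TABLE[(codon, within, alt)]


def enumerate_possible_substitutions(
    transcript: TranscriptModel,
    deleterious_labeler: Callable[[str, int, str, str], bool],
) -> SubstitutionSpectrum:
    """Count possible substitutions per consequence class for one transcript.

    ``deleterious_labeler(gene_id, cds_pos, ref, alt) -> bool`` marks each
    possible NS substitution as deleterious (counted in DNS) or benign.
    Stop-loss and stop-to-stop changes (the terminal codon's substitutions)
    are tallied separately and excluded from the S/NS/stop-gain denominators.
    """
    counts = {"S": 0, "NS": 0, "DNS": 0, "stop-gain": 0, "stop-loss": 0, "other": 0}
    for pos, ref, alt, csq in enumerate_substitutions(transcript.cds):
        counts[csq] += 1
        if csq == "NS" and deleterious_labeler(transcript.gene_id, pos, ref, alt):
            counts["DNS"] += 1
    return SubstitutionSpectrum(transcript.gene_id, counts)


def combine_deleteriousness(predictor1_label: str, predictor2_label: str) -> bool:
    """True only when both predictors call the substitution deleterious."""
    try:
        a = PREDICTOR1_LABELS[predictor1_label]
    except KeyError:
        raise ValueError(f"unknown predictor1 label {predictor1_label!r}") from None
    try:
        b = PREDICTOR2_LABELS[predictor2_label]
    except KeyError:
        raise ValueError(f"unknown predictor2 label {predictor2_label!r}") from None
    return a and b


# ---------------------------------------------------------------------------
# rates and ratios
# ---------------------------------------------------------------------------

def compute_rate(observed: int, possible: int) -> float:
    """Observed mutations of a type divided by all possible substitutions of that type."""
    if possible <= 0:
        raise UndefinedRateError("no possible substitutions of this type")
    if observed < 0 or observed > possible:
        raise ValueError("observed must be within [0, possible]")
    return observed / possible


def _variants_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    rows = [
        (v.gene_id, v.cds_pos, v.ref, v.alt, v.maf, v.consequence, v.predictor1, v.predictor2)
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "cds_pos", "ref", "alt", "maf",
            "consequence", "predictor1", "predictor2",
        ],
    )


def observed_counts(
    variants,
    genes: Iterable[str] | None = None,
    maf_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-gene observed S / DNS / stop-gain counts above a strict MAF threshold.

    A variant counts toward DNS when its consequence is NS and both predictors
    call it deleterious.
    """
    df = _variants_frame(variants)
    if genes is not None:
        df = df[df["gene_id"].isin(set(genes))]
    df = df[df["maf"] > maf_threshold]
    is_dns = (df["consequence"] == "NS") & np.array(
        [
            combine_deleteriousness(p1, p2)
            for p1, p2 in zip(df["predictor1"], df["predictor2"])
        ],
        dtype=bool,
    )
    out = pd.DataFrame(
        {
            "S": df[df["consequence"] == "S"].groupby("gene_id").size(),
            "DNS": df[is_dns].groupby("gene_id").size(),
            "stop-gain": df[df["consequence"] == "stop-gain"].groupby("gene_id").size(),
        }
    ).fillna(0).astype(int)
    if genes is not None:
        out = out.reindex(list(genes), fill_value=0)
    return out


def _pooled_ratio(obs_func: int, poss_func: int, obs_s: int, poss_s: int):
    """(rate_func/rate_S, defined?) with pooled counts; undefined when dS == 0."""
    if poss_func <= 0 or poss_s <= 0:
        return float("nan"), False
    d_func = obs_func / poss_func
    d_s = obs_s / poss_s
    if d_s == 0:
        return float("nan"), False
    return d_func / d_s, True


def selection_ratios(
    gene_set: Sequence[str],
    variants,
    spectra: Mapping[str, SubstitutionSpectrum],
    maf_dns: float = 0.005,
    maf_stop: float = 0.001,
    set_id: str = "set",
) -> SelectionResult:
    """Pooled dDNS/dS and dStop/dS for a gene set.

    Rates are pooled over the set (sum of observed over sum of possible).
    dDNS uses variants with MAF strictly above ``maf_dns``; dStop uses MAF
    strictly above ``maf_stop``; the synonymous rate in each ratio's
    denominator is computed at that ratio's own threshold, so each ratio
    compares classes on an identical frequency stratum.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in spectra]
    if missing:
        raise KeyError(f"no substitution spectrum for genes: {missing[:5]}")
    poss_s = sum(spectra[g]["S"] for g in genes)
    poss_dns = sum(spectra[g]["DNS"] for g in genes)
    poss_stop = sum(spectra[g]["stop-gain"] for g in genes)

    obs_dns_stratum = observed_counts(variants, genes, maf_dns).sum()
    obs_stop_stratum = observed_counts(variants, genes, maf_stop).sum()

    dns_ratio, dns_ok = _pooled_ratio(
        int(obs_dns_stratum["DNS"]), poss_dns, int(obs_dns_stratum["S"]), poss_s
    )
    stop_ratio, stop_ok = _pooled_ratio(
        int(obs_stop_stratum["stop-gain"]), poss_stop, int(obs_stop_stratum["S"]), poss_s
    )
    return SelectionResult(
        set_id=set_id,
        n_genes=len(genes),
        d_s_dns=int(obs_dns_stratum["S"]) / poss_s if poss_s else float("nan"),
        d_dns=int(obs_dns_stratum["DNS"]) / poss_dns if poss_dns else float("nan"),
        d_s_stop=int(obs_stop_stratum["S"]) / poss_s if poss_s else float("nan"),
        d_stop=int(obs_stop_stratum["stop-gain"]) / poss_stop if poss_stop else float("nan"),
        dns_ratio=dns_ratio,
        stop_ratio=stop_ratio,
        dns_ratio_defined=dns_ok,
        stop_ratio_defined=stop_ok,
    )


def per_gene_count_arrays(
    genes: Sequence[str],
    variants,
    spectra: Mapping[str, SubstitutionSpectrum],
    maf_dns: float = 0.005,
    maf_stop: float = 0.001,
) -> dict[str, np.ndarray]:
    """Aligned per-gene observed/possible count vectors used by the randomization test."""
    obs_dns = observed_counts(variants, genes, maf_dns)
    obs_stop = observed_counts(variants, genes, maf_stop)
    return {
        "poss_s": np.array([spectra[g]["S"] for g in genes], dtype=float),
        "poss_dns": np.array([spectra[g]["DNS"] for g in genes], dtype=float),
        "poss_stop": np.array([spectra[g]["stop-gain"] for g in genes], dtype=float),
        "obs_s_dns": obs_dns["S"].to_numpy(dtype=float),
        "obs_dns": obs_dns["DNS"].to_numpy(dtype=float),
        "obs_s_stop": obs_stop["S"].to_numpy(dtype=float),
        "obs_stop": obs_stop["stop-gain"].to_numpy(dtype=float),
    }


def _set_ratios_from_counts(counts: dict[str, np.ndarray], idx: np.ndarray):
    """dDNS/dS and dStop/dS for index sets (rows of idx); zero dS gives +inf."""
    def pooled(obs_f, poss_f, obs_s, poss_s):
        of = obs_f[idx].sum(axis=-1)
        pf = poss_f[idx].sum(axis=-1)
        os_ = obs_s[idx].sum(axis=-1)
        ps = poss_s[idx].sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (of / pf) / (os_ / ps)
        # a set with no observed synonymous variants cannot bound the ratio:
        # treat as infinitely relaxed (conservative for the >= tail)
        r = np.where((os_ == 0) | (pf == 0), np.inf, r)
        return r

    dns = pooled(counts["obs_dns"], counts["poss_dns"], counts["obs_s_dns"], counts["poss_s"])
    stop = pooled(counts["obs_stop"], counts["poss_stop"], counts["obs_s_stop"], counts["poss_s"])
    return dns, stop


def randomization_test(
    target_set: Sequence[str],
    pool: Sequence[str],
    variants,
    spectra: Mapping[str, SubstitutionSpectrum],
    n_iter: int = 10_000,
    seed: int | None = None,
    maf_dns: float = 0.005,
    maf_stop: float = 0.001,
    exhaustive: bool = False,
) -> SelectionResult:
    """Empirical significance of a gene set's ratios against random same-size sets.

    Random sets of ``len(target_set)`` genes are drawn (without replacement
    within a set) from ``pool`` — in the original design, all non-Y-linked,
    non-testis-specific protein-coding genes.  ``p = (r + 1) / (n_iter + 1)``
    where ``r`` counts random sets whose ratio is at least the target's
    (one-sided: the tested direction is reduced purifying selection, i.e. a
    higher ratio).  With ``exhaustive=True`` every subset of the pool is
    evaluated instead of sampling (small pools only).
    """
    target = list(target_set)
    pool = list(pool)
    k = len(target)
    if k == 0:
        raise ValueError("empty target set")
    if len(pool) < k:
        raise ValueError("pool smaller than target set size")

    result = selection_ratios(
        target, variants, spectra, maf_dns, maf_stop, set_id="target"
    )
    counts = per_gene_count_arrays(pool, variants, spectra, maf_dns, maf_stop)

    if exhaustive:
        idx = np.array(list(itertools.combinations(range(len(pool)), k)), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        # argpartition of a random matrix = n_iter draws without replacement
        noise = rng.random((n_iter, len(pool)))
        idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
    rand_dns, rand_stop = _set_ratios_from_counts(counts, idx)
    n_sets = idx.shape[0]

    def empirical_p(random_vals: np.ndarray, target_val: float, defined: bool):
        if not defined:
            return None
        r = int(np.sum(random_vals >= target_val))
        return (r + 1) / (n_sets + 1)

    finite_dns = rand_dns[np.isfinite(rand_dns)]
    finite_stop = rand_stop[np.isfinite(rand_stop)]
    result.dns_p = empirical_p(rand_dns, result.dns_ratio, result.dns_ratio_defined)
    result.stop_p = empirical_p(rand_stop, result.stop_ratio, result.stop_ratio_defined)
    result.random_dns_mean = float(finite_dns.mean()) if finite_dns.size else None
    result.random_dns_std = float(finite_dns.std(ddof=1)) if finite_dns.size > 1 else None
    result.random_stop_mean = float(finite_stop.mean()) if finite_stop.size else None
    result.random_stop_std = float(finite_stop.std(ddof=1)) if finite_stop.size > 1 else None
    return result


def compare_groups_fisher(
    observed_a: int, possible_a: int, observed_b: int, possible_b: int
) -> tuple[float, float, float]:
    """Compare one mutation-type rate between two gene groups.

    Builds the 2x2 table ``[[obs_a, poss_a - obs_a], [obs_b, poss_b - obs_b]]``
    and returns ``(rate fold-change a/b, odds ratio, two-sided exact p)``.
    """
    for obs, poss in ((observed_a, possible_a), (observed_b, possible_b)):
        if poss <= 0:
            raise ValueError("group with no possible substitutions")
        if obs < 0 or obs > poss:
            raise ValueError("observed must be within [0, possible]")
    table = [
        [observed_a, possible_a - observed_a],
        [observed_b, possible_b - observed_b],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    rate_b = observed_b / possible_b
    fold = (observed_a / possible_a) / rate_b if rate_b > 0 else float("inf")
    return float(fold), float(odds), float(p)


def maf_bin_distribution(
    genes: Sequence[str],
    variants,
    spectra: Mapping[str, SubstitutionSpectrum],
    bin_edges: Sequence[float],
    ratio_edges: Sequence[float] = (0.0, 0.1, 0.5, 1.0, 2.0, float("inf")),
) -> dict[str, pd.DataFrame]:
    """Histogram of per-gene ratio categories within each MAF bin.

    ``bin_edges`` define half-open MAF bins ``(e[i], e[i+1]]`` and must be
    strictly increasing.  Within each bin, each gene's dDNS/dS and dStop/dS
    are computed from the variants whose MAF falls in that bin; genes whose
    synonymous rate in the bin is zero fall into the ``"undefined"`` column.
    Returns one genes-per-category count table per statistic, indexed by bin.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    redges = list(ratio_edges)
    df = _variants_frame(variants)
    df = df[df["gene_id"].isin(set(genes))]

    poss = {
        g: (spectra[g]["S"], spectra[g]["DNS"], spectra[g]["stop-gain"]) for g in genes
    }
    bin_labels = [f"({lo:g}, {hi:g}]" for lo, hi in zip(edges, edges[1:])]
    cat_labels = [f"({lo:g}, {hi:g}]" for lo, hi in zip(redges, redges[1:])] + ["undefined"]
    out = {
        stat: pd.DataFrame(0, index=bin_labels, columns=cat_labels)
        for stat in ("dDNS/dS", "dStop/dS")
    }

    for label, lo, hi in zip(bin_labels, edges, edges[1:]):
        sub = df[(df["maf"] > lo) & (df["maf"] <= hi)]
        is_dns = (sub["consequence"] == "NS") & np.array(
            [
                combine_deleteriousness(p1, p2)
                for p1, p2 in zip(sub["predictor1"], sub["predictor2"])
            ],
            dtype=bool,
        )
        obs_s = sub[sub["consequence"] == "S"].groupby("gene_id").size()
        obs_dns = sub[is_dns].groupby("gene_id").size()
        obs_stop = sub[sub["consequence"] == "stop-gain"].groupby("gene_id").size()
        for g in genes:
            ps, pd_, pstop = poss[g]
            s = int(obs_s.get(g, 0))
            for stat, obs_f, poss_f in (
                ("dDNS/dS", int(obs_dns.get(g, 0)), pd_),
                ("dStop/dS", int(obs_stop.get(g, 0)), pstop),
            ):
                if ps == 0 or s == 0 or poss_f == 0:
                    out[stat].at[label, "undefined"] += 1
                    continue
                ratio = (obs_f / poss_f) / (s / ps)
                for cat, lo_r, hi_r in zip(cat_labels, redges, redges[1:]):
                    if lo_r < ratio <= hi_r or (ratio == 0 and lo_r == 0):
                        out[stat].at[label, cat] += 1
                        break
    return out


def per_gene_ratios(
    genes: Sequence[str],
    variants,
    spectra: Mapping[str, SubstitutionSpectrum],
    maf_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-gene dDNS/dS and dStop/dS above a strict MAF threshold (NaN when undefined)."""
    obs = observed_counts(variants, genes, maf_threshold)
    rows = []
    for g in genes:
        ps, pdns, pstop = spectra[g]["S"], spectra[g]["DNS"], spectra[g]["stop-gain"]
        s = int(obs.at[g, "S"])
        d_s = s / ps if ps else np.nan
        dns = (int(obs.at[g, "DNS"]) / pdns) / d_s if pdns and d_s else np.nan
        stp = (int(obs.at[g, "stop-gain"]) / pstop) / d_s if pstop and d_s else np.nan
        rows.append((g, dns, stp))
    return pd.DataFrame(rows, columns=["gene_id", "dDNS/dS", "dStop/dS"]).set_index("gene_id")
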