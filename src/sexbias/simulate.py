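"""Synthetic transcriptomes, expression matrices and variant catalogs.

The generator produces the three inputs the pipeline consumes — coding
sequences, a sex/tissue-structured expression matrix, and a coding-variant
table — together with the ground truth needed to score recovery:

* transcripts are random in-frame CDSs (uniform sense codons between an ATG
  and a single terminal stop);
* expression is negative-binomial read counts around per-(gene, tissue, sex)
  means, converted to RPKM at a nominal library size; planted gene classes
  scale one sex's mean in a target tissue so the cross-sex ratio of maximal
  expression equals the configured fold in expectation;
* variants are an accept/reject subsample of the gene's enumerated possible
  substitutions, with per-consequence acceptance probabilities acting as the
  selection regime, MAFs drawn from a rare-weighted stratified distribution,
  and two predictor labels that match the planted deleteriousness truth with
  a configurable concordance.

Everything is driven by a single integer seed; stage streams are spawned from
it so each stage is independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .selection import (
    SubstitutionSpectrum,
    TranscriptModel,
    enumerate_substitutions,
)

__all__ = [
    "EXPRESSION_CLASSES",
    "MafDistribution",
    "SelectionRegime",
    "SimulationConfig",
    "GroundTruth",
    "generate_transcriptome",
    "generate_expression",
    "plant_deleteriousness",
    "build_spectra",
    "generate_variants",
]

WOMEN_SPECIFIC = "women-specific"
MEN_SPECIFIC = "men-specific"
MOD_WOMEN = "moderately-women-specific"
MOD_MEN = "moderately-men-specific"
SDE_ONE_TISSUE = "sde-one-tissue"
SEX_SIMILAR = "sex-similar"
UNCONSTRAINED = "unconstrained"
EXPRESSION_CLASSES = (
    WOMEN_SPECIFIC, MEN_SPECIFIC, MOD_WOMEN, MOD_MEN, SDE_ONE_TISSUE, SEX_SIMILAR,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)

LIBRARY_SIZE_MILLIONS = 50.0  # nominal mapped reads per sample, in millions


@dataclass(frozen=True)
class MafDistribution:
    """Stratified minor-allele-frequency model weighted toward rare alleles.

    Three strata — rare (below 0.001), low (0.001–0.005) and common (above
    0.005) — receive the given probability masses; within a stratum the MAF
    is log-uniform.  The strata straddle both analysis thresholds so either
    branch of the MAF filtering is exercised.
    """

    p_rare: float = 0.70
    p_low: float = 0.15
    p_common: float = 0.15
    floor: float = 1e-4

    def __post_init__(self) -> None:
        probs = (self.p_rare, self.p_low, self.p_common)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("stratum masses must be non-negative and sum to 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        strata = rng.choice(3, size=size, p=[self.p_rare, self.p_low, self.p_common])
        bounds = [(self.floor, 0.001), (0.001, 0.005), (0.005, 0.5)]
        lo = np.array([bounds[s][0] for s in strata])
        hi = np.array([bounds[s][1] for s in strata])
        u = rng.random(size)
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


@dataclass(frozen=True)
class SelectionRegime:
    """Acceptance probability per consequence class for observed variants.

    Equal acceptance across classes is neutral; a lower functional acceptance
    relative to synonymous models purifying selection, and the planted
    dDNS/dS of a regime is ``dns / s``.  An optional per-regime MAF
    distribution couples allele frequency to the regime.
    """

    s: float = 0.10
    dns: float = 0.10
    ns_benign: float = 0.10
    stop: float = 0.10
    maf: MafDistribution | None = None

    def __post_init__(self) -> None:
        for p in (self.s, self.dns, self.ns_benign, self.stop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("acceptance probabilities must be in [0, 1]")


def _default_fractions() -> dict[str, float]:
    return {
        WOMEN_SPECIFIC: 0.05,
        MEN_SPECIFIC: 0.05,
        MOD_WOMEN: 0.05,
        MOD_MEN: 0.05,
        SDE_ONE_TISSUE: 0.10,
        SEX_SIMILAR: 0.50,
    }


def _default_regimes() -> dict[str, SelectionRegime]:
    # sex-specific classes sit under relaxed purifying selection relative to
    # the background: planted dDNS/dS 0.6 vs 0.25
    relaxed = SelectionRegime(s=0.10, dns=0.06, ns_benign=0.08, stop=0.06)
    background = SelectionRegime(s=0.10, dns=0.025, ns_benign=0.05, stop=0.02)
    return {
        WOMEN_SPECIFIC: relaxed,
        MEN_SPECIFIC: relaxed,
        MOD_WOMEN: relaxed,
        MOD_MEN: relaxed,
        SDE_ONE_TISSUE: background,
        SEX_SIMILAR: background,
        UNCONSTRAINED: background,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study in one place."""

    n_genes: int = 200
    n_tissues: int = 6
    samples_per_tissue_per_sex: int = 20
    cds_length_range: tuple[int, int] = (300, 900)
    planted_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_fold: float = 10.0
    moderate_fold: float = 3.0
    sde_fold: float = 2.0
    dispersion: float = 0.1
    selection_regimes: dict[str, SelectionRegime] = field(default_factory=_default_regimes)
    maf_distribution: MafDistribution = field(default_factory=MafDistribution)
    p_deleterious_ns: float = 0.5
    predictor_concordance: float = 0.95
    n_sex_limited: int = 2  # trailing tissues: one women-only, one men-only
    p_x_linked: float = 0.05
    p_y_linked: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 9 or lo % 3 or hi % 3 or hi < lo:
            raise ValueError("CDS length range must be multiples of 3, >= 9, lo <= hi")
        if any(f < 0 for f in self.planted_fractions.values()):
            raise ValueError("planted fractions must be non-negative")
        if sum(self.planted_fractions.values()) > 1 + 1e-9:
            raise ValueError("planted fractions sum above 1")
        unknown = set(self.planted_fractions) - set(EXPRESSION_CLASSES)
        if unknown:
            raise ValueError(f"unknown expression classes: {sorted(unknown)}")
        for p in (self.p_deleterious_ns, self.predictor_concordance,
                  self.p_x_linked, self.p_y_linked):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.effect_fold <= 0 or self.moderate_fold <= 0 or self.sde_fold <= 0:
            raise ValueError("fold effects must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.n_sex_limited <= 2 or self.n_sex_limited >= self.n_tissues:
            raise ValueError("n_sex_limited must be 0-2 and below n_tissues")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, all derived from one seed."""
        return np.random.default_rng([self.seed, stage])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cds_length_range"] = list(self.cds_length_range)
        return d


@dataclass
class GroundTruth:
    """Planted per-gene classes and per-variant deleteriousness."""

    expression_class: dict[str, str]
    selection_regime: dict[str, str]
    target_tissue: dict[str, str | None]
    deleterious: dict[str, bool]  # "gene:pos:alt" -> truth, NS sites only

    def to_dict(self) -> dict:
        return {
            "expression_class": self.expression_class,
            "selection_regime": self.selection_regime,
            "target_tissue": self.target_tissue,
            "deleterious": self.deleterious,
        }


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def generate_transcriptome(config: SimulationConfig) -> list[TranscriptModel]:
    """Random in-frame coding sequences with planted chromosome classes.

    Each CDS is an ATG, a run of uniform sense codons, and one stop codon;
    total length is a uniform multiple of 3 within ``cds_length_range``.
    """
    rng = config.rng(1)
    lo, hi = config.cds_length_range
    n_choices = (hi - lo) // 3 + 1
    transcripts = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        length = lo + 3 * int(rng.integers(n_choices))
        n_body = length // 3 - 2
        body = "".join(rng.choice(SENSE_CODONS, size=n_body)) if n_body > 0 else ""
        stop = str(rng.choice(STOP_CODONS))
        u = rng.random()
        if u < config.p_y_linked:
            chrom = "Y"
        elif u < config.p_y_linked + config.p_x_linked:
            chrom = "X"
        else:
            chrom = "autosome"
        transcripts.append(
            TranscriptModel(f"G{i + 1:0{width}d}", chrom, "ATG" + body + stop)
        )
    return transcripts


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _assign_classes(config: SimulationConfig, genes: list[str]) -> dict[str, str]:
    rng = config.rng(2)
    n = len(genes)
    order = rng.permutation(n)
    counts = {c: int(round(f * n)) for c, f in config.planted_fractions.items()}
    while sum(counts.values()) > n:  # rounding overflow
        biggest = max(counts, key=counts.get)
        counts[biggest] -= 1
    classes = {}
    cursor = 0
    for cls in EXPRESSION_CLASSES:
        for j in range(counts.get(cls, 0)):
            classes[genes[order[cursor + j]]] = cls
        cursor += counts.get(cls, 0)
    for idx in order[cursor:]:
        classes[genes[idx]] = UNCONSTRAINED
    return classes


def _tissue_names(config: SimulationConfig) -> tuple[list[str], dict[str, str | None]]:
    """Tissue list and a map tissue -> sex restriction (None = both sexes)."""
    n_common = config.n_tissues - config.n_sex_limited
    names = [f"tissue{i + 1:02d}" for i in range(n_common)]
    restriction: dict[str, str | None] = {t: None for t in names}
    if config.n_sex_limited >= 1:
        names.append("uterus")
        restriction["uterus"] = "F"
    if config.n_sex_limited >= 2:
        names.append("testis")
        restriction["testis"] = "M"
    return names, restriction


def generate_expression(config: SimulationConfig, transcripts: list[TranscriptModel]):
    """Expression matrix (RPKM + counts) with planted sex-bias classes.

    Both sexes share per-(gene, tissue) mean RPKM; planted classes multiply
    one sex's mean in the gene's maximal-mean tissue (restricted to tissues
    available to that sex) by the class fold, so the expected ratio of
    cross-sex maximal expression equals the fold.  Counts are negative
    binomial around ``mean_rpkm * length_kb * library_size``; at dispersion
    0 they equal the mean exactly.  Returns ``(ExpressionMatrix, GroundTruth)``.
    """
    from .expression import ExpressionMatrix  # local to avoid cycle at import time

    rng = config.rng(3)
    genes = [t.gene_id for t in transcripts]
    lengths_kb = {t.gene_id: len(t.cds) / 1000.0 for t in transcripts}
    classes = _assign_classes(config, genes)
    tissues, restriction = _tissue_names(config)

    # base means: gene level x tissue factor, shared by both sexes
    base = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=len(genes))
    tissue_factor = rng.lognormal(mean=0.0, sigma=0.5, size=(len(genes), len(tissues)))
    mean = {}  # sex -> genes x tissues array of mean RPKM
    for sex in ("F", "M"):
        mean[sex] = base[:, None] * tissue_factor

    mean["F"] = mean["F"].copy()
    mean["M"] = mean["M"].copy()
    sex_tissues = {
        s: [j for j, t in enumerate(tissues) if restriction[t] in (None, s)]
        for s in ("F", "M")
    }
    fold_of = {
        WOMEN_SPECIFIC: ("F", config.effect_fold),
        MEN_SPECIFIC: ("M", config.effect_fold),
        MOD_WOMEN: ("F", config.moderate_fold),
        MOD_MEN: ("M", config.moderate_fold),
        SDE_ONE_TISSUE: (None, config.sde_fold),
    }
    target_tissue: dict[str, str | None] = {}
    for i, g in enumerate(genes):
        cls = classes[g]
        if cls not in fold_of:
            target_tissue[g] = None
            continue
        sex, fold = fold_of[cls]
        if sex is None:  # sde-one-tissue: random boosted sex
            sex = "F" if rng.random() < 0.5 else "M"
        cols = sex_tissues[sex]
        j = cols[int(np.argmax(mean[sex][i, cols]))]
        mean[sex][i, j] *= fold
        target_tissue[g] = tissues[j]

    # samples
    sample_ids, meta_rows = [], []
    col_means = []
    for t_idx, tissue in enumerate(tissues):
        for sex in ("F", "M"):
            if restriction[tissue] not in (None, sex):
                continue
            for r in range(config.samples_per_tissue_per_sex):
                sid = f"{tissue}_{sex}_{r + 1:03d}"
                sample_ids.append(sid)
                meta_rows.append((sid, sex, tissue, int(rng.integers(20, 80))))
                col_means.append(mean[sex][:, t_idx])
    mean_rpkm = np.column_stack(col_means)

    len_kb = np.array([lengths_kb[g] for g in genes])[:, None]
    mean_counts = mean_rpkm * len_kb * LIBRARY_SIZE_MILLIONS
    if config.dispersion == 0:
        counts = mean_counts
    else:
        size = 1.0 / config.dispersion  # NB: var = m + d m^2
        p = size / (size + mean_counts)
        counts = rng.negative_binomial(size, p).astype(float)
    rpkm = counts / (len_kb * LIBRARY_SIZE_MILLIONS)

    values = pd.DataFrame(rpkm, index=genes, columns=sample_ids)
    count_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "sex", "tissue", "age"]
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values, metadata, counts=count_df)
    truth = GroundTruth(
        expression_class=classes,
        selection_regime={g: classes[g] for g in genes},
        target_tissue=target_tissue,
        deleterious={},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def plant_deleteriousness(
    config: SimulationConfig, transcripts: list[TranscriptModel]
) -> dict[str, bool]:
    """True deleteriousness flag for every possible NS substitution.

    Keys are ``"gene:pos:alt"``; each possible NS substitution is deleterious
    independently with probability ``p_deleterious_ns``.  Deterministic given
    the config seed.
    """
    rng = config.rng(4)
    truth: dict[str, bool] = {}
    for t in transcripts:
        for pos, _ref, alt, csq in enumerate_substitutions(t.cds):
            if csq == "NS":
                truth[f"{t.gene_id}:{pos}:{alt}"] = bool(
                    rng.random() < config.p_deleterious_ns
                )
    return truth


def build_spectra(
    transcripts: list[TranscriptModel], truth: Mapping[str, bool]
) -> dict[str, SubstitutionSpectrum]:
    """Per-gene possible-substitution spectra using the planted truth as labeler."""
    from .selection import enumerate_possible_substitutions

    return {
        t.gene_id: enumerate_possible_substitutions(
            t, lambda g, pos, ref, alt: truth[f"{g}:{pos}:{alt}"]
        )
        for t in transcripts
    }


def generate_variants(
    config: SimulationConfig,
    transcripts: list[TranscriptModel],
    spectra: Mapping[str, SubstitutionSpectrum],
    truth: GroundTruth | Mapping[str, bool],
) -> pd.DataFrame:
    """Observed variants as a regime-weighted subsample of possible substitutions.

    Each possible substitution of a gene is accepted with its regime's
    per-class probability (synonymous, deleterious NS, benign NS, stop-gain;
    stop-loss and stop-to-stop changes are never observed).  Accepted
    variants get a MAF from the regime's (or the global) MAF distribution,
    independent of consequence, and two predictor labels that each equal the
    planted truth with probability ``predictor_concordance``.  Returns a
    DataFrame with columns gene_id, cds_pos, ref, alt, maf, consequence,
    predictor1, predictor2.
    """
    rng = config.rng(5)
    if isinstance(truth, GroundTruth):
        if not truth.deleterious:
            raise ValueError(
                "ground truth has no deleteriousness map; call plant_deleteriousness "
                "and store its result in truth.deleterious first"
            )
        del_truth = truth.deleterious
        regime_of = truth.selection_regime
    else:
        del_truth = dict(truth)
        regime_of = {}
    rows = []
    for t in transcripts:
        if t.gene_id not in spectra:
            raise KeyError(f"no spectrum for {t.gene_id}")
        regime_key = regime_of.get(t.gene_id, UNCONSTRAINED)
        regime = config.selection_regimes.get(
            regime_key, config.selection_regimes.get(UNCONSTRAINED, SelectionRegime())
        )
        maf_dist = regime.maf or config.maf_distribution
        accepted = []
        for pos, ref, alt, csq in enumerate_substitutions(t.cds):
            if csq in ("stop-loss", "other"):
                continue
            if csq == "S":
                p_acc, deleterious = regime.s, False
            elif csq == "stop-gain":
                p_acc, deleterious = regime.stop, True
            else:
                deleterious = del_truth[f"{t.gene_id}:{pos}:{alt}"]
                p_acc = regime.dns if deleterious else regime.ns_benign
            if rng.random() < p_acc:
                accepted.append((pos, ref, alt, csq, deleterious))
        if not accepted:
            continue
        mafs = maf_dist.sample(rng, len(accepted))
        for (pos, ref, alt, csq, deleterious), maf in zip(accepted, mafs):
            if csq == "NS":
                truth_flag = deleterious
            else:
                truth_flag = False  # predictors only score missense changes
            p1_true = rng.random() < config.predictor_concordance
            p2_true = rng.random() < config.predictor_concordance
            p1_del = truth_flag if p1_true else not truth_flag
            p2_del = truth_flag if p2_true else not truth_flag
            rows.append(
                (
                    t.gene_id, pos, ref, alt, float(maf), csq,
                    "deleterious" if p1_del else "tolerated",
                    "deleterious" if p2_del else "benign",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "cds_pos", "ref", "alt", "maf",
            "consequence", "predictor1", "predictor2",
        ],
    )
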