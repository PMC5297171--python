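"""End-to-end orchestration: simulate/load -> summarize -> SDE -> specificity -> selection.

A run is described by a :class:`RunConfig` (YAML on disk): either a
simulation block or paths to real inputs, plus engine parameters.  Outputs
are TSV/JSON files in the output directory and a :class:`RunReport` of
per-stage record counts.  A fixed config and seed reproduce every output
byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .expression import ExpressionMatrix, filter_informative_genes, summarize_by_tissue_sex
from .sde import (
    build_sde_matrix,
    complementary_detection,
    de_probability_population_matrix,
    noiseq_sim_probability,
)
from .selection import randomization_test
from .simulate import (
    SimulationConfig,
    build_spectra,
    generate_expression,
    generate_transcriptome,
    generate_variants,
    plant_deleteriousness,
)
from . import specificity as spec_mod

log = logging.getLogger("sexbias")

__all__ = ["EngineParams", "RunConfig", "RunReport", "run_pipeline", "validate_inputs"]


@dataclass
class EngineParams:
    """Analysis thresholds; defaults are the published operating points."""

    informative_rpkm: float = 1.0
    probability_cutoff: float = 0.95
    sim_probability_min: float = 0.8
    complementary_gap: float = 0.2
    n_perm: int = 2000
    n_sim: int = 200
    maf_dns: float = 0.005
    maf_stop: float = 0.001
    n_iter: int = 10_000
    exclude_tissues: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict | None = None  # expression/metadata/fasta/variants paths
    engine: EngineParams = field(default_factory=EngineParams)

    def __post_init__(self) -> None:
        if self.simulation is None and not self.inputs:
            raise ValueError("config needs either a simulation block or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulation")
        if sim is not None:
            if "cds_length_range" in sim:
                sim["cds_length_range"] = tuple(sim["cds_length_range"])
            sim = SimulationConfig(**sim)
        engine = EngineParams(**raw.get("engine", {}))
        return cls(
            outdir=raw["outdir"],
            seed=raw.get("seed", 0),
            simulation=sim,
            inputs=raw.get("inputs"),
            engine=engine,
        )

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "inputs": self.inputs,
            "engine": vars(self.engine).copy(),
        }


@dataclass
class RunReport:
    version: str
    seed: int
    config: dict
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return vars(self).copy()


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


def _stage(report: RunReport, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.timings[name] = round(dt, 3)
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs", name, dt)
                raise StageError(f"[{name}] {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write every artifact under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=config.seed, config=config.to_dict())
    # hash covers the analysis-relevant config only, not where outputs land
    cfg_hash = io.config_hash(
        {k: v for k, v in config.to_dict().items() if k != "outdir"}
    )
    eng = config.engine

    # ---- stage: inputs -----------------------------------------------------
    with _stage(report, "inputs"):
        if config.simulation is not None:
            sim = config.simulation
            transcripts = generate_transcriptome(sim)
            matrix, truth = generate_expression(sim, transcripts)
            ns_truth = plant_deleteriousness(sim, transcripts)
            truth.deleterious = ns_truth
            spectra = build_spectra(transcripts, ns_truth)
            variants = generate_variants(sim, transcripts, spectra, truth)
            io.write_fasta(transcripts, outdir / "transcripts.fasta")
            io.write_expression(
                matrix, outdir / "expression.tsv", outdir / "samples.tsv",
                outdir / "counts.tsv", seed=config.seed, cfg_hash=cfg_hash,
            )
            io.write_variants(variants, outdir / "variants.tsv", config.seed, cfg_hash)
            io.write_json(truth.to_dict(), outdir / "ground_truth.json")
        else:
            paths = config.inputs
            transcripts = io.read_fasta(paths["fasta"])
            matrix = io.read_expression(
                paths["expression"], paths["metadata"], paths.get("counts")
            )
            variants = io.read_variants(paths["variants"], transcripts)
            truth = None
            ns_truth = None
            spectra = None
        report.counts["genes_input"] = len(matrix.genes)
        report.counts["samples"] = len(matrix.samples)
        report.counts["variants"] = len(variants)

    # ---- stage: expression summaries --------------------------------------
    with _stage(report, "expression"):
        filtered = filter_informative_genes(matrix, eng.informative_rpkm)
        summary = summarize_by_tissue_sex(filtered)
        report.counts["genes_informative"] = len(filtered.genes)

    # ---- stage: SDE --------------------------------------------------------
    with _stage(report, "sde"):
        common = summary.common_tissues
        genes = list(filtered.genes)
        pop_probs = pd.DataFrame(index=genes, columns=common, dtype=float)
        sim_probs = pd.DataFrame(index=genes, columns=common, dtype=float)
        for i, tissue in enumerate(common):
            w_samples = filtered.select_samples(sex="F", tissue=tissue)
            m_samples = filtered.select_samples(sex="M", tissue=tissue)
            pop_probs[tissue] = de_probability_population_matrix(
                filtered.values[w_samples].to_numpy(),
                filtered.values[m_samples].to_numpy(),
                n_perm=eng.n_perm,
                seed=config.seed * 1000 + i,
            )
            if summary.counts is not None:
                sim_probs[tissue] = noiseq_sim_probability(
                    summary.counts[(tissue, "F")].to_numpy(),
                    summary.counts[(tissue, "M")].to_numpy(),
                    n_sim=eng.n_sim,
                    seed=config.seed * 1000 + 500 + i,
                )
        if summary.counts is not None:
            comp = pd.DataFrame(
                [
                    [
                        complementary_detection(sim_probs.at[g, t], pop_probs.at[g, t])
                        for t in common
                    ]
                    for g in genes
                ],
                index=genes, columns=common,
            )
        else:
            comp = None
        scores = build_sde_matrix(
            summary, pop_probs, cutoff=eng.probability_cutoff, extra_significant=comp
        )
        calls = []
        for tissue in common:
            sig = scores[tissue] != 0
            for g in scores.index[sig]:
                calls.append((g, tissue, float(pop_probs.at[g, tissue]), float(scores.at[g, tissue])))
        calls_df = pd.DataFrame(calls, columns=["gene_id", "tissue", "probability", "score"])
        io.write_table(scores, outdir / "sde_scores.tsv", config.seed, cfg_hash)
        io.write_table(calls_df, outdir / "sde_calls.tsv", config.seed, cfg_hash, index=False)
        report.counts["sde_calls_per_tissue"] = {
            t: int((scores[t] != 0).sum()) for t in common
        }

    # ---- stage: specificity ------------------------------------------------
    with _stage(report, "specificity"):
        y_genes = {t.gene_id for t in transcripts if t.chromosome == "Y"}
        spec_table = spec_mod.classify_all(
            summary, filtered, exclude_genes=y_genes,
            n_perm=eng.n_perm, seed=config.seed, test_specific=True,
        )
        io.write_table(spec_table, outdir / "specificity.tsv", config.seed, cfg_hash)
        report.counts["specificity_categories"] = (
            spec_table["category"].value_counts().to_dict()
        )

    # ---- stage: selection --------------------------------------------------
    with _stage(report, "selection"):
        if spectra is None:
            ns_labeler = _predictor_labeler(variants)
            spectra = build_spectra(transcripts, ns_labeler)
        # pool: non-Y, non-testis-specific genes with expression data
        testis_specific = {
            g
            for g, row in spec_table.iterrows()
            if row["category"] in (spec_mod.MEN_SPECIFIC,)
            and row["tissue_m"] == "testis"
        }
        pool = [
            g for g in filtered.genes
            if g not in y_genes and g not in testis_specific and g in spectra
        ]
        groups = {
            "women-specific": spec_mod.WOMEN_SPECIFIC,
            "men-specific": spec_mod.MEN_SPECIFIC,
            "moderately-women-specific": spec_mod.MOD_WOMEN,
            "moderately-men-specific": spec_mod.MOD_MEN,
        }
        rows = []
        for i, (label, category) in enumerate(groups.items()):
            members = [
                g for g in spec_table.index[spec_table["category"] == category]
                if g in spectra
            ]
            if not members or len(pool) <= len(members):
                continue
            res = randomization_test(
                members, pool, variants, spectra,
                n_iter=eng.n_iter, seed=config.seed * 100 + i,
                maf_dns=eng.maf_dns, maf_stop=eng.maf_stop,
            )
            rows.append(
                (
                    label, res.n_genes, res.dns_ratio, res.dns_p,
                    res.stop_ratio, res.stop_p,
                    res.random_dns_mean, res.random_dns_std,
                )
            )
        sel_df = pd.DataFrame(
            rows,
            columns=[
                "group", "n_genes", "dDNS/dS", "p_dDNS",
                "dStop/dS", "p_dStop", "random_mean_dDNS/dS", "random_sd_dDNS/dS",
            ],
        )
        io.write_table(sel_df, outdir / "selection.tsv", config.seed, cfg_hash, index=False)
        report.counts["selection_groups"] = len(sel_df)

    io.write_json(report.to_dict(), outdir / "report.json")
    return report


def _predictor_labeler(variants: pd.DataFrame) -> dict[str, bool]:
    """Deleteriousness map from observed predictor calls (real-input mode).

    Only observed NS variants carry predictor labels, so possible NS
    substitutions never observed are treated as benign — a conservative
    denominator when full predictor annotation of possible substitutions is
    unavailable.
    """
    from .selection import combine_deleteriousness

    out: dict[str, bool] = {}
    ns = variants[variants["consequence"] == "NS"]
    for row in ns.itertuples(index=False):
        out[f"{row.gene_id}:{row.cds_pos}:{row.alt}"] = combine_deleteriousness(
            row.predictor1, row.predictor2
        )
    import collections

    return collections.defaultdict(bool, out)


def validate_inputs(paths: dict) -> list[str]:
    """Schema and consistency diagnostics for real input files.

    Returns a list of human-readable problems (empty = clean).  Checks FASTA
    readability and CDS validity, expression/metadata completeness, and
    variant reference alleles against the CDS.  Inputs are never modified.
    """
    problems: list[str] = []
    transcripts = None
    try:
        transcripts = io.read_fasta(paths["fasta"])
    except Exception as exc:
        problems.append(f"fasta: {exc}")
    try:
        matrix = io.read_expression(paths["expression"], paths["metadata"])
        meta = matrix.metadata
        no_sex = meta.index[~meta["sex"].isin(["F", "M"])].tolist()
        if no_sex:
            problems.append(f"metadata: samples with missing/unknown sex: {no_sex[:5]}")
    except Exception as exc:
        problems.append(f"expression: {exc}")
    if transcripts is not None:
        try:
            io.read_variants(paths["variants"], transcripts)
        except Exception as exc:
            problems.append(f"variants: {exc}")
    return problems
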