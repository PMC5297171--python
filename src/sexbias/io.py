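"""Readers and writers for the pipeline's plain-text formats.

Formats: FASTA for coding sequences, TSV for the expression matrix
(genes x samples), sample metadata, the variant table, and result tables;
JSON for ground truth and run reports.  TSV files are written with a
``#``-prefixed comment header (tool version, seed, config hash) and all
readers skip such lines; compression is transparent via file suffix.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .expression import ExpressionMatrix
from .selection import TranscriptModel, annotate_substitution

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_expression",
    "read_expression",
    "write_variants",
    "read_variants",
    "write_table",
    "write_json",
    "config_hash",
]

VARIANT_COLUMNS = ["gene_id", "cds_pos", "ref", "alt", "maf", "predictor1", "predictor2"]


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header(seed=None, cfg_hash=None) -> str:
    parts = [f"# sexbias v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts) + "\n"


def write_table(
    df: pd.DataFrame, path, seed=None, cfg_hash=None, index: bool = True
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index)


def write_fasta(transcripts, path, descriptions: bool = True) -> None:
    records = [
        SeqRecord(
            Seq(t.cds),
            id=t.gene_id,
            description=f"chromosome={t.chromosome}" if descriptions else "",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[TranscriptModel]:
    transcripts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chrom = "autosome"
        for token in rec.description.split():
            if token.startswith("chromosome="):
                chrom = token.split("=", 1)[1]
        transcripts.append(TranscriptModel(rec.id, chrom, str(rec.seq).upper()))
    if not transcripts:
        raise ValueError(f"no sequences in {path}")
    return transcripts


def write_expression(matrix: ExpressionMatrix, values_path, metadata_path,
                     counts_path=None, seed=None, cfg_hash=None) -> None:
    write_table(matrix.values, values_path, seed, cfg_hash)
    write_table(matrix.metadata, metadata_path, seed, cfg_hash)
    if counts_path is not None and matrix.counts is not None:
        write_table(matrix.counts, counts_path, seed, cfg_hash)


def read_expression(values_path, metadata_path, counts_path=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    counts = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values, metadata, counts)


def write_variants(variants: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Write the variant table (consequences are recomputable from the CDS)."""
    write_table(variants[VARIANT_COLUMNS], path, seed, cfg_hash, index=False)


def read_variants(path, transcripts=None) -> pd.DataFrame:
    """Read a variant table; annotate consequences when transcripts are given.

    With ``transcripts`` supplied, each variant's consequence is computed
    from the CDS, which also validates the reference allele against the
    sequence (mismatches raise with gene and position).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if transcripts is not None:
        cds_of = {t.gene_id: t.cds for t in transcripts}
        consequences = []
        for row in df.itertuples(index=False):
            if row.gene_id not in cds_of:
                raise ValueError(f"variant gene {row.gene_id} has no transcript")
            try:
                consequences.append(
                    annotate_substitution(cds_of[row.gene_id], int(row.cds_pos),
                                          row.ref, row.alt)
                )
            except ValueError as exc:
                raise ValueError(f"{row.gene_id} pos {row.cds_pos}: {exc}") from exc
        df = df.assign(consequence=consequences)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
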