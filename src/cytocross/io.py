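"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals are BED-style 0-based half-open.  Reads are stored
as a BED-like TSV of (chrom, pos5, strand); counts, annotations and
result tables are TSV; the truth table serializes to JSON; motif models
are read from JASPAR plain-text PFMs via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import PWM
from .stats import CountMatrix
from .tagdensity import ReadSet

__all__ = [
    "ValidationError",
    "read_genomic_tables",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_reads",
    "write_reads",
    "read_truth",
    "write_truth",
    "read_jaspar",
]


class ValidationError(ValueError):
    """Typed input-validation failure naming the offending file and line."""

    def __init__(self, path, line: int | None, message: str) -> None:
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """BED3/4/6 (+ optional 7th summit-offset column), validated."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(path, ln, "BED line needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValidationError(path, ln, f"non-integer coordinate: {e}") from e
            if start < 0:
                raise ValidationError(path, ln, "negative start coordinate")
            if start >= end:
                raise ValidationError(path, ln, f"start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"peak{ln:05d}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            summit = int(parts[6]) if len(parts) > 6 else None
            rows.append((chrom, start, end, name, score, strand, summit))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "summit"]
    )
    df["summit"] = pd.to_numeric(df["summit"], errors="coerce")
    # peak anchor: summit offset when provided, interval midpoint otherwise
    df["center"] = np.where(
        df["summit"].notna(),
        df["start"] + df["summit"].fillna(0).astype(np.int64),
        (df["start"] + df["end"]) // 2,
    ).astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
        else:
            break
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_counts(m: CountMatrix, counts_path, conditions_path=None) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="feature")
    if conditions_path is not None:
        pd.DataFrame(
            {"sample": list(m.counts.columns), "condition": [m.conditions[s] for s in m.counts.columns]}
        ).to_csv(conditions_path, sep="\t", index=False)


def read_counts(counts_path, conditions_path, lengths_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature")
    cond = pd.read_csv(conditions_path, sep="\t")
    conditions = dict(zip(cond["sample"], cond["condition"]))
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0].astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValidationError(counts_path, None, "negative counts")
    return CountMatrix(counts, conditions, lengths)


def write_annotation(ann: pd.DataFrame, path) -> None:
    cols = [c for c in ("gene_id", "chrom", "tss", "strand", "label") if c in ann.columns]
    ann[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(ann.columns):
        raise ValidationError(path, None, f"annotation needs columns {sorted(required)}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(path, None, f"duplicate gene id {dup!r}")
    if (ann["tss"] < 0).any():
        raise ValidationError(path, None, "negative TSS coordinate")
    return ann


def write_reads(rs: ReadSet, path) -> None:
    df = rs.reads.copy()
    df["sample_id"] = rs.sample_id
    df.to_csv(path, sep="\t", index=False)


def read_reads(path, read_length: int = 50) -> ReadSet:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos5", "strand"}
    if not required.issubset(df.columns):
        raise ValidationError(path, None, f"reads file needs columns {sorted(required)}")
    sample = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else Path(path).stem
    return ReadSet(sample, df[["chrom", "pos5", "strand"]], read_length=read_length)


def write_truth(truth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path):
    from .synthetic import TruthTable

    return TruthTable.from_json(Path(path).read_text())


def read_genomic_tables(
    counts=None,
    conditions=None,
    lengths=None,
    annotation=None,
    genome=None,
    peaks=None,
    reads=None,
) -> dict:
    """Load a dataset from paths and reconcile it.

    ``peaks`` and ``reads`` map condition/sample names to file paths.
    Validates each file and checks that every chromosome referenced by
    peaks, reads and annotation exists in the genome (when a genome is
    given).  Returns a dict with the loaded objects.
    """
    out: dict = {}
    if counts is not None:
        out["counts"] = read_counts(counts, conditions, lengths)
    if annotation is not None:
        out["annotation"] = read_annotation(annotation)
    if genome is not None:
        out["genome"] = read_fasta(genome)
    if peaks is not None:
        out["peaks"] = {name: read_bed(path) for name, path in dict(peaks).items()}
    if reads is not None:
        out["reads"] = {name: read_reads(path) for name, path in dict(reads).items()}

    if "genome" in out:
        known = set(out["genome"])
        def _check(chroms, origin):
            missing = set(chroms) - known
            if missing:
                raise ValidationError(
                    origin, None, f"chromosome(s) {sorted(missing)} absent from genome"
                )
        if "annotation" in out:
            _check(out["annotation"]["chrom"].unique(), annotation)
        for name, df in out.get("peaks", {}).items():
            _check(df["chrom"].unique(), f"peaks[{name}]")
        for name, rs in out.get("reads", {}).items():
            _check(rs.reads["chrom"].unique(), f"reads[{name}]")
    return out


def read_jaspar(path) -> list[PWM]:
    """Parse JASPAR plain-text PFMs into log-odds-ready PWMs."""
    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            out.append(PWM.from_counts(m.matrix_id or m.name, counts))
    return out
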