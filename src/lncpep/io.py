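"""Readers and writers for the flat formats the pipeline consumes.

FASTA goes through Biopython.  Annotation is accepted either as GTF
(1-based closed coordinates, converted here to 0-based half-open) or as
a minimal 6-column TSV (already 0-based half-open).  Expression tables,
peak BEDs and peptide lists are plain pandas tables.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import Transcript

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand", "start", "end"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqrecs, str(path), "fasta")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation_gtf(path: str | Path) -> pd.DataFrame:
    """Read transcript records from a GTF into a 0-based half-open table.

    Only ``transcript`` features are used (one row per transcript).  GTF
    start is 1-based closed, so start-1 is taken.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            rows.append(
                {
                    "transcript_id": attrs.get("transcript_id", ""),
                    "gene_id": attrs.get("gene_id", ""),
                    "chrom": f[0],
                    "strand": f[6],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_gtf(ann: pd.DataFrame, path: str | Path, source: str = "lncpep") -> None:
    """Write a transcript table as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for row in ann.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
            fh.write(
                f"{row.chrom}\t{source}\ttranscript\t{row.start + 1}\t{row.end}\t."
                f"\t{row.strand}\t.\t{attrs}\n"
            )


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read the minimal 6-column annotation TSV (0-based half-open)."""
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return ann[ANNOTATION_COLUMNS]


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return read_annotation_gtf(path)
    return read_annotation_tsv(path)


def load_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[Transcript]:
    """Join a transcript FASTA with its annotation into Transcript objects.

    Transcripts present in only one of the two inputs are skipped with a
    warning.
    """
    seqs = read_fasta(fasta_path)
    ann = read_annotation(annotation_path)
    out: list[Transcript] = []
    seen = set()
    for row in ann.itertuples(index=False):
        seen.add(row.transcript_id)
        seq = seqs.get(row.transcript_id)
        if seq is None:
            warnings.warn(f"{row.transcript_id}: annotated but absent from FASTA; skipped")
            continue
        out.append(
            Transcript(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                genomic_start=int(row.start),
                genomic_end=int(row.end),
                sequence=seq,
            )
        )
    for tid in seqs:
        if tid not in seen:
            warnings.warn(f"{tid}: in FASTA but not annotated; skipped")
    return out


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TPM table: first column transcript_id, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    return df.set_index(first).rename_axis("transcript_id")


def write_expression_tsv(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.rename_axis("transcript_id").to_csv(path, sep="\t")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ peak file into a (chrom, start, end, name) table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED file needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    else:
        out["name"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(out.chrom, out.start, out.end)
        ]
    return out


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in peaks.columns else [])
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_peptides_tsv(path: str | Path) -> pd.DataFrame:
    """Read a peptide list TSV; must contain a ``sequence`` column."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError("peptide TSV must contain a 'sequence' column")
    return df
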