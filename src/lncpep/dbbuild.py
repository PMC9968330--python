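"""Expression-gated target/decoy peptide search-database construction.

The immunopeptidomics search strategy translates every lncRNA transcript
in 3 frames and gates the entries on transcript expression: transcripts
expressed at detectable levels (TPM bins 'low' and 'high') form the
target database, transcripts with TPM = 0 form an identically constructed
decoy database, and the undefined gap 0 < TPM <= 0.5 is excluded from
both.  Frame translations are split at stop codons into maximal stop-free
segments, because search engines require stop-free entries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .seqcore import Transcript, three_frame_translate

Bin = Literal["non_expressed", "low", "high", "unassigned"]
Role = Literal["target", "decoy"]

DEFAULT_THRESHOLDS = {"zero_eps": 1e-9, "low_lo": 0.5, "low_hi": 1.0}


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript TPM values, their summary and the expression bin.

    The bin is a pure function of ``summary_tpm`` and the thresholds:
    <= zero_eps -> non_expressed; (low_lo, low_hi) -> low;
    >= low_hi -> high; the remaining gap (zero_eps, low_lo] -> unassigned.
    """

    transcript_id: str
    tpm_by_sample: Mapping[str, float]
    summary_tpm: float
    bin: Bin


def _assign_bin(summary: float, zero_eps: float, low_lo: float, low_hi: float) -> Bin:
    if summary <= zero_eps:
        return "non_expressed"
    if summary >= low_hi:
        return "high"
    if summary > low_lo:
        return "low"
    return "unassigned"


def bin_expression(
    table: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    aggregator: Literal["max", "mean"] = "max",
) -> list[ExpressionRecord]:
    """Bin each transcript of a TPM table (rows transcripts, columns samples).

    ``aggregator='max'`` treats a transcript as expressed if detectable in
    any sample; ``'mean'`` averages across samples.  Negative TPM values
    are rejected.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if (table < 0).any().any():
        bad = table.index[(table < 0).any(axis=1)][0]
        raise ValueError(f"negative TPM for transcript {bad!r}")
    if aggregator == "max":
        summary = table.max(axis=1)
    elif aggregator == "mean":
        summary = table.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    out = []
    for tid, row in table.iterrows():
        s = float(summary.loc[tid])
        out.append(
            ExpressionRecord(
                transcript_id=str(tid),
                tpm_by_sample=row.to_dict(),
                summary_tpm=s,
                bin=_assign_bin(s, th["zero_eps"], th["low_lo"], th["low_hi"]),
            )
        )
    return out


@dataclass(frozen=True)
class DbEntry:
    """One stop-free protein segment of a transcript frame translation."""

    transcript_id: str
    frame: int
    segment_index: int
    role: Role
    protein_segment: str

    @property
    def entry_id(self) -> str:
        return f"{self.transcript_id}|F{self.frame}|S{self.segment_index}"


@dataclass
class BuildResult:
    targets: list[DbEntry]
    decoys: list[DbEntry]
    skipped_transcripts: list[str] = field(default_factory=list)


def _segments(transcript: Transcript, role: Role, min_segment_aa: int) -> list[DbEntry]:
    entries = []
    for ft in three_frame_translate(transcript):
        seg_idx = 0
        for seg in ft.protein.split("*"):
            if len(seg) >= min_segment_aa:
                entries.append(
                    DbEntry(transcript.transcript_id, ft.frame, seg_idx, role, seg)
                )
                seg_idx += 1
    return entries


def build_search_databases(
    transcripts: Iterable[Transcript],
    records: Sequence[ExpressionRecord],
    min_segment_aa: int = 7,
    include_low: bool = True,
) -> BuildResult:
    """Build the target and decoy databases from binned transcripts.

    low/high transcripts contribute target entries (low switchable off),
    non-expressed transcripts contribute identically constructed decoy
    entries, unassigned transcripts contribute nothing.  Transcripts in
    the expression table but missing from the supplied sequences are
    skipped with a warning and counted in the result.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    target_bins = {"high", "low"} if include_low else {"high"}
    res = BuildResult(targets=[], decoys=[])
    for rec in records:
        if rec.bin == "unassigned":
            continue
        t = by_id.get(rec.transcript_id)
        if t is None:
            warnings.warn(
                f"{rec.transcript_id}: in expression table but no sequence; skipped"
            )
            res.skipped_transcripts.append(rec.transcript_id)
            continue
        if rec.bin in target_bins:
            res.targets.extend(_segments(t, "target", min_segment_aa))
        elif rec.bin == "non_expressed":
            res.decoys.extend(_segments(t, "decoy", min_segment_aa))
    return res


def write_database_fasta(
    entries: Sequence[DbEntry],
    path: str | Path,
    decoy_prefix: str = "DECOY_",
) -> None:
    """Write database entries as FASTA; decoy headers carry the prefix."""
    if not entries:
        warnings.warn(f"writing empty database to {path}")
    with open(path, "w") as fh:
        for e in entries:
            prefix = decoy_prefix if e.role == "decoy" else ""
            fh.write(f">{prefix}{e.entry_id}\n")
            for i in range(0, len(e.protein_segment), 60):
                fh.write(e.protein_segment[i : i + 60] + "\n")


_ENTRY_ID = re.compile(r"^(?P<tid>.+)\|F(?P<frame>[012])\|S(?P<seg>\d+)$")


def read_database_fasta(path: str | Path, decoy_prefix: str = "DECOY_") -> list[DbEntry]:
    """Inverse of :func:`write_database_fasta` (lossless round-trip)."""
    from .io import read_fasta

    out = []
    for name, seq in read_fasta(path).items():
        role: Role = "target"
        if name.startswith(decoy_prefix):
            role = "decoy"
            name = name[len(decoy_prefix) :]
        m = _ENTRY_ID.match(name)
        if not m:
            raise ValueError(f"unparseable database entry id: {name!r}")
        out.append(
            DbEntry(m["tid"], int(m["frame"]), int(m["seg"]), role, seq)
        )
    return out
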