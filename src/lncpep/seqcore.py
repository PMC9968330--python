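"""Sequence domain types and translation/ORF primitives.

Long non-coding RNAs (lncRNAs) are conventionally annotated as
untranslated, yet many carry small open reading frames (smORFs, typically
<100 residues) whose products can be processed into MHC class I ligands.
This module provides the primitives the rest of the pipeline builds on:
strand-aware transcript records, 3-frame translation of the spliced sense
sequence, and exhaustive ATG-to-stop ORF enumeration.

Coordinates are 0-based half-open throughout; 1-based annotation formats
(GTF) are converted at the parser boundary in :mod:`lncpep.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "Transcript",
    "FrameTranslation",
    "OrfCandidate",
    "translate",
    "three_frame_translate",
    "enumerate_orfs",
    "protein_mw_kda",
    "DNA_ALPHABET",
    "AA_ALPHABET",
]

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Standard genetic code, stops rendered '*'.  Built from Biopython's table
# but applied strictly: any codon containing N translates to 'X' (never
# resolved, even when the degenerate codon would be unambiguous), because
# an 'X' must never be able to match a peptide residue downstream.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate(dna: str, frame: int = 0) -> str:
    """Translate ``dna`` from ``frame`` with the standard genetic code.

    Stops are rendered ``*``; any codon containing ``N`` renders ``X``;
    a trailing partial codon (<3 nt) is ignored.

    Raises
    ------
    ValueError
        If ``dna`` contains a character outside ``{A,C,G,T,N}`` (the
        message names the offending 0-based position) or ``frame`` is not
        in {0, 1, 2}.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    for i, ch in enumerate(dna):
        if ch not in DNA_ALPHABET:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {i}; expected one of A,C,G,T,N"
            )
    out: list[str] = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TO_AA[codon])
    return "".join(out)


@dataclass(frozen=True)
class Transcript:
    """A spliced transcript with its gene-level genomic placement.

    ``sequence`` is the 5'->3' sense-strand spliced sequence;
    ``genomic_start``/``genomic_end`` are the 0-based half-open gene
    boundaries on ``chrom`` (the genomic span may exceed the spliced
    length when the gene has introns).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    genomic_start: int
    genomic_end: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.genomic_end <= self.genomic_start:
            raise ValueError(
                f"{self.transcript_id}: genomic_end must exceed genomic_start"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c not in DNA_ALPHABET
            )
            raise ValueError(
                f"{self.transcript_id}: invalid nucleotide "
                f"{self.sequence[pos]!r} at position {pos}"
            )

    @property
    def tss(self) -> int:
        """Genomic transcription start site (strand-aware, 0-based)."""
        return self.genomic_start if self.strand == "+" else self.genomic_end - 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a transcript's sense-strand translation."""

    transcript_id: str
    frame: int
    protein: str


def three_frame_translate(t: Transcript) -> tuple[FrameTranslation, ...]:
    """Translate the sense strand in all three frames.

    Returns exactly three records (frames 0, 1, 2); each protein has
    length ``floor((L - frame) / 3)``.  Antisense frames are deliberately
    not produced: the search-database procedure is 3-frame, sense only.
    """
    return tuple(
        FrameTranslation(t.transcript_id, f, translate(t.sequence, f))
        for f in (0, 1, 2)
    )


@dataclass(frozen=True)
class OrfCandidate:
    """An ATG-to-stop open reading frame on a transcript.

    ``start_nt``/``end_nt`` are 0-based half-open transcript positions;
    when a stop terminates the ORF, ``end_nt`` is the position just after
    the stop codon and ``protein`` excludes the stop.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    protein: str
    has_stop: bool

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def enumerate_orfs(
    t: Transcript,
    require_stop: bool = True,
    min_aa: int = 1,
    start_codons: Sequence[str] = ("ATG",),
) -> list[OrfCandidate]:
    """Enumerate every start-codon-to-stop ORF in all three frames.

    For every occurrence of a start codon (ATG by default), one candidate
    is emitted ending at the first downstream in-frame stop; nested ORFs
    sharing a stop are all reported.  ORFs running off the 3' end without
    a stop are reported only when ``require_stop`` is False (with
    ``has_stop=False``).  Output is sorted by ``(frame, start_nt)``.

    ``start_codons`` exists because some annotation practice admits
    near-cognate initiation; the default is strict ATG.
    """
    starts = {c.upper() for c in start_codons}
    seq = t.sequence
    out: list[OrfCandidate] = []
    for frame in (0, 1, 2):
        aa = translate(seq, frame)
        n = len(aa)
        # next in-frame stop at or after each codon index
        next_stop = [n] * (n + 1)
        for i in range(n - 1, -1, -1):
            next_stop[i] = i if aa[i] == "*" else next_stop[i + 1]
        for i in range(n):
            codon = seq[frame + 3 * i : frame + 3 * i + 3]
            if codon not in starts:
                continue
            j = next_stop[i]
            if j < n:
                cand = OrfCandidate(
                    transcript_id=t.transcript_id,
                    frame=frame,
                    start_nt=frame + 3 * i,
                    end_nt=frame + 3 * (j + 1),
                    protein=aa[i:j],
                    has_stop=True,
                )
            elif not require_stop:
                cand = OrfCandidate(
                    transcript_id=t.transcript_id,
                    frame=frame,
                    start_nt=frame + 3 * i,
                    end_nt=frame + 3 * n,
                    protein=aa[i:n],
                    has_stop=False,
                )
            else:
                continue
            if cand.length_aa >= min_aa:
                out.append(cand)
    out.sort(key=lambda c: (c.frame, c.start_nt))
    return out


def protein_mw_kda(protein: str) -> float:
    """Theoretical average molecular weight of a polypeptide, in kDa.

    Sum of standard average residue masses plus one water.  Used for
    reporting the size of candidate ORF products (e.g. a ~26 kDa smORF
    polypeptide).  Rejects empty input, stop characters and residues
    outside the 20-letter alphabet.
    """
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    return ProteinAnalysis(protein).molecular_weight() / 1000.0
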