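"""Poly-antigen vaccine cassette and ORF cloning-construct design.

Each selected MHC class I peptide (typically a 9-mer) is carried into the
cassette together with 24 bp of natural flanking sequence on each side,
copied verbatim from its source ORF so that proteasomal processing sees
the endogenous context.  Flanks are bounded by the ORF, not the raw
transcript: they truncate at the ORF's start methionine and at its stop
codon.  Segments are concatenated in frame behind a Kozak sequence and a
tissue plasminogen activator (tPA) secretion leader.

The cloning amplicon for expressing a candidate ORF with a C-terminal
tag spans 30 bp of upstream transcript context (to retain any inherent
ribosome binding site) through the ORF minus its stop codon, leaving the
3' end in frame with the tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seqcore import OrfCandidate, Transcript, translate

# Kozak consensus used ahead of the leader ATG.
DEFAULT_KOZAK = "GCCACC"

# Human tissue plasminogen activator (PLAT) signal-peptide CDS, the
# standard secretion leader fused to vectored vaccine antigens.
DEFAULT_TPA_LEADER = (
    "ATGGATGCAATGAAGAGAGGGCTCTGCTGTGTGCTGCTGCTGTGTGGAGCAGTCTTCGTTTCGCCCAGC"
)


@dataclass(frozen=True)
class FlankedSegment:
    """A peptide plus its natural in-frame flanking residues.

    ``nt_segment`` is copied verbatim from the source transcript and
    translates (frame 0) to ``upstream_aa + peptide + downstream_aa``.
    """

    peptide: str
    upstream_aa: str
    downstream_aa: str
    nt_segment: str
    source_transcript_id: str = ""

    @property
    def protein(self) -> str:
        return self.upstream_aa + self.peptide + self.downstream_aa


@dataclass(frozen=True)
class CassetteDesign:
    """The assembled poly-antigen cassette."""

    segments: tuple[FlankedSegment, ...]
    leader_nt: str
    cassette_nt: str
    cassette_protein: str


def extract_flanked_segment(
    peptide: str,
    orf: OrfCandidate,
    transcript: Transcript,
    flank_nt: int = 24,
) -> FlankedSegment:
    """Cut the peptide plus up to ``flank_nt`` bp of natural flank per side.

    Flanks are taken in frame from the ORF protein and truncate where the
    ORF ends (start Met upstream, stop codon downstream).  If the peptide
    occurs more than once in the ORF, the leftmost occurrence is used
    with a warning; a peptide absent from the ORF is rejected.
    """
    if flank_nt % 3:
        raise ValueError(f"flank_nt must be divisible by 3, got {flank_nt}")
    prot = orf.protein
    pos = prot.find(peptide)
    if pos < 0:
        raise ValueError(
            f"peptide {peptide!r} not found in ORF protein of {orf.transcript_id}"
        )
    if prot.find(peptide, pos + 1) >= 0:
        warnings.warn(
            f"peptide {peptide!r} occurs multiple times in ORF of "
            f"{orf.transcript_id}; using leftmost occurrence"
        )
    flank_aa = flank_nt // 3
    up = min(flank_aa, pos)
    down = min(flank_aa, len(prot) - pos - len(peptide))
    nt_start = orf.start_nt + 3 * (pos - up)
    nt_end = orf.start_nt + 3 * (pos + len(peptide) + down)
    nt = transcript.sequence[nt_start:nt_end]
    seg = FlankedSegment(
        peptide=peptide,
        upstream_aa=prot[pos - up : pos],
        downstream_aa=prot[pos + len(peptide) : pos + len(peptide) + down],
        nt_segment=nt,
        source_transcript_id=transcript.transcript_id,
    )
    assert translate(seg.nt_segment, 0) == seg.protein
    return seg


def assemble_cassette(
    segments: Sequence[FlankedSegment],
    kozak: str = DEFAULT_KOZAK,
    tpa_leader: str = DEFAULT_TPA_LEADER,
) -> CassetteDesign:
    """Concatenate flanked segments in frame behind Kozak + tPA leader.

    Every segment's nucleotide length must be divisible by 3 so codons
    never span junctions.  Should a stop codon nonetheless appear in the
    post-leader translation, a warning names the offending junction
    (segment index); nothing is recoded.
    """
    for i, s in enumerate(segments):
        if len(s.nt_segment) % 3:
            raise ValueError(f"segment {i} length {len(s.nt_segment)} not divisible by 3")
    leader_nt = kozak + tpa_leader
    body = "".join(s.nt_segment for s in segments)
    cassette_nt = leader_nt + body
    # translation read in frame immediately after the leader
    protein = translate(body, 0)
    if "*" in protein:
        # map the stop back to a segment index
        stop_aa = protein.index("*")
        acc = 0
        for i, s in enumerate(segments):
            acc += len(s.nt_segment) // 3
            if stop_aa < acc:
                warnings.warn(f"internal stop codon within/at junction of segment {i}")
                break
    return CassetteDesign(
        segments=tuple(segments),
        leader_nt=leader_nt,
        cassette_nt=cassette_nt,
        cassette_protein=protein,
    )


def cloning_amplicon(
    orf: OrfCandidate,
    transcript: Transcript,
    upstream_nt: int = 30,
) -> str:
    """The PCR amplicon for ORF-tag cloning: upstream context + ORF minus stop.

    Spans ``transcript[max(0, start_nt - upstream_nt) : end_nt - 3]``.
    The upstream context may be shorter than ``upstream_nt`` when the ORF
    sits near the transcript 5' end.  An ORF without a stop codon is
    rejected (there is no stop to drop).
    """
    if not orf.has_stop:
        raise ValueError(
            f"ORF at {orf.transcript_id}:{orf.start_nt} has no stop codon; "
            "cannot build an in-frame tagged amplicon"
        )
    return transcript.sequence[max(0, orf.start_nt - upstream_nt) : orf.end_nt - 3]


def design_report(design: CassetteDesign) -> pd.DataFrame:
    """Tabular per-segment report of a cassette design."""
    rows = []
    offset = len(design.leader_nt)
    for i, s in enumerate(design.segments):
        rows.append(
            {
                "segment": i,
                "peptide": s.peptide,
                "upstream_aa": s.upstream_aa,
                "downstream_aa": s.downstream_aa,
                "protein": s.protein,
                "nt_start_in_cassette": offset,
                "nt_length": len(s.nt_segment),
                "source_transcript": s.source_transcript_id,
            }
        )
        offset += len(s.nt_segment)
    return pd.DataFrame(rows)


def write_cassette(
    design: CassetteDesign, fasta_path: str | Path, report_path: str | Path | None = None
) -> None:
    """Write the cassette FASTA (with per-segment feature lines) + TSV report."""
    with open(fasta_path, "w") as fh:
        fh.write(
            f">polyantigen_cassette length={len(design.cassette_nt)}nt "
            f"segments={len(design.segments)} leader={len(design.leader_nt)}nt\n"
        )
        seq = design.cassette_nt
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    if report_path is not None:
        design_report(design).to_csv(report_path, sep="\t", index=False)
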