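"""Peptide provenance assignment and immunopeptidome summaries.

MS-identified MHC class I peptides are matched by exact substring search
against two databases: the canonical proteome (SwissProt-like) and the
lncRNA-derived target database.  A peptide matching only the lncRNA
database is called lncRNA-unique; canonical evidence dominates, so a
peptide found in both is 'shared', never lncRNA-unique.  Candidate
source ORFs are attached by containment in ATG-to-stop ORF products.

Significance calls (up/down/unchanged) are consumed as input flags from
the upstream quantitative analysis; this module only aggregates them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .dbbuild import DbEntry
from .seqcore import AA_ALPHABET, OrfCandidate, Transcript, enumerate_orfs

Provenance = Literal["canonical", "lncRNA_unique", "shared", "unmatched"]
RegulationFlag = Literal["up", "down", "unchanged"]


@dataclass
class PeptideObservation:
    """One MS-identified peptide with optional quantitation."""

    sequence: str
    abundance_by_condition: Mapping[str, float] | None = None
    regulation_flag: RegulationFlag | None = None
    provenance: Provenance | None = None
    source_orfs: list[OrfCandidate] = field(default_factory=list)


def _validate_peptide(p: str) -> None:
    if not p:
        raise ValueError("empty peptide")
    bad = set(p) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue(s) in peptide {p!r}: {sorted(bad)}")


def _collapse_il(s: str) -> str:
    return s.replace("I", "L")


def classify_peptide_provenance(
    peptide: str,
    canonical: Mapping[str, str] | Iterable[str],
    lnc_targets: Sequence[DbEntry] | Iterable[str],
    il_equivalent: bool = False,
) -> Provenance:
    """Classify a peptide against the canonical and lncRNA target databases.

    ``il_equivalent=True`` collapses I and L on both sides before
    matching (mass spectrometry cannot distinguish them); off by default.
    """
    _validate_peptide(peptide)
    canon_seqs = canonical.values() if isinstance(canonical, Mapping) else canonical
    lnc_seqs = [
        e.protein_segment if isinstance(e, DbEntry) else e for e in lnc_targets
    ]
    query = _collapse_il(peptide) if il_equivalent else peptide
    prep = _collapse_il if il_equivalent else (lambda s: s)
    in_canon = any(query in prep(s) for s in canon_seqs)
    in_lnc = any(query in prep(s) for s in lnc_seqs)
    if in_canon and in_lnc:
        return "shared"
    if in_canon:
        return "canonical"
    if in_lnc:
        return "lncRNA_unique"
    return "unmatched"


def assign_orfs_to_peptide(
    peptide: str,
    transcripts: Iterable[Transcript],
    require_stop: bool = True,
) -> list[OrfCandidate]:
    """All ATG-to-stop ORFs whose protein contains the peptide.

    Searched across all supplied transcripts; sorted by
    (transcript_id, frame, start_nt); an empty result is allowed.
    """
    _validate_peptide(peptide)
    hits = [
        orf
        for t in transcripts
        for orf in enumerate_orfs(t, require_stop=require_stop)
        if peptide in orf.protein
    ]
    hits.sort(key=lambda o: (o.transcript_id, o.frame, o.start_nt))
    return hits


def peptide_length_distribution(
    peptides: Sequence[str] | Sequence[PeptideObservation],
) -> tuple[dict[int, int], float]:
    """Counts per peptide length and the mean length (1 decimal).

    MHC class I ligands are typically 8-11-mers with a mode at 9; this
    reproduces the pie-chart summary of that distribution.
    """
    seqs = [p.sequence if isinstance(p, PeptideObservation) else p for p in peptides]
    if not seqs:
        raise ValueError("empty peptide set")
    lengths = [len(s) for s in seqs]
    counts = dict(sorted(Counter(lengths).items()))
    return counts, round(sum(lengths) / len(lengths), 1)


def normalize_to_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its mean so every row mean becomes exactly 1.

    This is the relative-abundance normalisation used for heat-map
    display of peptide/transcript abundance across conditions.  Rows
    whose mean is not strictly positive are rejected by label.
    """
    means = matrix.mean(axis=1)
    bad = means.index[means <= 0]
    if len(bad):
        raise ValueError(f"row {bad[0]!r} has non-positive mean; cannot normalise")
    return matrix.div(means, axis=0)


def summarize_regulation(
    observations: Sequence[PeptideObservation] | Sequence[str],
) -> dict[str, dict[str, float]]:
    """Fractions of up-/down-/unchanged peptides, as percentages.

    Returns ``{"counts": {...}, "percent": {...}}``; percentages sum to
    100 up to rounding.  Every observation must carry a flag.
    """
    flags = [
        o.regulation_flag if isinstance(o, PeptideObservation) else o
        for o in observations
    ]
    if not flags:
        raise ValueError("empty observation set")
    for i, f in enumerate(flags):
        if f not in ("up", "down", "unchanged"):
            raise ValueError(f"observation {i} has missing/invalid regulation flag: {f!r}")
    n = len(flags)
    counts = {k: flags.count(k) for k in ("up", "down", "unchanged")}
    percent = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return {"counts": counts, "percent": percent}


def build_peptide_report(
    peptides: Sequence[str],
    canonical: Mapping[str, str],
    lnc_targets: Sequence[DbEntry],
    transcripts: Sequence[Transcript],
    il_equivalent: bool = False,
) -> pd.DataFrame:
    """Per-peptide provenance report with attached ORF evidence.

    One row per peptide: provenance, number of containing ORFs and the
    coordinates of the best (longest) ORF, all lncRNA sources listed.
    """
    rows = []
    for p in peptides:
        prov = classify_peptide_provenance(p, canonical, lnc_targets, il_equivalent)
        orfs = (
            assign_orfs_to_peptide(p, transcripts)
            if prov in ("lncRNA_unique", "shared")
            else []
        )
        best = max(orfs, key=lambda o: o.length_aa, default=None)
        rows.append(
            {
                "sequence": p,
                "length": len(p),
                "provenance": prov,
                "n_orfs": len(orfs),
                "source_transcripts": ",".join(sorted({o.transcript_id for o in orfs})),
                "best_orf": (
                    f"{best.transcript_id}:F{best.frame}:{best.start_nt}-{best.end_nt}"
                    if best
                    else ""
                ),
                "best_orf_aa": best.length_aa if best else 0,
            }
        )
    return pd.DataFrame(rows)
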