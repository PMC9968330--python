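"""Transcription-factor target classification from ChIP-seq peaks.

A gene is scored a potential direct E2F1 target if any ChIP-seq peak
intersects the 1000-bp window centred on its TSS (500 bp either side,
half-open, >= 1 shared nt).  A gene that is not direct but whose gene
boundaries overlap, or are contained within, the boundaries of a direct
target gene (same or opposite strand) is scored 'associated'; everything
else is 'none'.  Precedence is direct > associated > none.

The reference set for 'associated' is built by applying the same peak
rule to every gene supplied (lncRNA genes plus any reference genes);
peaks from multiple tracks/cell lines may simply be pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

TargetClass = Literal["direct", "associated", "none"]


@dataclass(frozen=True)
class PeakInterval:
    """A ChIP-seq peak, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak end must exceed start: {self}")


@dataclass(frozen=True)
class GeneRecord:
    """Gene-level annotation used for target scoring."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise ValueError(f"{self.gene_id}: missing/invalid strand {self.strand!r}")


@dataclass
class GeneTargetCall:
    gene_id: str
    tss: int
    window: tuple[int, int]
    target_class: TargetClass
    evidence: list[str] = field(default_factory=list)


def genes_from_annotation(
    ann: pd.DataFrame, tss_policy: Literal["representative", "five_prime"] = "representative"
) -> list[GeneRecord]:
    """Collapse a transcript annotation table to gene records.

    ``representative`` keeps the first annotated transcript per gene;
    ``five_prime`` takes gene boundaries as the union over isoforms (the
    TSS then being the 5'-most start).
    """
    out = []
    for gid, grp in ann.groupby("gene_id", sort=False):
        if tss_policy == "representative":
            row = grp.iloc[0]
            out.append(
                GeneRecord(str(gid), row.chrom, row.strand, int(row.start), int(row.end))
            )
        elif tss_policy == "five_prime":
            row = grp.iloc[0]
            out.append(
                GeneRecord(
                    str(gid),
                    row.chrom,
                    row.strand,
                    int(grp.start.min()),
                    int(grp.end.max()),
                )
            )
        else:
            raise ValueError(f"unknown tss_policy {tss_policy!r}")
    return out


def tss_window(gene: GeneRecord, half_width: int = 500) -> tuple[int, int]:
    """Half-open promoter window [tss - half_width, tss + half_width), clamped at 0."""
    tss = gene.tss  # raises on missing strand
    return (max(0, tss - half_width), tss + half_width)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_gene_targets(
    lnc_genes: Sequence[GeneRecord],
    peaks: Iterable[PeakInterval] | pd.DataFrame,
    reference_genes: Sequence[GeneRecord] = (),
    half_width: int = 500,
) -> list[GeneTargetCall]:
    """Classify each lncRNA gene as direct / associated / none.

    ``reference_genes`` extends the pool from which direct targets (and
    hence 'associated' anchors) are drawn; lncRNA genes themselves always
    participate.  Peaks on chromosomes absent from the annotation are
    ignored with a warning.  The result is independent of the input
    ordering of peaks and genes.
    """
    if isinstance(peaks, pd.DataFrame):
        names = (
            peaks["name"].astype(str).tolist()
            if "name" in peaks.columns
            else [""] * len(peaks)
        )
        peaks = [
            PeakInterval(str(c), int(s), int(e), nm)
            for c, s, e, nm in zip(peaks["chrom"], peaks["start"], peaks["end"], names)
        ]
    all_genes = list(lnc_genes) + [g for g in reference_genes if g not in lnc_genes]
    chroms = {g.chrom for g in all_genes}
    by_chrom: dict[str, list[PeakInterval]] = {}
    for p in peaks:
        if p.chrom not in chroms:
            warnings.warn(f"peak on unannotated chromosome {p.chrom!r} ignored")
            continue
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: (p.start, p.end))

    def window_peaks(g: GeneRecord) -> list[PeakInterval]:
        lo, hi = tss_window(g, half_width)
        return [
            p for p in by_chrom.get(g.chrom, []) if _overlaps(lo, hi, p.start, p.end)
        ]

    direct_hits = {g.gene_id: window_peaks(g) for g in all_genes}
    direct_genes = sorted(
        (g for g in all_genes if direct_hits[g.gene_id]), key=lambda g: g.gene_id
    )

    calls = []
    for g in lnc_genes:
        lo, hi = tss_window(g, half_width)
        hits = direct_hits[g.gene_id]
        if hits:
            calls.append(
                GeneTargetCall(
                    g.gene_id,
                    g.tss,
                    (lo, hi),
                    "direct",
                    [p.name or f"{p.chrom}:{p.start}-{p.end}" for p in hits],
                )
            )
            continue
        anchors = [
            d.gene_id
            for d in direct_genes
            if d.gene_id != g.gene_id
            and d.chrom == g.chrom
            and _overlaps(g.start, g.end, d.start, d.end)
        ]
        if anchors:
            calls.append(GeneTargetCall(g.gene_id, g.tss, (lo, hi), "associated", anchors))
        else:
            calls.append(GeneTargetCall(g.gene_id, g.tss, (lo, hi), "none", []))
    return calls


def summarize_target_fractions(calls: Sequence[GeneTargetCall]) -> dict[str, float]:
    """Percentage of genes per class, 1 decimal, summing to 100 +/- rounding."""
    if not calls:
        raise ValueError("no gene target calls to summarise")
    n = len(calls)
    return {
        cls: round(100.0 * sum(c.target_class == cls for c in calls) / n, 1)
        for cls in ("direct", "associated", "none")
    }


def calls_to_frame(calls: Sequence[GeneTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "tss": [c.tss for c in calls],
            "window_start": [c.window[0] for c in calls],
            "window_end": [c.window[1] for c in calls],
            "target_class": [c.target_class for c in calls],
            "evidence": [";".join(c.evidence) for c in calls],
        }
    )
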