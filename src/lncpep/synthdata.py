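"""Synthetic datasets with planted ground truth for the whole pipeline.

The generators emulate, at toy scale, the inputs the pipeline consumes in
a real study: lncRNA transcripts carrying planted smORFs (mostly <100
residues), a TPM table spanning the three expression bins across two
treatment conditions with replicates, a canonical proteome, MS peptide
lists of known provenance (8-11-mers, mode 9), and ChIP-seq peaks placed
inside or outside TSS windows so that direct/associated/none target
classes are known by construction.  Every generator records its ground
truth in a :class:`TruthManifest` sufficient to predict every downstream
call, and is deterministic for a fixed seed.

Geometry conventions: standalone genes are laid out with >= 5 kb gaps and
genomic spans at least three times their spliced length (introns), so a
promoter peak can never touch a neighbouring gene's window.  'Nested'
genes are placed >= 1200 nt inside a host gene's span; each host carries
at most one nested gene so target-class counts can be made exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ANNOTATION_COLUMNS,
    write_annotation_gtf,
    write_expression_tsv,
    write_fasta,
    write_peaks_bed,
)
from .regclass import GeneRecord
from .seqcore import Transcript, translate, _CODON_TO_AA

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(c for c, aa in _CODON_TO_AA.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in _CODON_TO_AA.items() if aa == "*")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# MHC class I ligand length model: 8-11-mers, mode 9, mean exactly 9.0.
PEPTIDE_LENGTH_PROBS: dict[int, float] = {8: 0.25, 9: 0.55, 10: 0.15, 11: 0.05}

_NESTED_TX_LEN = 300  # spliced length of nested genes (single exon)
_NESTED_MARGIN = 1200  # distance kept from both host edges
_GAP = 5000  # intergenic gap between standalone genes


@dataclass
class TruthManifest:
    """Planted ground truth: predicts every downstream pipeline call."""

    orfs: dict[str, list[dict]] = field(default_factory=dict)
    bins: dict[str, str] = field(default_factory=dict)
    nested_in: dict[str, str] = field(default_factory=dict)  # gene -> host gene
    peptides: list[dict] = field(default_factory=list)
    target_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _largest_remainder_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, closest to n * proportions."""
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def generate_transcriptome(
    n_transcripts: int = 100,
    length_range: tuple[int, int] = (400, 1200),
    orf_rate: float = 0.8,
    nested_fraction: float = 0.1,
    orf_aa_range: tuple[int, int] = (15, 90),
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[Transcript], TruthManifest]:
    """Random transcripts with planted ATG-to-stop smORFs and genomic layout.

    ``orf_rate`` is the probability a transcript carries one planted ORF
    (protein length uniform in ``orf_aa_range``, i.e. the <100-residue
    smORF regime).  ``nested_fraction`` of genes are placed inside a
    previously generated standalone gene's span, providing material for
    'associated' target-class designs.  One gene per transcript.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    min_needed = 3 * (orf_aa_range[0] + 1) + 6
    if lo < min_needed or lo > hi:
        raise ValueError(
            f"infeasible length range {length_range}; need at least {min_needed} nt"
        )
    rng = np.random.default_rng(seed)
    n_nested = int(round(nested_fraction * n_transcripts))
    nested_idx = (
        set(rng.choice(np.arange(1, n_transcripts), size=n_nested, replace=False))
        if n_nested
        else set()
    )

    manifest = TruthManifest()
    transcripts: list[Transcript] = []
    free_hosts: list[int] = []  # indices into `transcripts`
    cursor = 10_000
    for i in range(n_transcripts):
        tid, gid = f"TX{i:04d}", f"GENE{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if i in nested_idx and free_hosts:
            length = _NESTED_TX_LEN
            host_i = free_hosts.pop(int(rng.integers(len(free_hosts))))
            host = transcripts[host_i]
            span = length
            max_off = (host.genomic_end - host.genomic_start) - span - _NESTED_MARGIN
            offset = int(rng.integers(_NESTED_MARGIN, max_off + 1))
            g_start = host.genomic_start + offset
            g_end = g_start + span
            manifest.nested_in[gid] = host.gene_id
        else:
            length = int(rng.integers(lo, hi + 1))
            span = max(3 * length, _NESTED_TX_LEN + 2 * _NESTED_MARGIN + 300)
            g_start = cursor
            g_end = cursor + span
            cursor = g_end + _GAP

        seq = rng.choice(_BASES, size=length)
        planted: list[dict] = []
        if rng.random() < orf_rate:
            aa_len = int(rng.integers(orf_aa_range[0], orf_aa_range[1] + 1))
            orf_nt = 3 * aa_len + 3
            start_nt = int(rng.integers(0, length - orf_nt + 1))
            codons = (
                ["ATG"]
                + [
                    _NON_STOP_CODONS[j]
                    for j in rng.integers(len(_NON_STOP_CODONS), size=aa_len - 1)
                ]
                + [_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]]
            )
            orf_seq = "".join(codons)
            seq[start_nt : start_nt + orf_nt] = list(orf_seq)
            planted.append(
                {
                    "frame": start_nt % 3,
                    "start_nt": start_nt,
                    "end_nt": start_nt + orf_nt,
                    "protein": translate(orf_seq, 0)[:-1],
                }
            )
        t = Transcript(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            genomic_start=g_start,
            genomic_end=g_end,
            sequence="".join(seq),
        )
        transcripts.append(t)
        manifest.orfs[tid] = planted
        if gid not in manifest.nested_in:
            free_hosts.append(i)
    return transcripts, manifest


def annotation_frame(transcripts: Sequence[Transcript]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "start": t.genomic_start,
                "end": t.genomic_end,
            }
            for t in transcripts
        ],
        columns=ANNOTATION_COLUMNS,
    )


def genes_of(transcripts: Sequence[Transcript]) -> list[GeneRecord]:
    return [
        GeneRecord(t.gene_id, t.chrom, t.strand, t.genomic_start, t.genomic_end)
        for t in transcripts
    ]


def generate_expression(
    transcripts: Sequence[Transcript],
    proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    conditions: tuple[str, str] = ("DMSO", "T1_44"),
    n_replicates: int = 3,
    regulated_fraction: float = 0.3,
    effect_size: float = 2.0,
    manifest: TruthManifest | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """TPM table placing each transcript in its designed expression bin.

    ``proportions`` over {non_expressed, low, high} must sum to 1; counts
    are allocated exactly (largest remainder).  Replicate values are
    drawn inside bin-safe intervals so the designed bin is recovered by
    ``bin_expression`` under the max aggregator: non-expressed exactly 0,
    low in (0.55, 0.95), high >= 1.05.  Among 'high' transcripts,
    ``regulated_fraction`` get a ``effect_size``-fold shift between the
    two conditions (random direction) to emulate treatment response.
    """
    props = dict(proportions or {"non_expressed": 0.3, "low": 0.2, "high": 0.5})
    keys = ["non_expressed", "low", "high"]
    total = sum(props.get(k, 0.0) for k in keys)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"bin proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    n = len(transcripts)
    counts = _largest_remainder_counts([props.get(k, 0.0) for k in keys], n)
    order = rng.permutation(n)
    bins: dict[str, str] = {}
    pos = 0
    for k, c in zip(keys, counts):
        for idx in order[pos : pos + c]:
            bins[transcripts[idx].transcript_id] = k
        pos += c

    samples = [f"{c}_rep{r + 1}" for c in conditions for r in range(n_replicates)]
    data = {}
    for t in transcripts:
        b = bins[t.transcript_id]
        if b == "non_expressed":
            vals = [0.0] * len(samples)
        elif b == "low":
            vals = list(rng.uniform(0.55, 0.95, size=len(samples)))
        else:
            base = float(np.exp(rng.normal(np.log(10.0), 1.0)))
            means = [base, base]
            if rng.random() < regulated_fraction:
                if rng.random() < 0.5:
                    means[1] = base * effect_size
                else:
                    means[1] = base / effect_size
            vals = []
            for ci in range(2):
                jitter = rng.uniform(0.85, 1.15, size=n_replicates)
                vals.extend(np.maximum(1.05, means[ci] * jitter))
        data[t.transcript_id] = vals
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    df.index.name = "transcript_id"
    if manifest is not None:
        manifest.bins.update(bins)
    return df, bins


def generate_proteome(
    n_proteins: int = 40,
    length_range: tuple[int, int] = (150, 400),
    seed: int = 0,
) -> dict[str, str]:
    """A random canonical proteome (SwissProt stand-in, uniform residues)."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA20))
    out = {}
    for i in range(n_proteins):
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        out[f"sp|P{i:05d}|SYNTH{i:03d}"] = "".join(rng.choice(aa, size=ln))
    return out


def _sample_length(rng: np.random.Generator, probs: Mapping[int, float]) -> int:
    ls = sorted(probs)
    return int(rng.choice(ls, p=[probs[l] for l in ls]))


def generate_peptides(
    transcripts: Sequence[Transcript],
    bins: Mapping[str, str],
    orf_manifest: Mapping[str, list[dict]],
    proteome: Mapping[str, str],
    n_lnc: int = 60,
    n_canonical: int = 30,
    n_unmatched: int = 10,
    regulation_proportions: tuple[float, float, float] = (0.10, 0.32, 0.58),
    length_probs: Mapping[int, float] | None = None,
    seed: int = 0,
    conditions: tuple[str, str] = ("DMSO", "T1_44"),
    manifest: TruthManifest | None = None,
) -> pd.DataFrame:
    """MS peptide table with known provenance and regulation flags.

    lncRNA-origin peptides are 8-11-mer substrings of planted ORF
    proteins on expressed (low/high) transcripts, screened against the
    canonical proteome so they are lncRNA-unique by construction.
    Canonical contaminants come from the proteome and are screened
    against all expressed-frame translations.  Unmatched peptides are
    random strings occurring in neither database.  Regulation flags are
    allocated in exact counts per ``regulation_proportions``
    (up, down, unchanged).
    """
    probs = dict(length_probs or PEPTIDE_LENGTH_PROBS)
    rng = np.random.default_rng(seed)
    expressed = [
        t for t in transcripts if bins.get(t.transcript_id) in ("low", "high")
    ]
    expressed_frames = [
        translate(t.sequence, f) for t in expressed for f in (0, 1, 2)
    ]
    canon_seqs = list(proteome.values())
    sources = [
        (t.transcript_id, o["protein"])
        for t in expressed
        for o in orf_manifest.get(t.transcript_id, [])
        if len(o["protein"]) >= max(probs)
    ]
    if n_lnc > 0 and not sources:
        raise ValueError("no planted ORFs on expressed transcripts to sample from")

    chosen: dict[str, tuple[str, str]] = {}  # seq -> (provenance, source)
    attempts = 0
    while sum(v[0] == "lncRNA_unique" for v in chosen.values()) < n_lnc:
        attempts += 1
        if attempts > 500 * max(n_lnc, 1):
            raise ValueError(
                "cannot plant the requested number of distinct lncRNA peptides"
            )
        tid, prot = sources[int(rng.integers(len(sources)))]
        ln = _sample_length(rng, probs)
        if len(prot) < ln:
            continue
        start = int(rng.integers(0, len(prot) - ln + 1))
        pep = prot[start : start + ln]
        if pep in chosen or any(pep in s for s in canon_seqs):
            continue
        chosen[pep] = ("lncRNA_unique", tid)

    attempts = 0
    n_canon_done = 0
    while n_canon_done < n_canonical:
        attempts += 1
        if attempts > 500 * max(n_canonical, 1):
            raise ValueError("cannot sample the requested canonical contaminants")
        pid = list(proteome)[int(rng.integers(len(proteome)))]
        prot = proteome[pid]
        ln = _sample_length(rng, probs)
        start = int(rng.integers(0, len(prot) - ln + 1))
        pep = prot[start : start + ln]
        if pep in chosen or any(pep in s for s in expressed_frames):
            continue
        chosen[pep] = ("canonical", pid)
        n_canon_done += 1

    aa = np.array(list(_AA20))
    attempts = 0
    n_unm_done = 0
    while n_unm_done < n_unmatched:
        attempts += 1
        if attempts > 500 * max(n_unmatched, 1):
            raise ValueError("cannot sample the requested unmatched peptides")
        pep = "".join(rng.choice(aa, size=_sample_length(rng, probs)))
        if (
            pep in chosen
            or any(pep in s for s in canon_seqs)
            or any(pep in s for s in expressed_frames)
        ):
            continue
        chosen[pep] = ("unmatched", "")
        n_unm_done += 1

    peps = list(chosen)
    n_total = len(peps)
    flag_counts = _largest_remainder_counts(regulation_proportions, n_total)
    flags = (
        ["up"] * flag_counts[0]
        + ["down"] * flag_counts[1]
        + ["unchanged"] * flag_counts[2]
    )
    flags = [flags[i] for i in rng.permutation(n_total)]

    rows = []
    for pep, flag in zip(peps, flags):
        prov, src = chosen[pep]
        base = float(np.exp(rng.normal(np.log(1e4), 0.5)))
        if flag == "up":
            second = base * rng.uniform(2.0, 5.0)
        elif flag == "down":
            second = base / rng.uniform(2.0, 5.0)
        else:
            second = base * rng.uniform(0.95, 1.05)
        rows.append(
            {
                "sequence": pep,
                conditions[0]: round(base, 2),
                conditions[1]: round(float(second), 2),
                "regulation_flag": flag,
            }
        )
        if manifest is not None:
            manifest.peptides.append(
                {
                    "sequence": pep,
                    "provenance": prov,
                    "source": src,
                    "regulation_flag": flag,
                }
            )
    return pd.DataFrame(rows)


def generate_peaks(
    transcripts: Sequence[Transcript],
    nested_in: Mapping[str, str],
    direct_fraction: float = 0.8,
    associated_fraction: float = 0.1,
    seed: int = 0,
    half_width: int = 500,
    peak_half: int = 50,
    manifest: TruthManifest | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Promoter peaks realising an exact direct/associated/none design.

    Direct genes get one peak strictly inside their TSS window;
    associated genes are nested genes whose host is made direct and which
    receive no peak of their own; all remaining genes stay peak-free.
    Counts are exact (largest remainder).  Infeasible designs — more
    associated genes than nested candidates, or associated without
    enough direct slots for their hosts — are rejected.
    """
    if direct_fraction + associated_fraction > 1 + 1e-9:
        raise ValueError("direct_fraction + associated_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    genes = genes_of(transcripts)
    n = len(genes)
    n_direct, n_assoc = _largest_remainder_counts(
        [direct_fraction, associated_fraction, 1 - direct_fraction - associated_fraction],
        n,
    )[:2]
    by_id = {g.gene_id: g for g in genes}
    nested = [g for g in genes if g.gene_id in nested_in]
    hosts_all = set(nested_in.values())
    if n_assoc > len(nested):
        raise ValueError(
            f"geometric infeasibility: {n_assoc} associated genes designed but "
            f"only {len(nested)} nested genes available"
        )
    if n_assoc > n_direct:
        raise ValueError(
            "geometric infeasibility: each associated gene needs its host "
            "among the direct genes"
        )
    assoc_pick = [
        nested[i] for i in rng.choice(len(nested), size=n_assoc, replace=False)
    ] if n_assoc else []
    direct_ids = {nested_in[g.gene_id] for g in assoc_pick}
    pool = [
        g
        for g in genes
        if g.gene_id not in hosts_all
        and g.gene_id not in nested_in
        and g.gene_id not in direct_ids
    ]
    n_more = n_direct - len(direct_ids)
    if n_more > len(pool):
        raise ValueError(
            "geometric infeasibility: not enough standalone genes for the "
            "requested direct fraction"
        )
    if n_more:
        direct_ids |= {
            pool[i].gene_id for i in rng.choice(len(pool), size=n_more, replace=False)
        }

    rows = []
    for gid in sorted(direct_ids):
        tss = by_id[gid].tss
        rows.append(
            {
                "chrom": by_id[gid].chrom,
                "start": max(0, tss - peak_half),
                "end": tss + peak_half,
                "name": f"peak_{gid}",
            }
        )
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    expected = {}
    assoc_ids = {g.gene_id for g in assoc_pick}
    for g in genes:
        if g.gene_id in direct_ids:
            expected[g.gene_id] = "direct"
        elif g.gene_id in assoc_ids:
            expected[g.gene_id] = "associated"
        else:
            expected[g.gene_id] = "none"
    if manifest is not None:
        manifest.target_classes.update(expected)
    return peaks, expected


@dataclass
class SyntheticDataset:
    transcripts: list[Transcript]
    annotation: pd.DataFrame
    tpm: pd.DataFrame
    proteome: dict[str, str]
    peptides: pd.DataFrame
    peaks: pd.DataFrame
    manifest: TruthManifest


def simulate(
    seed: int = 0,
    n_transcripts: int = 100,
    outdir: str | Path | None = None,
    bin_proportions: Mapping[str, float] | None = None,
    direct_fraction: float = 0.8,
    associated_fraction: float = 0.1,
    n_lnc_peptides: int = 60,
    n_canonical_peptides: int = 30,
    n_unmatched_peptides: int = 10,
    **transcriptome_kwargs,
) -> SyntheticDataset:
    """Generate a complete, internally consistent dataset (optionally written).

    When ``outdir`` is given, writes transcripts.fa, annotation.gtf,
    expression.tsv, proteome.fa, peptides.tsv, peaks.bed and
    manifest.json in the standard formats the CLIs consume.
    """
    rng = np.random.default_rng(seed)
    s = [int(x) for x in rng.integers(0, 2**31 - 1, size=5)]
    transcripts, manifest = generate_transcriptome(
        n_transcripts=n_transcripts, seed=s[0], **transcriptome_kwargs
    )
    tpm, bins = generate_expression(
        transcripts, proportions=bin_proportions, seed=s[1], manifest=manifest
    )
    proteome = generate_proteome(seed=s[2])
    peptides = generate_peptides(
        transcripts,
        bins,
        manifest.orfs,
        proteome,
        n_lnc=n_lnc_peptides,
        n_canonical=n_canonical_peptides,
        n_unmatched=n_unmatched_peptides,
        seed=s[3],
        manifest=manifest,
    )
    peaks, _ = generate_peaks(
        transcripts,
        manifest.nested_in,
        direct_fraction=direct_fraction,
        associated_fraction=associated_fraction,
        seed=s[4],
        manifest=manifest,
    )
    ann = annotation_frame(transcripts)
    ds = SyntheticDataset(transcripts, ann, tpm, proteome, peptides, peaks, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({t.transcript_id: t.sequence for t in transcripts}, outdir / "transcripts.fa")
        write_annotation_gtf(ann, outdir / "annotation.gtf")
        write_expression_tsv(tpm, outdir / "expression.tsv")
        write_fasta(proteome, outdir / "proteome.fa")
        peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        write_peaks_bed(peaks, outdir / "peaks.bed")
        manifest.to_json(outdir / "manifest.json")
    return ds
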