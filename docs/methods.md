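# Methods

## Scope and model

`lncpep` implements the computational arm of a proteogenomic workflow for
discovering MHC class I peptides encoded by long non-coding RNAs and
engineering them into a vectored vaccine. The wet-lab and heavy-compute
stages that surround it — read trimming/alignment/quantification,
spectrum-level peptide identification, differential-expression testing,
MHC binding prediction — are treated as upstream or downstream tools whose
outputs (TPM tables, peptide lists with significance flags, affinity ranks)
this package consumes as flat files.

## Translation and ORF model

Translation uses the standard genetic code over `{A,C,G,T,N}`. Two strict
rules matter downstream and are therefore not delegated to a library call:
any codon containing `N` translates to `X` (never resolved, even when the
degenerate codon would be unambiguous), so that an uncertain base can never
support a peptide match; and invalid characters are rejected with the
offending position named. Trailing partial codons are dropped, giving the
frame-length invariant `len(protein) == floor((L - frame)/3)`.

Translation is **3-frame, sense strand only** — the database procedure is
defined on the spliced transcript, not the genome, so antisense frames are
never produced. An ORF is every ATG to its first in-frame stop; nested ORFs
sharing a stop are all reported, since any of them could be the translated
unit. ORFs running off the 3' end are excluded by default (`require_stop`)
because the definition demands a stop codon; they can be included for
exploratory scans. Near-cognate (non-ATG) initiation is not enumerated by
default — whether the original databases admitted it is not documented — but
the start-codon set is configurable (`start_codons=("ATG", "CTG", ...)`).

Molecular weights are average residue masses plus one water (Biopython's
ProtParam), reported in kDa; they support sanity-checking candidate ORF
products (e.g. a ~26 kDa smORF polypeptide), not any fitted quantity.

## Expression gating and database construction

Transcripts are binned on a summary TPM: `<= zero_eps` (default 1e-9, to
absorb quantifier float noise) → *non-expressed*; strictly between 0.5 and
1.0 → *low*; `>= 1.0` → *high*. Two choices were genuinely open:

- **The gap (0, 0.5]** is undefined by the three published bins; such
  transcripts are excluded from both databases rather than silently
  assigned, since a borderline transcript in either database would
  contaminate FDR calibration.
- **Exactly 1.0** is assigned to *high*; reading both "<1.0" and ">1.0"
  strictly would orphan exactly-1.0 transcripts.
- **The summary aggregator** is the maximum across samples (expressed "at
  detectable levels" in any sample), switchable to the mean; whether the
  original gating pooled conditions is not documented, so the choice is
  explicit configuration.

Frame translations are split at stops and every maximal stop-free segment of
at least `min_segment_aa` residues (default 7, the shortest plausible class I
ligand) becomes one database entry, because search engines require stop-free
entries. Low-bin transcripts enter the target database by default
(switchable), non-expressed transcripts produce the decoy entries by the
identical construction, and the decoy prefix (default `DECOY_`) marks them
in the FASTA. Reversed/shuffled decoys and FDR estimation are out of scope:
the decoy here *is* the translated non-expressed set.

## Peptide provenance

Matching is exact substring search against full protein strings; an optional
I/L-collapsed mode exists because mass spectrometry cannot distinguish
isoleucine from leucine, but it is off by default. Canonical evidence
dominates: a peptide found in both databases is `shared`, never
`lncRNA_unique`, which keeps the "unique lncRNA-derived" set conservative.
Peptides mapping to several lncRNA ORFs are reported once with all sources
listed, rather than double-counted. Regulation calls (up/down/unchanged) are
consumed as input flags — the significance testing happened upstream — and
only aggregated into percentages.

## Promoter-window target classification

The promoter window is half-open `[tss - 500, tss + 500)` — exactly 1000 nt,
clamped at the chromosome start — and overlap means at least one shared
nucleotide. TSS is strand-aware (`start` for +, `end - 1` for −) and taken
from the representative (first annotated) transcript per gene, configurable
to the 5'-most isoform start. A gene with any window peak is *direct*; a
non-direct gene whose boundaries intersect a direct gene's boundaries
(strand-blind, containment included) is *associated*; precedence is
direct > associated > none, so a gene satisfying both rules counts once as
direct. Peaks from multiple tracks are pooled; peaks on chromosomes absent
from the annotation are ignored with a warning.

## Cassette and cloning design

Each selected peptide is carried with `flank_nt = 24` bp (8 residues) of
natural flanking sequence per side, copied verbatim from the source
transcript in the ORF's frame. Flanks truncate at the ORF boundaries — the
start methionine and the stop codon — not at the raw transcript ends, which
is what the published truncated example (a 7-residue downstream flank)
implies. Segment lengths are always multiples of 3, so codons never span
junctions; the assembler still scans the post-leader translation and warns
with the segment index if a stop appears (for valid flanked segments the
condition is structurally unreachable, the check guards hand-built
segments). Junction stops are warned, never recoded.

The leader is Kozak (`GCCACC`) plus a tPA signal-peptide CDS. The exact
sequences used in the original constructs are not published, so the package
ships the canonical human tissue plasminogen activator signal CDS as a
configurable default and echoes both into the design report.

The cloning amplicon is `transcript[max(0, start - 30) : end - 3]`: 30 bp of
upstream transcript context (retaining any inherent ribosome-binding
context) through the ORF minus its stop, leaving the 3' end in frame with a
C-terminal tag. Stop-less ORFs are rejected — there is no stop to drop.

## Candidate selection

The three shortlist criteria (predicted MHC affinity rank, thymic expression
of the source lncRNA, regulation q-value) have no published cut-offs, so
thresholds are mandatory configuration with no silent defaults. Survivors
are ordered lexicographically by (affinity rank, thymus expression, q),
ties broken by peptide string, making the shortlist a deterministic total
order stable under input permutation.

## Synthetic data: what it emulates, and what it does not

The generators produce, at desk scale, structurally faithful stand-ins for
the study's inputs: transcripts of 400–1200 nt with planted ATG-to-stop
ORFs of 15–90 residues (the <100-residue smORF regime) at `orf_rate = 0.8`;
a TPM table over two conditions × 3 replicates spanning the three bins
(default 30% non-expressed / 20% low / 50% high, exact counts); a random
canonical proteome; peptide sets of 60 lncRNA-derived / 30 canonical / 10
unmatched with regulation flags allocated in exact 10/32/58 proportions;
and promoter peaks realising an exact 80/10/10 direct/associated/none
design. Peptide lengths are drawn from 8–11 with probabilities
(0.25, 0.55, 0.15, 0.05): mode 9 and mean exactly 9.0, matching the
reported mean ligand size.

Deliberate constructions worth knowing when interpreting green tests:

- Replicate TPMs are drawn inside bin-safe intervals (non-expressed exactly
  0; low in (0.55, 0.95); high clipped at ≥ 1.05), so bin recovery is exact
  by design. Real quantification noise straddles bin boundaries; the tests
  validate the gating logic, not robustness to borderline TPMs.
- Planted peptides are screened at generation time so their intended
  provenance is unambiguous (lncRNA peptides absent from the proteome,
  contaminants absent from expressed-frame translations). Real data contain
  genuinely shared peptides; the classifier handles them (`shared`), the
  generator just does not plant them.
- Gene geometry is simplified: one transcript per gene, ≥5-kb intergenic
  gaps, genomic spans at least 3× the spliced length, nested genes placed
  ≥1.2 kb inside a host with at most one nested gene per host. This makes
  target-class designs exactly realisable; real annotations have overlapping
  isoforms and tangled loci the classifier resolves by the same rules but
  without exact-recovery guarantees.
- Base composition is uniform; a GC-bias knob exists in principle but no
  composition model is claimed. No read-level or spectrum-level simulation
  is attempted.

All generators are deterministic for a fixed seed; `simulate()` derives
per-stage child seeds from one master seed.

## Numerical and problem-size choices

Substring matching is exact string search (the databases at pipeline scale
are a few MB; no suffix indexing is needed). Interval logic is plain
half-open arithmetic — the boundary semantics are the point, and the test
suite scans a 1-nt peak across a window to pin the exact 1000-bp direct
width. The acceptance script runs 1000 random transcripts for the ORF
oracle comparison and a 120-transcript end-to-end dataset, sizes at which
every check completes in seconds while exercising all code paths; the
percentages it reports are computed, never asserted.

## Known limitations

- No FDR estimation from search scores, no spectrum handling, no binding
  prediction — by design, these live in the surrounding tools.
- Provenance is transcript-level; peptides are not mapped back to genomic
  coordinates (no liftover).
- The 3-frame model assumes the supplied FASTA is the sense-strand spliced
  transcript; unstranded assemblies would need 6-frame treatment, which is
  intentionally not offered.
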