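# lncpep

**Discovery and vaccine engineering of lncRNA-derived MHC class I peptides.**

Long non-coding RNAs (lncRNAs) are conventionally annotated as untranslated,
yet many harbour small open reading frames (smORFs, typically <100 residues)
whose products are processed into 8–11-mer peptides presented on MHC class I.
`lncpep` is a tested, reusable implementation of the computational pipeline
that discovers such peptides from immunopeptidomics data and engineers them
into a poly-antigen vaccine cassette:

1. **Search-database construction** (`lncpep.dbbuild`) — every lncRNA
   transcript is translated in all 3 sense frames; transcripts are gated on
   expression (TPM = 0 → *non-expressed*; 0.5 < TPM < 1 → *low*; TPM > 1 →
   *high*). Stop-free segments of low/high transcripts form the **target**
   database; the identically constructed non-expressed set is the **decoy**
   database for FDR calibration in the MS search.
2. **smORF enumeration** (`lncpep.seqcore`) — every ATG-to-in-frame-stop ORF
   in every frame, nested starts included.
3. **Peptide provenance** (`lncpep.pepmap`) — MS-identified peptides are
   substring-matched against the canonical proteome and the lncRNA target
   database (`canonical` / `lncRNA_unique` / `shared` / `unmatched`), with
   candidate source ORFs attached, plus the standard summaries
   (length distribution, normalisation to the row mean, regulation fractions).
4. **TF-target classification** (`lncpep.regclass`) — a gene is a potential
   **direct** E2F1 target if a ChIP-seq peak intersects the 1000-bp window
   centred on its TSS (half-open `[tss−500, tss+500)`), **associated** if its
   gene boundaries overlap a direct target gene (strand-blind), else **none**.
5. **Vaccine design** (`lncpep.cassette`, `lncpep.selection`) — shortlisted
   peptides (high predicted MHC affinity, low thymic expression of the source
   lncRNA, significant regulation under PRMT5 inhibition) are carried into a
   cassette with 24 bp of natural flanking sequence each side, truncated at
   the ORF boundaries, behind a Kozak sequence and tPA secretion leader; ORF
   cloning amplicons include 30 bp of upstream transcript context and drop
   the stop codon.
6. **Synthetic data** (`lncpep.synthdata`) — seeded generators that plant
   smORFs, expression bins, peptides of known provenance and promoter peaks,
   with a truth manifest that predicts every downstream call.

## Worked example

```python
from lncpep import Transcript, enumerate_orfs, extract_flanked_segment
from lncpep.cassette import assemble_cassette

# a transcript whose frame-0 smORF contains the 9-mer RGPSHFSRL
from lncpep.seqcore import translate
seq = ("ATGCAAAGCATAACAGACCCAGGAACAGTACCAAGAGGACCAAGCCACTTCAGCAGACTA"
       "CCACTAGGAGGATGGGCAGAAGACAAACTATAA")
t = Transcript("tx1", "g1", "chr1", "+", 0, len(seq), seq)
orf = enumerate_orfs(t)[0]
seg = extract_flanked_segment("RGPSHFSRL", orf, t, flank_nt=24)
print(seg.protein)             # ITDPGTVPRGPSHFSRLPLGGWAED
print(len(seg.upstream_aa)*3)  # 24
design = assemble_cassette([seg])
print(len(design.cassette_nt)) # 150
```

The printed segment is the 9-mer plus its 8 natural residues (24 bp) per
side; the cassette is the 75-nt segment behind the 75-nt Kozak + tPA leader.

Command-line equivalents:

```bash
lncpep simulate --seed 1 --n-transcripts 100 --out ds/
lncpep builddb --fasta ds/transcripts.fa --tpm ds/expression.tsv \
    --out target.fa --decoy-out decoy.fa
lncpep map --peptides ds/peptides.tsv --canonical ds/proteome.fa \
    --lncdb target.fa --fasta ds/transcripts.fa --out report.tsv
lncpep e2f --genes ds/annotation.gtf --peaks ds/peaks.bed --out calls.tsv
```

On the seeded dataset above, `builddb` reports the target/decoy entry counts,
`map` recovers the planted provenance of all 100 peptides, and `e2f` prints
`{'direct': 80.0, 'associated': 10.0, 'none': 10.0}` — the planted design.

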