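import pytest

from lncpep.cassette import (
    DEFAULT_KOZAK,
    DEFAULT_TPA_LEADER,
    assemble_cassette,
    cloning_amplicon,
    design_report,
    extract_flanked_segment,
    write_cassette,
)
from lncpep.seqcore import Transcript, enumerate_orfs, translate
from conftest import dna_for_protein


def _transcript_with_orf(protein, pad5="", pad3=""):
    """Transcript carrying one ORF encoding `protein` (ATG...stop)."""
    seq = pad5 + dna_for_protein(protein) + pad3
    t = Transcript("T1", "G1", "chr1", "+", 0, max(len(seq), 1), seq)
    orfs = [o for o in enumerate_orfs(t) if o.protein == protein]
    assert orfs, "fixture ORF not recovered"
    return t, orfs[0]


class TestExtractFlankedSegment:
    def test_printed_upstream_context_example(self):
        # 9-mer RGPSHFSRL with 8 natural residues each side inside its ORF
        t, orf = _transcript_with_orf("MQSITDPGTVPRGPSHFSRLPLGGWAEDKL")
        seg = extract_flanked_segment("RGPSHFSRL", orf, t, flank_nt=24)
        assert seg.protein == "ITDPGTVPRGPSHFSRLPLGGWAED"
        assert len(seg.upstream_aa) * 3 == 24
        assert translate(seg.nt_segment, 0) == seg.protein

    def test_downstream_truncated_at_orf_stop(self):
        # KYLRLHERI near the ORF 3' end: only 7 residues remain downstream
        t, orf = _transcript_with_orf("MVCDKAFLKLKYLRLHERIYSGKKPY")
        seg = extract_flanked_segment("KYLRLHERI", orf, t, flank_nt=24)
        assert seg.protein == "CDKAFLKLKYLRLHERIYSGKKPY"
        assert len(seg.downstream_aa) == 7

    def test_upstream_truncated_at_orf_start(self):
        t, orf = _transcript_with_orf("MKWLRSAADDEEFFGG")
        seg = extract_flanked_segment("MKWLRS", orf, t)
        assert seg.upstream_aa == ""
        assert len(seg.downstream_aa) == 8

    def test_flank_truncation_length_rule(self):
        prot = "MABCDEFGHIKLMNPQRSTVWY".replace("B", "A")  # 22 aa, valid alphabet
        t, orf = _transcript_with_orf(prot)
        pep = prot[10:19]
        seg = extract_flanked_segment(pep, orf, t, flank_nt=24)
        avail_up, avail_down = 10, len(prot) - 19
        assert len(seg.protein) == len(pep) + min(8, avail_up) + min(8, avail_down)

    def test_absent_peptide_rejected(self):
        t, orf = _transcript_with_orf("MKWLRSAA")
        with pytest.raises(ValueError, match="not found"):
            extract_flanked_segment("YYYYY", orf, t)

    def test_multiple_occurrences_use_leftmost_with_warning(self):
        t, orf = _transcript_with_orf("MAKWLRSDDKWLRSEE")
        with pytest.warns(UserWarning, match="leftmost"):
            seg = extract_flanked_segment("KWLRS", orf, t)
        assert seg.upstream_aa == "MA"

    def test_flank_must_be_codon_aligned(self):
        t, orf = _transcript_with_orf("MKWLRSAA")
        with pytest.raises(ValueError, match="divisible by 3"):
            extract_flanked_segment("KWLRS", orf, t, flank_nt=20)

    def test_nt_copied_verbatim_from_transcript(self):
        t, orf = _transcript_with_orf("MQSITDPGTVPRGPSHFSRLPLGGWAEDKL", pad5="GGGG")
        seg = extract_flanked_segment("RGPSHFSRL", orf, t)
        assert seg.nt_segment in t.sequence


class TestAssembleCassette:
    def test_length_additivity(self):
        t1, o1 = _transcript_with_orf("MQSITDPGTVPRGPSHFSRLPLGGWAEDKL")
        s1 = extract_flanked_segment("RGPSHFSRL", o1, t1)  # 25 aa -> 75 nt
        t2, o2 = _transcript_with_orf("MVCDKAFLKLKYLRLHERIYSGKKPY")
        s2 = extract_flanked_segment("KYLRLHERI", o2, t2)  # 24 aa -> 72 nt
        design = assemble_cassette([s1, s2])
        leader = DEFAULT_KOZAK + DEFAULT_TPA_LEADER
        assert len(s1.nt_segment) == 75 and len(s2.nt_segment) == 72
        assert len(design.cassette_nt) == len(leader) + 75 + 72
        assert design.cassette_nt == leader + s1.nt_segment + s2.nt_segment

    def test_post_leader_translation_reproduces_segment_proteins(self):
        t, o = _transcript_with_orf("MQSITDPGTVPRGPSHFSRLPLGGWAEDKL")
        seg = extract_flanked_segment("RGPSHFSRL", o, t)
        design = assemble_cassette([seg])
        assert design.cassette_protein == seg.protein
        assert "*" not in design.cassette_protein

    def test_unaligned_segment_rejected(self):
        from lncpep.cassette import FlankedSegment

        bad = FlankedSegment("KK", "", "", "AAAAAAA")  # 7 nt
        with pytest.raises(ValueError, match="divisible by 3"):
            assemble_cassette([bad])

    def test_twenty_segment_cassette_reproduces_all_planted_peptides(self, dataset):
        from lncpep.pepmap import assign_orfs_to_peptide

        by_id = {t.transcript_id: t for t in dataset.transcripts}
        lnc = [p for p in dataset.manifest.peptides if p["provenance"] == "lncRNA_unique"]
        segments = []
        for p in lnc:
            if len(segments) == 20:
                break
            src = by_id[p["source"]]
            orfs = assign_orfs_to_peptide(p["sequence"], [src])
            segments.append(
                extract_flanked_segment(p["sequence"], orfs[0], src)
            )
        assert len(segments) == 20
        design = assemble_cassette(segments)
        for seg in segments:
            assert seg.peptide in design.cassette_protein
            assert translate(seg.nt_segment, 0) == seg.protein
        assert "*" not in design.cassette_protein

    def test_report_and_fasta_written(self, dataset, tmp_path):
        t, o = _transcript_with_orf("MQSITDPGTVPRGPSHFSRLPLGGWAEDKL")
        seg = extract_flanked_segment("RGPSHFSRL", o, t)
        design = assemble_cassette([seg])
        rep = design_report(design)
        assert rep.loc[0, "peptide"] == "RGPSHFSRL"
        fa, tsv = tmp_path / "c.fa", tmp_path / "c.tsv"
        write_cassette(design, fa, tsv)
        assert design.cassette_nt in fa.read_text().replace("\n", "")
        assert tsv.exists()


class TestCloningAmplicon:
    def test_arithmetic_with_full_upstream_context(self):
        # ORF of 30 nt incl. stop, >= 30 nt upstream -> 57-nt amplicon
        prot = "MKWLRSAAD"  # 9 aa -> 30 nt with stop
        pad5 = "ACC" * 11  # 33 nt upstream, no ATG introduced
        t, orf = _transcript_with_orf(prot, pad5=pad5)
        amp = cloning_amplicon(orf, t, upstream_nt=30)
        assert len(amp) == 30 - 3 + 30 == 57

    def test_orf_at_transcript_start(self):
        prot = "MKWLRSAAD"
        t, orf = _transcript_with_orf(prot)
        amp = cloning_amplicon(orf, t, upstream_nt=30)
        assert amp == dna_for_protein(prot)[:-3]

    def test_amplicon_translates_back_to_orf_protein(self):
        prot = "MKWLRSAADGHI".replace("B", "")
        pad5 = "ACC" * 10
        t, orf = _transcript_with_orf(prot, pad5=pad5, pad3="GG")
        amp = cloning_amplicon(orf, t, upstream_nt=30)
        assert translate(amp[30:], 0) == prot

    def test_stopless_orf_rejected(self):
        seq = dna_for_protein("MKKKKK", stop=False)
        t = Transcript("T1", "G1", "chr1", "+", 0, len(seq), seq)
        (orf,) = enumerate_orfs(t, require_stop=False)
        with pytest.raises(ValueError, match="no stop codon"):
            cloning_amplicon(orf, t)
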