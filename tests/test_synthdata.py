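import numpy as np
import pandas as pd
import pytest

from lncpep.dbbuild import bin_expression, build_search_databases
from lncpep.regclass import classify_gene_targets
from lncpep.seqcore import enumerate_orfs
from lncpep.synthdata import (
    TruthManifest,
    generate_expression,
    generate_peaks,
    generate_peptides,
    generate_proteome,
    generate_transcriptome,
    genes_of,
    simulate,
)


class TestTranscriptome:
    def test_deterministic_for_fixed_seed(self):
        a, ma = generate_transcriptome(n_transcripts=50, seed=1)
        b, mb = generate_transcriptome(n_transcripts=50, seed=1)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert ma.orfs == mb.orfs and ma.nested_in == mb.nested_in
        c, _ = generate_transcriptome(n_transcripts=50, seed=2)
        assert [t.sequence for t in a] != [t.sequence for t in c]

    def test_orf_rate_zero_plants_nothing(self):
        _, manifest = generate_transcriptome(n_transcripts=30, orf_rate=0.0, seed=3)
        assert all(not orfs for orfs in manifest.orfs.values())

    def test_manifest_orfs_recovered_verbatim(self):
        transcripts, manifest = generate_transcriptome(n_transcripts=40, seed=4)
        by_id = {t.transcript_id: t for t in transcripts}
        planted = 0
        for tid, orfs in manifest.orfs.items():
            found = {
                (o.frame, o.start_nt, o.end_nt, o.protein)
                for o in enumerate_orfs(by_id[tid])
            }
            for o in orfs:
                assert (o["frame"], o["start_nt"], o["end_nt"], o["protein"]) in found
                planted += 1
        assert planted > 20

    def test_smorf_regime_under_100_residues(self):
        _, manifest = generate_transcriptome(n_transcripts=50, seed=5)
        lengths = [len(o["protein"]) for orfs in manifest.orfs.values() for o in orfs]
        assert lengths and all(l < 100 for l in lengths)

    def test_infeasible_length_range_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_transcriptome(length_range=(30, 40))

    def test_nested_genes_lie_within_their_hosts(self):
        transcripts, manifest = generate_transcriptome(
            n_transcripts=60, nested_fraction=0.2, seed=6
        )
        genes = {g.gene_id: g for g in genes_of(transcripts)}
        assert manifest.nested_in
        for gid, host_id in manifest.nested_in.items():
            g, h = genes[gid], genes[host_id]
            assert h.start + 1200 <= g.start and g.end <= h.end - 1200


class TestExpression:
    def test_designed_bins_recovered_by_binning(self):
        transcripts, _ = generate_transcriptome(n_transcripts=50, seed=7)
        tpm, bins = generate_expression(
            transcripts, {"non_expressed": 0.3, "low": 0.2, "high": 0.5}, seed=7
        )
        got = {r.transcript_id: r.bin for r in bin_expression(tpm)}
        assert got == bins
        assert list(bins.values()).count("non_expressed") == 15

    def test_all_high_design_leaves_decoy_empty(self):
        transcripts, _ = generate_transcriptome(n_transcripts=20, seed=8)
        tpm, _ = generate_expression(
            transcripts, {"non_expressed": 0.0, "low": 0.0, "high": 1.0}, seed=8
        )
        res = build_search_databases(transcripts, bin_expression(tpm))
        assert res.decoys == [] and res.targets

    def test_fixed_seed_reproducibility(self):
        transcripts, _ = generate_transcriptome(n_transcripts=20, seed=9)
        a, _ = generate_expression(transcripts, seed=10)
        b, _ = generate_expression(transcripts, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_proportions_rejected(self):
        transcripts, _ = generate_transcriptome(n_transcripts=5, seed=1)
        with pytest.raises(ValueError, match="sum to 1"):
            generate_expression(transcripts, {"non_expressed": 0.5, "high": 0.6})


@pytest.fixture(scope="module")
def base():
    transcripts, manifest = generate_transcriptome(n_transcripts=60, seed=11)
    tpm, bins = generate_expression(transcripts, seed=11, manifest=manifest)
    proteome = generate_proteome(seed=11)
    return transcripts, manifest, tpm, bins, proteome


@pytest.fixture(scope="module")
def layout():
    return generate_transcriptome(n_transcripts=50, nested_fraction=0.1, seed=16)


class TestPeptides:
    def test_intended_provenance_recovered_completely(self, base):
        transcripts, manifest, tpm, bins, proteome = base
        peps = generate_peptides(
            transcripts, bins, manifest.orfs, proteome, seed=12, manifest=manifest
        )
        res = build_search_databases(transcripts, bin_expression(tpm))
        from lncpep.pepmap import classify_peptide_provenance

        truth = {p["sequence"]: p["provenance"] for p in manifest.peptides}
        assert len(truth) == len(peps) == 100
        for seq in peps.sequence:
            assert classify_peptide_provenance(seq, proteome, res.targets) == truth[seq]

    def test_no_unmatched_when_none_requested(self, base):
        transcripts, manifest, tpm, bins, proteome = base
        peps = generate_peptides(
            transcripts, bins, manifest.orfs, proteome, n_unmatched=0, seed=13
        )
        assert len(peps) == 90

    def test_regulation_proportions_exact_at_n_100(self, base):
        from lncpep.pepmap import summarize_regulation

        transcripts, manifest, tpm, bins, proteome = base
        peps = generate_peptides(
            transcripts, bins, manifest.orfs, proteome, seed=14
        )
        res = summarize_regulation(peps.regulation_flag.tolist())
        assert res["percent"] == {"up": 10.0, "down": 32.0, "unchanged": 58.0}

    def test_infeasible_request_rejected(self, base):
        transcripts, manifest, tpm, bins, proteome = base
        with pytest.raises(ValueError):
            generate_peptides(
                transcripts, {}, manifest.orfs, proteome, n_lnc=10, seed=15
            )


class TestPeaks:
    def test_design_recovered_exactly(self, layout):
        transcripts, manifest = layout
        peaks, expected = generate_peaks(
            transcripts, manifest.nested_in, 0.8, 0.1, seed=17
        )
        calls = classify_gene_targets(genes_of(transcripts), peaks)
        assert {c.gene_id: c.target_class for c in calls} == expected
        counts = pd.Series(expected).value_counts()
        assert counts["direct"] == 40 and counts["associated"] == 5

    def test_zero_direct_means_zero_associated(self, layout):
        transcripts, manifest = layout
        peaks, expected = generate_peaks(
            transcripts, manifest.nested_in, 0.0, 0.0, seed=18
        )
        assert peaks.empty
        calls = classify_gene_targets(genes_of(transcripts), peaks)
        assert all(c.target_class == "none" for c in calls)

    def test_infeasible_designs_rejected(self, layout):
        transcripts, manifest = layout
        with pytest.raises(ValueError, match="infeasibility"):
            generate_peaks(transcripts, manifest.nested_in, 0.1, 0.5, seed=19)
        with pytest.raises(ValueError, match="infeasibility"):
            generate_peaks(transcripts, manifest.nested_in, 0.0, 0.1, seed=19)
        with pytest.raises(ValueError, match="<= 1"):
            generate_peaks(transcripts, manifest.nested_in, 0.9, 0.2, seed=19)

    def test_boundary_edge_peaks_follow_half_open_rule(self, layout):
        from lncpep.regclass import PeakInterval, tss_window

        transcripts, _ = layout
        g = genes_of(transcripts)[0]
        lo, hi = tss_window(g)
        at_edge = classify_gene_targets([g], [PeakInterval(g.chrom, hi, hi + 1)])
        inward = classify_gene_targets([g], [PeakInterval(g.chrom, hi - 1, hi)])
        assert at_edge[0].target_class == "none"
        assert inward[0].target_class == "direct"


class TestSimulate:
    def test_writes_complete_dataset(self, tmp_path):
        out = tmp_path / "ds"
        ds = simulate(seed=2, n_transcripts=30, outdir=out)
        for fname in (
            "transcripts.fa",
            "annotation.gtf",
            "expression.tsv",
            "proteome.fa",
            "peptides.tsv",
            "peaks.bed",
            "manifest.json",
        ):
            assert (out / fname).exists(), fname
        manifest = TruthManifest.from_json(out / "manifest.json")
        assert manifest.bins == ds.manifest.bins
        assert manifest.target_classes == ds.manifest.target_classes

    def test_round_trip_through_standard_formats(self, tmp_path):
        from lncpep.io import load_transcripts, read_expression_tsv, read_peaks_bed

        out = tmp_path / "ds"
        ds = simulate(seed=3, n_transcripts=30, outdir=out)
        transcripts = load_transcripts(out / "transcripts.fa", out / "annotation.gtf")
        assert [t.transcript_id for t in transcripts] == [
            t.transcript_id for t in ds.transcripts
        ]
        assert [t.genomic_start for t in transcripts] == [
            t.genomic_start for t in ds.transcripts
        ]
        tpm = read_expression_tsv(out / "expression.tsv")
        got = {r.transcript_id: r.bin for r in bin_expression(tpm)}
        assert got == ds.manifest.bins
        peaks = read_peaks_bed(out / "peaks.bed")
        calls = classify_gene_targets(genes_of(transcripts), peaks)
        assert {c.gene_id: c.target_class for c in calls} == ds.manifest.target_classes
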