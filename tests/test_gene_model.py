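"""Exon-intron assembly: chaining, splice validation, gap filling, splicing."""

import numpy as np
import pytest

import xistkit as xk
from xistkit.gene_model import SpliceChainError
from xistkit._util import revcomp


def _gene_region(bundle):
    """Gene span in transcribed orientation plus the truth model in its frame."""
    t = bundle.truth
    g0 = t.tss_locus_index
    region = t.locus_seq[g0: g0 + t.spec.gene_span]
    exons = [(a - g0 + 1, b - g0) for a, b in t.exon_locus]
    introns = [(a - g0 + 1, b - g0) for a, b in t.intron_locus]
    return region, xk.ExonIntronModel(exons, introns, "+")


class TestInferExons:
    def test_unspliced_amplicon_single_exon(self):
        g = "ACGTTGCA" * 30
        model = xk.infer_exons(g, g)
        assert model.exons == [(1, len(g))] and model.introns == []

    def test_recovers_planted_desk_model(self, desk_bundle):
        region, truth_model = _gene_region(desk_bundle)
        model = xk.infer_exons(region, desk_bundle.transcript_seq)
        assert model.exons == truth_model.exons
        assert model.introns == truth_model.introns

    @pytest.mark.parametrize("seed", range(12))
    def test_three_exon_recovery(self, seed, mini_spec_factory):
        spec = mini_spec_factory(exon_lengths=(200, 90, 150),
                                 intron_lengths=(45, 60))
        b = xk.build_scaffold(spec, seed=seed)
        region, truth_model = _gene_region(b)
        model = xk.infer_exons(region, b.transcript_seq)
        # alignment-free oracle: splicing the reported exons yields the amplicon
        spliced = "".join(region[a - 1: b_] for a, b_ in model.exons)
        assert spliced == b.transcript_seq
        assert model.exons == truth_model.exons

    def test_unexplainable_amplicon_reports_partial(self, desk_bundle):
        region, _ = _gene_region(desk_bundle)
        amp = desk_bundle.transcript_seq
        broken = amp[:500] + "ACGT" * 200     # tail not from the region
        with pytest.raises(SpliceChainError) as e:
            xk.infer_exons(region, broken)
        assert e.value.matched >= 500


class TestSpliceSites:
    def test_planted_introns_canonical(self, desk_bundle):
        region, model = _gene_region(desk_bundle)
        report = xk.validate_splice_sites(model, region)
        assert len(report) == 6
        assert all(r == ("GT", "AG", True) for r in report)

    def test_noncanonical_donor_flagged(self):
        #          exon1     intron (GC..AG)     exon2
        g = "AAATTTCCC" + "GC" + "T" * 20 + "AG" + "GGGTTTAAA"
        model = xk.ExonIntronModel([(1, 9), (34, 42)], [(10, 33)], "+")
        (don, acc, canon), = xk.validate_splice_sites(model, g)
        assert (don, acc, canon) == ("GC", "AG", False)

    def test_minus_strand_reads_reverse_complement(self, desk_bundle):
        t = desk_bundle.truth
        model = xk.ExonIntronModel(t.exon_scaffold_intervals,
                                   t.intron_scaffold_intervals, "-")
        report = xk.validate_splice_sites(model, t.filled_scaffold)
        assert all(r == ("GT", "AG", True) for r in report)
        # hand-computed check on the 5'-most intron: the donor read on the
        # transcribed strand is the reverse complement of the forward top strand
        a, b = model.introns_5p_to_3p()[0]
        assert report[0][0] == revcomp(t.filled_scaffold[b - 2: b])


class TestFillGap:
    def _bridge(self, bundle, pad=160):
        ga, gb = bundle.truth.gap_locus
        pair = xk.design_primer_pair(bundle, "gdna", ga - pad + 1, gb + pad)
        return xk.simulate_amplicons(bundle, [pair], "gdna")[0]

    def test_desk_gap_delta(self, desk_bundle):
        res = xk.fill_gap(desk_bundle.scaffold_seq, self._bridge(desk_bundle))
        assert res.delta == 526
        assert len(res.fill_sequence) == 626

    def test_reconstruction_matches_truth(self, desk_bundle):
        res = xk.fill_gap(desk_bundle.scaffold_seq, self._bridge(desk_bundle))
        assert res.apply(desk_bundle.scaffold_seq) == \
            desk_bundle.truth.filled_scaffold

    @pytest.mark.parametrize("seed", range(8))
    def test_random_fills_roundtrip(self, seed, mini_spec_factory):
        spec = mini_spec_factory(
            exon_lengths=(700,), intron_lengths=(),
            gap=xk.GapSpec(gene_start=200, fill_len=230, placeholder_len=60))
        b = xk.build_scaffold(spec, seed=seed)
        res = xk.fill_gap(b.scaffold_seq, self._bridge(b, pad=80))
        assert res.apply(b.scaffold_seq) == b.truth.filled_scaffold

    def test_zero_delta(self, mini_spec_factory):
        spec = mini_spec_factory(
            exon_lengths=(700,), intron_lengths=(),
            gap=xk.GapSpec(gene_start=200, fill_len=80, placeholder_len=80))
        b = xk.build_scaffold(spec, seed=3)
        res = xk.fill_gap(b.scaffold_seq, self._bridge(b, pad=80))
        assert res.delta == 0

    def test_missing_flanks_error(self, desk_bundle):
        with pytest.raises(ValueError, match="flank"):
            xk.fill_gap(desk_bundle.scaffold_seq, "ACGT" * 50)


class TestTranscript:
    def test_porcine_scale_length(self, porcine_bundle):
        region, model = _gene_region(porcine_bundle)
        tr = xk.build_transcript(model, region)
        assert tr.length == 25215
        assert tr.sequence == porcine_bundle.transcript_seq

    def test_single_exon(self):
        g = "ACGT" * 50
        model = xk.ExonIntronModel([(1, 200)], [], "+")
        assert xk.build_transcript(model, g).sequence == g

    def test_coordinate_map_roundtrip(self, desk_bundle):
        t = desk_bundle.truth
        model = xk.ExonIntronModel(t.exon_scaffold_intervals,
                                   t.intron_scaffold_intervals, "-")
        tr = xk.build_transcript(model, t.filled_scaffold)
        assert tr.sequence == desk_bundle.transcript_seq
        for pos in range(1, tr.length + 1):
            assert tr.map_to_transcript(tr.map_to_scaffold(pos)) == pos

    def test_residual_n_rejected(self, mini_spec_factory):
        # exonic gap: splicing the released (unfilled) scaffold must fail
        spec = mini_spec_factory(
            exon_lengths=(700,), intron_lengths=(),
            gap=xk.GapSpec(gene_start=200, fill_len=230, placeholder_len=60))
        b = xk.build_scaffold(spec, seed=0)
        t = b.truth
        a, bb = t.exon_locus[0]
        shrink = 230 - 60                      # fill replaced by placeholder
        L = len(b.scaffold_seq)
        model = xk.ExonIntronModel([(L - (bb - shrink) + 1, L - a)], [], "-")
        with pytest.raises(ValueError, match="N"):
            xk.build_transcript(model, b.scaffold_seq)


class TestSummary:
    def test_porcine_scale_lengths_column(self, porcine_bundle):
        region, model = _gene_region(porcine_bundle)
        table = xk.summarize_model(model, region)
        lengths = table["length"].tolist()
        assert lengths[:13] == [17184, 1460, 89, 2271, 136, 2136, 209, 356,
                                329, 390, 129, 989, 7139]
        assert lengths[13:] == [25215, 32817]

    def test_single_exon_rows(self):
        model = xk.ExonIntronModel([(1, 120)], [], "+")
        table = xk.summarize_model(model, "ACGT" * 30)
        assert table["feature"].tolist() == ["Exon 1", "Transcript total",
                                             "Gene span total"]

    def test_exon_rows_splice_to_transcript(self, desk_bundle):
        region, model = _gene_region(desk_bundle)
        table = xk.summarize_model(model, region)
        exon_rows = table[table.feature.str.startswith("Exon")]
        assert exon_rows["length"].sum() == len(desk_bundle.transcript_seq)
        assert table[table.feature.str.startswith(("Exon", "Intron"))][
            "length"].sum() == model.gene_span
        # first/last 8 nt of exon 1 match the transcript itself
        assert desk_bundle.transcript_seq.startswith(exon_rows.iloc[0].first_8nt)
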