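"""Generator invariants: planted geometry, determinism, and simulated readouts."""

import numpy as np
import pytest

import xistkit as xk
from xistkit.synthetic_data import ConflictError, RepeatSpec


class TestBuildScaffold:
    def test_porcine_scale_geometry(self, porcine_bundle):
        t = porcine_bundle.truth
        assert len(porcine_bundle.transcript_seq) == 25215
        assert t.spec.gene_span == 32817
        assert sum(t.spec.exon_lengths) == len(t.transcript_seq)

    def test_single_exon_degenerate(self):
        spec = xk.GeneSpec(exon_lengths=(500,), intron_lengths=(),
                           flank_lengths=(260, 120), cpg_window=200,
                           promoter_cpg_offsets=(), motif_plants=(), gap=None)
        b = xk.build_scaffold(spec, seed=0)
        assert spec.gene_span == 500
        assert len(b.transcript_seq) == 500
        t = b.truth
        span = t.exon_locus[0]
        assert b.transcript_seq == t.locus_seq[span[0]: span[1]]

    def test_deterministic_given_spec_and_seed(self):
        a = xk.build_scaffold(xk.desk_spec(), seed=11)
        b = xk.build_scaffold(xk.desk_spec(), seed=11)
        c = xk.build_scaffold(xk.desk_spec(), seed=12)
        assert a.scaffold_seq == b.scaffold_seq
        assert a.transcript_seq == b.transcript_seq
        assert c.scaffold_seq != a.scaffold_seq

    def test_conservation_of_lengths(self, desk_bundle):
        t = desk_bundle.truth
        assert len(t.transcript_seq) == sum(t.spec.exon_lengths)
        gene = sum(b - a for a, b in t.exon_locus + t.intron_locus)
        assert gene == t.spec.gene_span

    def test_planted_introns_are_canonical(self, desk_bundle):
        t = desk_bundle.truth
        for a, b in t.intron_locus:
            assert t.locus_seq[a: a + 2] == "GT"
            assert t.locus_seq[b - 2: b] == "AG"

    def test_cpg_window_is_exact(self, desk_bundle, desk_window):
        win, tss = desk_window
        found = [i for i in range(len(win) - 1) if win[i: i + 2] == "CG"]
        assert len(found) == 78
        sites = xk.scan_cpg(win, tss).sites
        assert tuple(sites) == tuple(desk_bundle.truth.cpg_offsets)

    def test_minus_strand_scaffold_mapping(self, desk_bundle):
        t = desk_bundle.truth
        # transcript position 1 is the TSS base; t = tss - s + 1 within exon 1
        for tr in (1, 2, 100, 500):
            s = xk.coords.locus_to_scaffold(int(t.t_to_g[tr - 1]),
                                            t.locus_len, "-")
            assert tr == t.tss_scaffold_pos - s + 1

    def test_overlapping_features_rejected(self):
        from dataclasses import replace
        spec = xk.desk_spec()
        bad = spec.repeat_specs + (RepeatSpec(24, 4.0, 330),)
        with pytest.raises(ConflictError):
            replace(spec, repeat_specs=bad).validate()


class TestRaceClones:
    def test_eight_offset_classes(self, desk_bundle):
        clones = xk.simulate_race_clones(desk_bundle, "five", seed=0)
        starts = {seq[:40] for _, seq in clones}
        assert len(starts) == 8

    def test_zero_clones(self, desk_bundle):
        assert xk.simulate_race_clones(desk_bundle, "five",
                                       clones_per_offset=0) == []

    def test_five_prime_starts_map_to_tss(self, desk_bundle):
        t = desk_bundle.truth
        clones = xk.simulate_race_clones(desk_bundle, "five", offsets=[1],
                                         clones_per_offset=5, seed=0)
        assert len(clones) == 5
        for _, seq in clones:
            # brute-force exact search on the transcribed-strand locus
            g = t.locus_seq.find(seq[:60])
            assert g == t.tss_locus_index
            assert t.locus_seq.find(seq[:60], g + 1) == -1

    def test_three_prime_polya(self, desk_bundle):
        clones = xk.simulate_race_clones(desk_bundle, "three", seed=0)
        for _, seq in clones:
            assert seq.endswith("A" * 8)

    def test_bad_offset_rejected(self, desk_bundle):
        with pytest.raises(ValueError, match="offset"):
            xk.simulate_race_clones(desk_bundle, "five", offsets=[10 ** 6])


class TestBisulfiteSim:
    def test_full_conversion_all_methylated(self, desk_bundle):
        spec = desk_bundle.truth.spec
        bundle = desk_bundle
        bundle.truth.spec.methyl_profile["test_all"] = 1.0
        try:
            sim = xk.simulate_bisulfite_clones(bundle, "test_all", 2,
                                               conversion_rate=1.0, seed=0)
            win, tss = bundle.truth.promoter_window_seq()
            for cid, seq in sim.clones:
                lo, hi = sim.clone_regions[cid]
                a = xk.coords.promoter_to_index(lo, tss - 1)
                ref = win[a: a + len(seq)]
                # every C in the region is a planted CpG C here or a non-CpG C;
                # only non-CpG Cs convert
                for rc, cc in zip(ref, seq):
                    if rc != "C":
                        assert cc == rc
                # every CpG C is protected under the all-methylated profile
                for off, state in sim.states[cid].items():
                    assert state is True
                    i = xk.coords.promoter_to_index(off, tss - 1) - a
                    assert seq[i] == "C"
        finally:
            del spec.methyl_profile["test_all"]

    def test_female_pooled_fraction(self, desk_bundle):
        sim = xk.simulate_bisulfite_clones(desk_bundle, "female", 200, seed=5)
        states = [v for d in sim.states.values() for v in d.values()]
        n = len(states)
        frac = sum(states) / n
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_male_mean_sites(self, desk_bundle):
        # p=0.96 over 67 analysed sites -> about 64.3 methylated per clone-set
        sim = xk.simulate_bisulfite_clones(desk_bundle, "male", 30, seed=6)
        per_cloneset = 0.96 * 67
        total = sum(sum(d.values()) for d in sim.states.values()) / 30
        assert abs(total - per_cloneset) < 3 * np.sqrt(67 * 0.96 * 0.04 / 30)

    def test_unknown_sex(self, desk_bundle):
        with pytest.raises(ValueError, match="profile"):
            xk.simulate_bisulfite_clones(desk_bundle, "unknown", 1)


class TestRnaSeq:
    def test_reads_are_transcript_substrings(self, desk_bundle):
        from xistkit._util import revcomp
        tx = desk_bundle.transcript_seq
        pairs = xk.simulate_rnaseq(desk_bundle, "female", 50, seed=0)
        for p in pairs:
            assert len(p.seq1) == len(p.seq2) == 90
            assert p.seq1 in tx
            assert revcomp(p.seq2) in tx

    def test_empty_cases(self, desk_bundle):
        assert xk.simulate_rnaseq(desk_bundle, "female", 0) == []
        assert xk.simulate_rnaseq(desk_bundle, "male", 100, seed=1) == []

    def test_insert_too_long(self, desk_bundle):
        L = len(desk_bundle.transcript_seq)
        with pytest.raises(ValueError, match="insert"):
            xk.simulate_rnaseq(desk_bundle, "female", 1, insert=L + 1)


class TestAmplicons:
    def test_intron_spanning_pair_shorter_on_cdna(self, desk_bundle):
        t = desk_bundle.truth
        # primers in exon 1 and exon 7 span all six introns
        # both primers sit inside single exons (exon 1 ends at +3000)
        pair = xk.design_primer_pair(desk_bundle, "cdna", 2900, 4500)
        cdna, = xk.simulate_amplicons(desk_bundle, [pair], "cdna")
        gdna, = xk.simulate_amplicons(desk_bundle, [pair], "gdna")
        assert len(gdna) - len(cdna) == sum(t.spec.intron_lengths)

    def test_single_exon_pair_identical(self, desk_bundle):
        pair = xk.design_primer_pair(desk_bundle, "cdna", 100, 600)
        cdna, = xk.simulate_amplicons(desk_bundle, [pair], "cdna")
        gdna, = xk.simulate_amplicons(desk_bundle, [pair], "gdna")
        assert cdna == gdna

    def test_gap_spanning_amplicon_length(self, desk_bundle):
        t = desk_bundle.truth
        ga, gb = t.gap_locus
        pair = xk.design_primer_pair(desk_bundle, "gdna", ga - 150 + 1, gb + 150)
        amp, = xk.simulate_amplicons(desk_bundle, [pair], "gdna")
        expected_from_released = 150 + t.placeholder_len + 150
        assert len(amp) == expected_from_released + (len(t.fill_seq)
                                                    - t.placeholder_len)

    def test_primer_not_found(self, desk_bundle):
        with pytest.raises(ValueError, match="primer"):
            xk.simulate_amplicons(desk_bundle, [("A" * 20, "C" * 20)], "cdna")
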