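"""Map simulated RNA-seq reads and verify sex-specific expression boundaries.

Female libraries yield reads only from the spliced transcript, so on the gene
locus the coverage is confined to exons, starts in the TSS window, ends at the
called terminus, and is zero upstream/downstream; male libraries yield none.
"""

import xistkit as xk

bundle = xk.build_scaffold(xk.desk_spec(), seed=1)
t = bundle.truth
locus = t.locus_seq

pairs = xk.simulate_rnaseq(bundle, "female", n_pairs=400, read_len=90,
                           insert=200, seed=5)
reads = ([(p.name + "/1", p.seq1) for p in pairs]
         + [(p.name + "/2", p.seq2) for p in pairs])
alignments = xk.map_reads(reads, locus, max_mismatch=0)
print(f"female: {len(alignments.placements)} of {len(reads)} reads aligned "
      f"to the locus (junction-spanning reads stay unaligned)")

track = xk.coverage_track(alignments, len(locus), 90)
exons = [(a + 1, b) for a, b in t.exon_locus]
report = xk.expression_check(
    track, exons,
    tss_window=(t.tss_locus_index + 1 - 10, t.tss_locus_index + 1 + 250),
    terminus=int(t.t_to_g[-1]) + 1)
print(f"exonic fraction of aligned bases: {report.exonic_fraction:.3f}")
print(f"coverage starts in TSS window: {report.starts_in_tss_window}; "
      f"upstream depth zero: {report.upstream_zero}; "
      f"downstream depth zero: {report.downstream_zero}")
print(f"repeat-ambiguity peaks (depth > 5x exonic median): "
      f"{len(report.ambiguity_peaks)} positions")

male = xk.simulate_rnaseq(bundle, "male", n_pairs=400, seed=5)
print(f"\nmale: {len(male)} transcript-derived read pairs "
      f"(the gene is silent on the single active X)")
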