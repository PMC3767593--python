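"""Build a synthetic XIST-like locus and inspect its planted ground truth.

The generator plants a minus-strand, 7-exon lncRNA gene on a scaffold-scale
sequence: GT..AG introns, four tandem-repeat arrays, a CpG-dense promoter, an
N-gap with a known 626-bp fill, and a poly-A signal 21 bp upstream of the
terminus.  Everything downstream of this script treats the scaffold as data
and the truth table as the answer key.
"""

import xistkit as xk

bundle = xk.build_scaffold(xk.desk_spec(), seed=1)
t = bundle.truth

print(f"released scaffold : {len(bundle.scaffold_seq):6d} bp "
      f"({bundle.scaffold_seq.count('N')} N placeholder)")
print(f"spliced transcript: {len(bundle.transcript_seq):6d} bp "
      f"({len(t.spec.exon_lengths)} exons)")
print(f"gene span         : {t.spec.gene_span:6d} bp")
print(f"TSS at scaffold position {t.tss_scaffold_pos} (minus strand: "
      f"transcription runs toward lower coordinates)")
print(f"terminus at scaffold position {t.terminus_scaffold_pos}")
print("\nplanted repeat arrays (transcript coordinates):")
for r in t.repeats:
    print(f"  +{r.transcript_start:5d}..+{r.transcript_end:5d}  "
          f"{r.copies:5.1f} copies of a {r.period}-mer")
print(f"\npromoter CpG sites in +/-2 kb: {len(t.cpg_offsets)}")

# the porcine-scale preset reproduces the reported locus geometry exactly
full = xk.build_scaffold(xk.porcine_scale_spec(), seed=1)
print(f"\nporcine-scale preset: transcript {len(full.transcript_seq)} bp, "
      f"gene span {full.truth.spec.gene_span} bp")
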