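"""Call transcript ends from RACE-style clones and scan the promoter.

5' clone starts become TSS calls in promoter coordinates (+1 = reference TSS,
no position 0).  3' clones are poly-A trimmed and the modal end is the
terminus; the offset from the homology-expected site is counted inclusively,
the convention under which a 9-base shift prints as "10 bp downstream".
"""

import xistkit as xk

bundle = xk.build_scaffold(xk.desk_spec(), seed=1)
t = bundle.truth
scaffold = t.filled_scaffold         # end calling runs on the gap-filled assembly

clones5 = xk.simulate_race_clones(bundle, "five", seed=1)
tss = xk.call_tss(clones5, scaffold, t.tss_scaffold_pos)
print(f"{len(tss.calls)} TSS calls at promoter offsets: {tss.offsets}")

clones3 = xk.simulate_race_clones(bundle, "three", seed=1)
term = xk.call_terminus(clones3, scaffold, t.expected_terminus_scaffold_pos)
print(f"terminus at scaffold {term.scaffold_position}: "
      f"{term.offset_from_expected} positions (inclusive) from the expected "
      f"site, i.e. a {term.downstream_shift}-bp shift")

polya = xk.find_polya_signal(bundle.transcript_seq, t.terminus_transcript)
print(f"poly-A signal {polya[0]} ends {polya[1]} bp upstream of the terminus")

win, tss_pos = t.promoter_window_seq()
for pat in ("TTAAAG", "CCGCCATNTT"):
    hits = [h for h in xk.scan_motifs(win, tss_pos, [pat]) if h.strand == "+"]
    for h in hits:
        print(f"motif {pat}: {h.matched_sequence} at {h.interval[0]}..{h.interval[1]}")

# restriction check of the gap fill: the planted DraI site cuts TTT/AAA
frag = xk.digest(t.fill_seq, ("DraI", "TTTAAA", 3))
print(f"DraI digest of the {len(t.fill_seq)}-bp gap fill -> fragments "
      f"{frag.fragment_lengths}")
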