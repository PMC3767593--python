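"""Promoter CpG enumeration and sex-stratified bisulfite methylation calling.

The +/-2 kb promoter window holds 78 CpGs, 67 of them in two dense regions
(-284..+53 and +285..+1,727).  Male clones are ~96% methylated, female clones
~50% — the differentially methylated region that silences the gene on the
male (single, active) X while the female inactive X keeps it expressed.
"""

import xistkit as xk

bundle = xk.build_scaffold(xk.desk_spec(), seed=1)
win, tss = bundle.truth.promoter_window_seq()

cpg = xk.scan_cpg(win, tss)
print(f"CpG sites in +/-2 kb: {len(cpg.sites)}")
dense = xk.dense_regions(cpg)
for d in dense:
    print(f"  dense region {d.interval[0]:+5d}..{d.interval[1]:+5d}: "
          f"{d.site_count} sites")
print(f"  analysed (dense) sites: {sum(d.site_count for d in dense)}")

for sex in ("male", "female"):
    sim = xk.simulate_bisulfite_clones(bundle, sex, n_clones=10,
                                       conversion_rate=0.99, seed=2)
    mat = xk.call_methylation(sim.clones, win, cpg)
    summary = xk.summarize_methylation(mat, dense)
    print(f"\n{sex}: {summary.aggregate_percent}% methylated "
          f"({summary.n_methylated}/{summary.n_methylated + summary.n_unmethylated}"
          f" calls; {len(mat.excluded_clones)} clones failed conversion QC)")

# lollipop grid for a small female clone set
sim = xk.simulate_bisulfite_clones(bundle, "female", 3, seed=3,
                                   regions=[(-300, 60)])
mat = xk.call_methylation(sim.clones, win, cpg)
print("\nlollipop grid (* methylated, o unmethylated, . not covered):")
print(xk.lollipop_report(mat, dense))
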