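"""Detect tandem-repeat regions, build consensus monomers, and fold them.

Copy numbers are fractional (span / period, half-up to one decimal): the
porcine-scale preset's third region is 91.7 copies of a 96-mer.  An A-repeat
style monomer folds into two stem-loops under base-pair maximisation.
"""

import xistkit as xk

bundle = xk.build_scaffold(xk.porcine_scale_spec(), seed=1)

regions = xk.find_tandem_repeats(bundle.transcript_seq)
print("detected tandem-repeat regions (transcript coordinates):")
for r in regions:
    print(f"  +{r.interval[0]:5d}..+{r.interval[1]:5d}  period {r.period:3d}  "
          f"{r.copy_number:5.1f} copies  mean identity {r.mean_identity:.2f}")

# consensus of the largest array vs its planted monomer
big = max(regions, key=lambda r: r.span)
planted = {t.period: t.monomer for t in bundle.truth.repeats}[big.period]
ham = sum(a != b for a, b in zip(big.consensus, planted))
print(f"\nconsensus of the {big.period}-mer array differs from the planted "
      f"monomer at {ham} positions")

# query-monomer search: a foreign probe (like the mouse C-repeat) is absent
import numpy as np
from xistkit._util import random_dna
probe = random_dna(np.random.default_rng(0), 120)
ident, pos, present = xk.search_monomer(bundle.transcript_seq, probe)
print(f"foreign 120-mer probe: best identity {ident:.2f} -> "
      f"{'present' if present else 'absent'} (threshold 0.7)")

# fold an A-repeat style two-arm monomer
fold = xk.fold_monomer("GGCGAAACGCCAGGGCAAAGCCCA")
print(f"\ndesigned 24-mer fold: {fold.structure}")
print(f"{fold.pairs} base pairs, {fold.stem_loops} stem-loops")
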