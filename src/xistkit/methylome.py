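"""Promoter CpG enumeration and bisulfite methylation calling.

CpG sites are enumerated in a +/-2 kb window around the TSS (promoter
coordinates, +1 = TSS, no position 0), chained into dense regions, and scored
from bisulfite-converted clone sequences: at each site a retained C is a
methylated call, a T an unmethylated call.  Per-clone conversion QC uses
non-CpG cytosines, which have no biological methylation in this model and so
measure conversion efficiency directly.  Summaries follow the field's
reporting style: pooled percentages rounded half-up to two decimals and mean
methylated sites per clone to one decimal (33.4 of 67 sites pools to 49.85%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import check_dna, round_half_up, seq_to_array
from .coords import index_to_promoter, promoter_to_index

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1


@dataclass
class CpGSiteMap:
    sites: List[int]                    # promoter coordinate of each CpG's C
    window: Tuple[int, int]             # (-W, +W)
    tss_index: int                      # 0-based index of the TSS in the reference

    def site_indices(self) -> List[int]:
        return [promoter_to_index(s, self.tss_index) for s in self.sites]


@dataclass
class DenseRegion:
    interval: Tuple[int, int]           # promoter coordinates, endpoints at sites
    site_count: int


@dataclass
class BisulfiteCallMatrix:
    clone_ids: List[str]
    sites: List[int]                    # promoter coordinates
    calls: np.ndarray                   # clones x sites, {1, 0, -1}
    conversion_qc: List[float]          # per-clone non-CpG C conversion fraction
    excluded_clones: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.clone_ids, columns=self.sites)


@dataclass
class MethylationSummary:
    per_site_percent: List[float]
    per_region_percent: List[float]
    aggregate_percent: float            # 2 decimals, half-up
    mean_methylated_sites_per_clone: float   # 1 decimal, half-up
    n_methylated: int
    n_unmethylated: int


# ---------------------------------------------------------------------------


def scan_cpg(reference: str, tss: int, window: int = 2000) -> CpGSiteMap:
    """All CG dinucleotide positions (promoter coordinate of the C) within
    +/-``window`` of the TSS.

    ``reference`` is the promoter region in transcribed orientation; ``tss``
    is the 1-based position of the TSS base within it.
    """
    seq = check_dna(reference, "reference")
    tss_index = tss - 1
    lo = tss_index - window
    hi = tss_index + window
    if lo < 0 or hi > len(seq):
        raise ValueError("reference does not cover the requested window")
    sites = [index_to_promoter(i, tss_index)
             for i in range(lo, hi)
             if seq[i: i + 2] == "CG"]
    return CpGSiteMap(sites, (-window, window), tss_index)


def dense_regions(cpg_map: CpGSiteMap, max_gap: int = 200,
                  min_sites: int = 6) -> List[DenseRegion]:
    """Single-linkage chains of CpG sites with inter-site distance <= max_gap;
    chains with at least ``min_sites`` sites are dense regions whose interval
    endpoints are the outermost sites."""
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    idx = sorted(promoter_to_index(s, cpg_map.tss_index) for s in cpg_map.sites)
    if not idx:
        return []
    chains: List[List[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i - chains[-1][-1] <= max_gap:
            chains[-1].append(i)
        else:
            chains.append([i])
    out = []
    for ch in chains:
        if len(ch) >= min_sites:
            out.append(DenseRegion(
                (index_to_promoter(ch[0], cpg_map.tss_index),
                 index_to_promoter(ch[-1], cpg_map.tss_index)),
                len(ch)))
    return out


def bisulfite_convert(reference: str, methyl_states: Dict[int, bool]
                      ) -> str:
    """Deterministic full-efficiency bisulfite conversion of the top strand:
    every C converts to T unless it is the C of a CpG whose state is
    methylated.  ``methyl_states`` maps the 0-based position of each CpG C to
    its state and must cover every CpG in the reference."""
    seq = check_dna(reference, "reference")
    for i in range(len(seq) - 1):
        if seq[i: i + 2] == "CG" and i not in methyl_states:
            raise ValueError(f"no methylation state for CpG at index {i}")
    out = []
    for i, ch in enumerate(seq):
        if ch == "C" and not methyl_states.get(i, False):
            ch = "T"
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# calling


def _place_clone(clone: str, reference: str,
                 ref_collapsed: Optional[str] = None) -> Optional[int]:
    """Ungapped placement of a bisulfite clone on the unconverted reference:
    the unique offset where every clone base equals the reference base or is
    the T of a converted reference C.

    Collapsing C->T on both strings removes exactly the conversion degrees of
    freedom, so valid placements are the exact matches of the collapsed clone
    in the collapsed reference, minus offsets where the clone shows a C over a
    reference non-C.
    """
    if ref_collapsed is None:
        ref_collapsed = reference.replace("C", "T")
    collapsed = clone.replace("C", "T")
    c = seq_to_array(clone)
    r = seq_to_array(reference)
    placed = None
    i = ref_collapsed.find(collapsed)
    while i >= 0:
        window = r[i: i + len(c)]
        ok = (window == c) | ((c == ord("T")) & (window == ord("C")))
        if ok.all():
            if placed is not None:
                return None
            placed = i
        i = ref_collapsed.find(collapsed, i + 1)
    return placed


def call_methylation(clones: Sequence[Tuple[str, str]], reference: str,
                     cpg_map: CpGSiteMap, min_conversion: float = 0.95
                     ) -> BisulfiteCallMatrix:
    """Per-clone, per-site methylation states from bisulfite clones.

    At each covered site: C -> methylated, T -> unmethylated, anything else or
    uncovered -> missing.  Clones whose non-CpG C conversion fraction is below
    ``min_conversion`` (incomplete conversion) are excluded, as are clones
    that place nowhere or ambiguously on the reference.
    """
    reference = check_dna(reference, "reference")
    site_idx = cpg_map.site_indices()
    site_set = set(site_idx)
    noncpg_c = [i for i, ch in enumerate(reference)
                if ch == "C" and i not in site_set]
    noncpg_set = set(noncpg_c)

    rows, ids, qcs, excluded = [], [], [], []
    ref_collapsed = reference.replace("C", "T")
    for cid, seq in clones:
        seq = check_dna(seq, f"clone {cid}")
        off = _place_clone(seq, reference, ref_collapsed)
        if off is None:
            excluded.append(cid)
            continue
        covered = range(off, off + len(seq))
        n_c = sum(1 for i in covered if i in noncpg_set)
        conv = sum(1 for i in covered
                   if i in noncpg_set and seq[i - off] == "T")
        qc = conv / n_c if n_c else 1.0
        if qc < min_conversion:
            excluded.append(cid)
            continue
        row = []
        for i in site_idx:
            if off <= i < off + len(seq):
                base = seq[i - off]
                row.append(METHYLATED if base == "C"
                           else UNMETHYLATED if base == "T" else MISSING)
            else:
                row.append(MISSING)
        rows.append(row)
        ids.append(cid)
        qcs.append(qc)
    if not rows:
        raise ValueError("no clone could be placed on the reference")
    return BisulfiteCallMatrix(ids, list(cpg_map.sites),
                               np.array(rows, dtype=np.int8), qcs, excluded)


def summarize_methylation(matrix: BisulfiteCallMatrix,
                          regions: Optional[Sequence[DenseRegion]] = None
                          ) -> MethylationSummary:
    """Pooled and per-site methylation percentages.

    aggregate = 100 x methylated / (methylated + unmethylated), half-up to two
    decimals; mean methylated sites per clone is the clone-mean of methylated
    call counts, half-up to one decimal.
    """
    calls = matrix.calls
    if calls.size == 0 or (calls == MISSING).all():
        raise ValueError("matrix contains no informative calls")
    meth = int((calls == METHYLATED).sum())
    unmeth = int((calls == UNMETHYLATED).sum())
    per_site = []
    for j in range(calls.shape[1]):
        col = calls[:, j]
        m, u = int((col == METHYLATED).sum()), int((col == UNMETHYLATED).sum())
        per_site.append(round_half_up(100 * m / (m + u), 2) if m + u else float("nan"))
    per_region = []
    if regions:
        for reg in regions:
            js = [j for j, s in enumerate(matrix.sites)
                  if reg.interval[0] <= s <= reg.interval[1]]
            sub = calls[:, js]
            m = int((sub == METHYLATED).sum())
            u = int((sub == UNMETHYLATED).sum())
            per_region.append(round_half_up(100 * m / (m + u), 2)
                              if m + u else float("nan"))
    mean_sites = float(np.mean((calls == METHYLATED).sum(axis=1)))
    return MethylationSummary(
        per_site_percent=per_site,
        per_region_percent=per_region,
        aggregate_percent=round_half_up(100 * meth / (meth + unmeth), 2),
        mean_methylated_sites_per_clone=round_half_up(mean_sites, 1),
        n_methylated=meth,
        n_unmethylated=unmeth,
    )


def lollipop_report(matrix: BisulfiteCallMatrix,
                    regions: Optional[Sequence[DenseRegion]] = None,
                    glyphs: str = "*o.") -> str:
    """Text lollipop grid: one row per clone, one column per site; filled (*),
    empty (o) and missing (.) glyphs, with '|' separators at dense-region
    boundaries."""
    filled, empty, missing = glyphs
    seps = set()
    if regions:
        starts = {r.interval[0] for r in regions}
        for j, s in enumerate(matrix.sites):
            if s in starts and j > 0:
                seps.add(j)
    lines = []
    width = max((len(c) for c in matrix.clone_ids), default=0)
    for cid, row in zip(matrix.clone_ids, matrix.calls):
        cells = []
        for j, v in enumerate(row):
            if j in seps:
                cells.append("|")
            cells.append(filled if v == METHYLATED
                         else empty if v == UNMETHYLATED else missing)
        lines.append(f"{cid:>{width}} " + "".join(cells))
    return "\n".join(lines)
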