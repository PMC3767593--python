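"""Transcript-end calling, promoter motif scanning, and restriction digests.

5' RACE clone starts are mapped to the scaffold and reported as promoter-
coordinate TSS calls (+1 = reference TSS, no position 0); 3' RACE clones are
poly-A trimmed (resolving A-run junctions in favour of the longest genomic
match) and the modal end is the terminus, with the offset from the expected
site counted inclusively — the convention under which a terminus nine bases
past the expected one is "10 bp downstream".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from ._util import check_dna, iupac_regex, revcomp
from .coords import inclusive_offset, index_to_promoter


@dataclass
class TssCallSet:
    calls: List[Tuple[int, int]]        # (promoter offset, clone support count)
    reference_tss: int                  # scaffold position set as +1
    excluded: int = 0                   # unmappable clones

    @property
    def offsets(self) -> List[int]:
        return [o for o, _ in self.calls]


@dataclass
class TerminusCall:
    scaffold_position: int
    offset_from_expected: int           # inclusive position count (primary)
    downstream_shift: int               # plain difference in bp
    support: int = 0
    polya_signal: Optional[Tuple[str, int]] = None


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    interval: Tuple[int, int]           # promoter coordinates, no 0
    strand: str
    matched_sequence: str


@dataclass
class DigestResult:
    enzyme: str
    recognition_site: str
    cut_positions: List[int]            # 1-based: fragment boundary after this base
    fragment_lengths: List[int]


# ---------------------------------------------------------------------------
# TSS / terminus calling


def _map_unique(scaffold: str, probe: str) -> Optional[Tuple[int, str]]:
    """Unique placement of a probe on either scaffold strand.

    Returns (0-based forward-strand start of the probe's 5' end match, strand).
    """
    fwd = [i for i in _find_all(scaffold, probe)]
    rc = revcomp(probe)
    rev = [i for i in _find_all(scaffold, rc)]
    if len(fwd) + len(rev) != 1:
        return None
    if fwd:
        return fwd[0], "+"
    return rev[0], "-"


def _find_all(hay: str, needle: str) -> Iterable[int]:
    i = hay.find(needle)
    while i >= 0:
        yield i
        i = hay.find(needle, i + 1)


def call_tss(clones: Sequence[Tuple[str, str]], scaffold: str,
             reference_tss: int, min_support: int = 1,
             probe_len: int = 30) -> TssCallSet:
    """Distinct clone 5'-end scaffold positions with enough support become TSS
    calls, reported as promoter offsets relative to ``reference_tss``."""
    scaffold = check_dna(scaffold, "scaffold")
    counter: Counter = Counter()
    excluded = 0
    for _, seq in clones:
        probe = check_dna(seq, "clone")[:probe_len]
        placed = _map_unique(scaffold, probe)
        if placed is None:
            excluded += 1
            continue
        start, strand = placed
        five_end = start + 1 if strand == "+" else start + len(probe)
        raw = (five_end - reference_tss if strand == "+"
               else reference_tss - five_end)
        counter[raw + 1 if raw >= 0 else raw] += 1
    calls = sorted((o, n) for o, n in counter.items() if n >= min_support)
    return TssCallSet(calls, reference_tss, excluded)


def call_terminus(clones: Sequence[Tuple[str, str]], scaffold: str,
                  expected_terminus: int, min_polya: int = 8,
                  probe_len: int = 40) -> TerminusCall:
    """Trim each 3' clone's poly-A tract, map the genomic end, and call the
    modal end position.

    A-runs at the tract junction are resolved in favour of the longest genomic
    match: trimmed As are re-absorbed while the genomic sequence continues with
    'A'.  ``offset_from_expected`` counts positions inclusively between the
    expected and called termini.
    """
    scaffold = check_dna(scaffold, "scaffold")
    ends: Counter = Counter()
    for _, seq in clones:
        seq = check_dna(seq, "clone")
        stripped = seq.rstrip("A")
        n_a = len(seq) - len(stripped)
        if n_a < min_polya or not stripped:
            continue
        placed = _map_unique(scaffold, stripped[-probe_len:])
        if placed is None:
            continue
        start, strand = placed
        if strand == "+":
            end = start + min(probe_len, len(stripped))   # 1-based inclusive end
            while n_a > 0 and end < len(scaffold) and scaffold[end] == "A":
                end += 1
                n_a -= 1
        else:
            end = start + 1                               # transcribed 3' end
            while n_a > 0 and end > 1 and scaffold[end - 2] == "T":
                end -= 1
                n_a -= 1
        ends[(end, strand)] += 1
    if not ends:
        raise ValueError("no clone carries a poly-A tract of the required length")
    (pos, _strand), support = ends.most_common(1)[0]
    return TerminusCall(
        scaffold_position=pos,
        offset_from_expected=inclusive_offset(expected_terminus, pos),
        downstream_shift=abs(expected_terminus - pos),
        support=support,
    )


def find_polya_signal(transcript_3prime: str, terminus: int, window: int = 50,
                      patterns: Sequence[str] = ("AATAAA",)
                      ) -> Optional[Tuple[str, int]]:
    """Nearest upstream poly-A signal within ``window`` bp of the terminus.

    Returns (hexamer, distance) with distance = terminus - signal end, in
    transcript coordinates; None when absent.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    seq = check_dna(transcript_3prime, "transcript")
    best: Optional[Tuple[str, int]] = None
    for pat in patterns:
        rx = iupac_regex(pat)
        pos = max(0, terminus - window - len(pat))
        while True:                       # overlapping occurrences
            m = rx.search(seq, pos, terminus)
            if m is None:
                break
            pos = m.start() + 1
            dist = terminus - m.end()
            if 0 <= dist <= window and (best is None or dist < best[1]):
                best = (m.group(0), dist)
    return best


# ---------------------------------------------------------------------------
# motif scanning / digest


def scan_motifs(promoter_seq: str, anchor_tss: int,
                patterns: Sequence[str]) -> List[MotifHit]:
    """All IUPAC pattern matches on both strands of a promoter window,
    reported in promoter coordinates (no position 0).

    ``anchor_tss`` is the 1-based position of the TSS base within
    ``promoter_seq``.
    """
    seq = check_dna(promoter_seq, "promoter")
    tss_index = anchor_tss - 1
    hits: List[MotifHit] = []
    for pat in patterns:
        for strand, rx in (("+", iupac_regex(pat)),
                           ("-", iupac_regex(revcomp(pat)))):
            pos = 0
            while True:
                m = rx.search(seq, pos)
                if m is None:
                    break
                pos = m.start() + 1
                hits.append(MotifHit(
                    pattern=pat,
                    interval=(index_to_promoter(m.start(), tss_index),
                              index_to_promoter(m.end() - 1, tss_index)),
                    strand=strand,
                    matched_sequence=m.group(0),
                ))
    return sorted(hits, key=lambda h: (h.interval, h.strand))


def digest(amplicon: str, enzyme: Tuple[str, str, int]) -> DigestResult:
    """Blunt-cut restriction digest: fragments between successive cut sites.

    ``enzyme`` is (name, IUPAC recognition site, cut offset within the site);
    e.g. DraI TTT/AAA is ("DraI", "TTTAAA", 3).
    """
    name, site, cut_offset = enzyme
    seq = check_dna(amplicon, "amplicon")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut offset outside the recognition site")
    rx = iupac_regex(site)
    cuts = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            break
        pos = m.start() + 1
        cut = m.start() + cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(seq)]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return DigestResult(name, site, cuts, frags)
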