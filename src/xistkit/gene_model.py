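"""Exon-intron model assembly from spliced amplicons.

A Sanger-validated spliced amplicon is explained as an ordered chain of exact
substrings of the genomic region; the skipped stretches are introns.  Junction
placement that is ambiguous (identical bases at both intron ends) is resolved
by shifting maximally 5', preferring any shift that yields canonical GT..AG
ends.  The module also validates splice sites, reconstructs scaffold N-gaps
from bridging amplicons, splices the transcript with a bijective coordinate
map, and emits a per-feature summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._util import check_dna, revcomp


@dataclass
class ExonIntronModel:
    """Exon/intron intervals, 1-based inclusive, in ascending coordinate order;
    ``strand`` gives the direction of transcription."""

    exons: List[Tuple[int, int]]
    introns: List[Tuple[int, int]]
    strand: str = "+"

    def __post_init__(self):
        if len(self.exons) != len(self.introns) + 1:
            raise ValueError("need len(exons) == len(introns) + 1")
        for (a, b) in self.exons + self.introns:
            if a > b:
                raise ValueError("empty interval")
        pos = self.exons[0][0]
        for i, (a, b) in enumerate(self.exons):
            if a != pos:
                raise ValueError("exons and introns must tile the span")
            pos = b + 1
            if i < len(self.introns):
                ia, ib = self.introns[i]
                if ia != pos:
                    raise ValueError("exons and introns must alternate")
                pos = ib + 1

    @property
    def gene_span(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1

    @property
    def transcript_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    def transcription_order(self) -> "ExonIntronModel":
        return self

    def exons_5p_to_3p(self) -> List[Tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_5p_to_3p(self) -> List[Tuple[int, int]]:
        return self.introns if self.strand == "+" else list(reversed(self.introns))


@dataclass
class TranscriptRecord:
    sequence: str
    length: int
    exon_boundaries: List[int]          # transcript positions starting exons 2..n
    t_to_s: np.ndarray                  # transcript pos (1-based) -> scaffold pos

    _s_to_t: Optional[Dict[int, int]] = None

    def map_to_scaffold(self, t: int) -> int:
        if not 1 <= t <= self.length:
            raise ValueError(f"transcript position {t} out of range")
        return int(self.t_to_s[t - 1])

    def map_to_transcript(self, s: int) -> int:
        if self._s_to_t is None:
            self._s_to_t = {int(v): i + 1 for i, v in enumerate(self.t_to_s)}
        try:
            return self._s_to_t[s]
        except KeyError:
            raise ValueError(f"scaffold position {s} is not exonic") from None


@dataclass
class GapFillResult:
    gap_interval: Tuple[int, int]       # N-run on the released scaffold, 1-based
    fill_sequence: str
    delta: int                          # len(fill) - placeholder length

    def apply(self, scaffold: str) -> str:
        a, b = self.gap_interval
        return scaffold[: a - 1] + self.fill_sequence + scaffold[b:]


# ---------------------------------------------------------------------------
# exon inference by ordered exact-substring chaining


class SpliceChainError(ValueError):
    def __init__(self, msg: str, matched: int):
        super().__init__(f"{msg} (best partial explanation: first {matched} "
                         f"amplicon bases placed)")
        self.matched = matched


def infer_exons(genomic_region: str, spliced_amplicon: str,
                min_intron: int = 20, donor: str = "GT",
                acceptor: str = "AG") -> ExonIntronModel:
    """Explain a spliced amplicon as ordered exact substrings of the genomic
    region; skipped genomic stretches (each >= ``min_intron``) are introns.

    Coordinates in the returned model are 1-based on ``genomic_region`` with
    strand '+' (pass the region in transcribed orientation).
    """
    if min_intron < 20:
        raise ValueError("min_intron must be >= 20")
    G = check_dna(genomic_region, "genomic_region")
    A = check_dna(spliced_amplicon, "amplicon")
    if not A:
        raise ValueError("empty amplicon")
    anchor_k = min(20, len(A))
    best_partial = 0
    dead: set = set()

    def lce(g: int, a: int) -> int:
        m = 0
        while g + m < len(G) and a + m < len(A) and G[g + m] == A[a + m]:
            m += 1
        return m

    def occurrences(probe: str, start: int) -> List[int]:
        out, i = [], G.find(probe, start)
        while i >= 0:
            out.append(i)
            i = G.find(probe, i + 1)
        return out

    def chain(g: int, a: int) -> Optional[List[Tuple[int, int]]]:
        nonlocal best_partial
        if (g, a) in dead:
            return None
        m = lce(g, a)
        best_partial = max(best_partial, a + m)
        if a + m == len(A):
            return [(g, g + m)]
        probe = A[a + m: a + m + anchor_k]
        for h in occurrences(probe, g + m + min_intron):
            # the junction can slide 5' while both intron ends read the same
            max_d = 0
            while (max_d < m and h - max_d - 1 >= g + m and
                   G[h - max_d - 1] == A[a + m - max_d - 1]):
                max_d += 1
            slide = None
            for d in range(max_d, -1, -1):     # maximal 5' shift first
                if (G[g + m - d: g + m - d + 2] == donor and
                        G[h - d - 2: h - d] == acceptor):
                    slide = d
                    break
            if slide is None:
                slide = max_d
            rest = chain(h - slide, a + m - slide)
            if rest is not None:
                return [(g, g + m - slide)] + rest
        dead.add((g, a))
        return None

    for start in occurrences(A[:anchor_k], 0):
        result = chain(start, 0)
        if result is not None:
            exons = [(a + 1, b) for a, b in result]
            introns = [(exons[i][1] + 1, exons[i + 1][0] - 1)
                       for i in range(len(exons) - 1)]
            model = ExonIntronModel(exons, introns, "+")
            spliced = "".join(G[a - 1: b] for a, b in exons)
            assert spliced == A, "internal error: chained exons do not splice"
            return model
    raise SpliceChainError(
        "amplicon is not an ordered spliced chain of genomic substrings",
        best_partial)


# ---------------------------------------------------------------------------


def validate_splice_sites(model: ExonIntronModel, scaffold: str
                          ) -> List[Tuple[str, str, bool]]:
    """(donor, acceptor, is_canonical) per intron in transcription (5'->3')
    order, read on the transcribed strand; canonical means GT..AG."""
    out = []
    for a, b in model.introns_5p_to_3p():
        if b - a + 1 < 4:
            raise ValueError(f"intron {a}-{b} shorter than 4 nt")
        if model.strand == "+":
            d, ac = scaffold[a - 1: a + 1], scaffold[b - 2: b]
        else:
            d, ac = revcomp(scaffold[b - 2: b]), revcomp(scaffold[a - 1: a + 1])
        out.append((d, ac, (d, ac) == ("GT", "AG")))
    return out


def fill_gap(scaffold: str, bridging_amplicon: str, flank: int = 30
             ) -> GapFillResult:
    """Replace the single N-run spanned by the amplicon with the amplicon
    content between exact flank matches (either amplicon orientation)."""
    import re

    runs = [(m.start(), m.end()) for m in re.finditer(r"N+", scaffold)]
    if not runs:
        raise ValueError("scaffold contains no N-run")
    solutions = []
    for a, b in runs:
        left = scaffold[max(0, a - flank): a]
        right = scaffold[b: b + flank]
        if len(left) < flank or len(right) < flank:
            continue
        for amp in (bridging_amplicon, revcomp(bridging_amplicon)):
            li = _find_unique(amp, left)
            ri = _find_unique(amp, right)
            if li is None or ri is None or ri < li + flank:
                continue
            fill = amp[li + flank: ri]
            if "N" in fill or not fill:
                continue
            solutions.append(GapFillResult((a + 1, b), fill, len(fill) - (b - a)))
    if not solutions:
        raise ValueError("amplicon flanks not found around any N-run")
    if len(solutions) > 1:
        raise ValueError("ambiguous gap fill: flanks match more than one way")
    return solutions[0]


def _find_unique(hay: str, needle: str) -> Optional[int]:
    i = hay.find(needle)
    if i < 0 or hay.find(needle, i + 1) >= 0:
        return None
    return i


def build_transcript(model: ExonIntronModel, scaffold: str) -> TranscriptRecord:
    """Splice the exons 5'->3' on the transcribed strand with a bijective
    transcript<->scaffold coordinate map."""
    pieces, coords = [], []
    for a, b in model.exons_5p_to_3p():
        seq = scaffold[a - 1: b]
        if model.strand == "-":
            seq = revcomp(seq)
            coords.append(np.arange(b, a - 1, -1))
        else:
            coords.append(np.arange(a, b + 1))
        if "N" in seq:
            raise ValueError(f"exon {a}-{b} contains N; fill the gap first")
        pieces.append(seq)
    sequence = "".join(pieces)
    boundaries, t = [], 0
    for p in pieces[:-1]:
        t += len(p)
        boundaries.append(t + 1)
    return TranscriptRecord(sequence, len(sequence), boundaries,
                            np.concatenate(coords))


def summarize_model(model: ExonIntronModel, scaffold: str) -> pd.DataFrame:
    """Per-feature table in gene order: (feature, first 8 nt, last 8 nt, length),
    plus transcript and gene-span totals rows."""
    rows = []
    exons = model.exons_5p_to_3p()
    introns = model.introns_5p_to_3p()
    for i, (a, b) in enumerate(exons):
        rows.append(_feature_row(f"Exon {i + 1}", a, b, model.strand, scaffold))
        if i < len(introns):
            ia, ib = introns[i]
            rows.append(_feature_row(f"Intron {i + 1}", ia, ib, model.strand,
                                     scaffold))
    rows.append({"feature": "Transcript total", "first_8nt": "", "last_8nt": "",
                 "length": model.transcript_length})
    rows.append({"feature": "Gene span total", "first_8nt": "", "last_8nt": "",
                 "length": model.gene_span})
    return pd.DataFrame(rows, columns=["feature", "first_8nt", "last_8nt",
                                       "length"])


def _feature_row(name: str, a: int, b: int, strand: str, scaffold: str) -> dict:
    seq = scaffold[a - 1: b]
    if strand == "-":
        seq = revcomp(seq)
    return {"feature": name, "first_8nt": seq[:8], "last_8nt": seq[-8:],
            "length": b - a + 1}
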