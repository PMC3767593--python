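"""Coordinate conventions.

Three frames are used throughout the package:

* **locus** — 0-based half-open indices into the gene-forward (transcribed-strand)
  sequence that the synthetic builder works in.  Position ``g0`` is the TSS base.
* **scaffold** — 1-based inclusive positions on the forward strand of the released
  scaffold.  For a minus-strand gene the scaffold is the reverse complement of the
  locus, so the TSS sits at a high scaffold coordinate and transcription runs
  toward lower coordinates.
* **promoter** — the field convention for positions around a TSS: +1 is the TSS
  base, -1 the base immediately upstream, and position 0 does not exist.

The helpers below are the only place those conversions are written out.
"""

from __future__ import annotations


def promoter_to_index(p: int, tss_index: int) -> int:
    """Promoter coordinate -> 0-based index, given the 0-based index of the TSS."""
    if p == 0:
        raise ValueError("promoter coordinate 0 does not exist")
    return tss_index + p - 1 if p > 0 else tss_index + p


def index_to_promoter(i: int, tss_index: int) -> int:
    """0-based index -> promoter coordinate (never 0)."""
    d = i - tss_index
    return d + 1 if d >= 0 else d


def promoter_span(start: int, end: int) -> int:
    """Inclusive length of a promoter interval, accounting for the missing 0."""
    if start > end:
        raise ValueError("start > end")
    n = end - start + 1
    if start < 0 and end > 0:
        n -= 1
    return n


def scaffold_to_locus(s: int, scaffold_len: int, strand: str) -> int:
    """1-based forward-scaffold position -> 0-based locus index."""
    if strand == "+":
        return s - 1
    return scaffold_len - s


def locus_to_scaffold(g: int, scaffold_len: int, strand: str) -> int:
    """0-based locus index -> 1-based forward-scaffold position."""
    if strand == "+":
        return g + 1
    return scaffold_len - g


def inclusive_offset(a: int, b: int) -> int:
    """Count of positions in the inclusive span between two coordinates.

    The convention the field uses for statements like "10 bp downstream": the span
    257,103..257,094 contains 10 positions, so two equal coordinates count 1.
    """
    return abs(a - b) + 1
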