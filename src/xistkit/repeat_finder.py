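"""Tandem-repeat detection, consensus building, and monomer folding.

Periods are proposed by a k-mer distance histogram (distances between repeated
k-mers vote for candidate periods), verified by gapless consensus identity,
and array boundaries are refined by score-drop extension against the consensus
phase.  Copy numbers are fractional (span / period, rounded half-up to one
decimal, so an 8,801-bp array of 96-mers is 91.7 copies).  Monomers are folded
with the Nussinov base-pair-maximisation recursion (Watson-Crick + GU) and
hairpin (stem-loop) counts are read off the dot-bracket structure.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import binom

from ._util import check_dna, round_half_up, seq_to_array


@dataclass
class RepeatRegion:
    interval: Tuple[int, int]          # transcript coordinates, 1-based inclusive
    period: int
    copy_number: float                 # span/period, half-up to 1 decimal
    consensus: str
    mean_identity: float
    copies: List[Tuple[Tuple[int, int], float]]   # (interval, identity) per copy

    @property
    def span(self) -> int:
        return self.interval[1] - self.interval[0] + 1


@dataclass
class FoldResult:
    structure: str
    pairs: int
    stem_loops: int


# ---------------------------------------------------------------------------
# consensus


def build_consensus(region_seq: str, period: int
                    ) -> Tuple[str, List[float]]:
    """Majority-vote consensus of fixed-period gapless copies.

    Column ties resolve in fixed base order A < C < G < T.  Returns the
    consensus monomer and per-copy identities (a trailing partial copy is
    scored over its own length).
    """
    seq = check_dna(region_seq, "region")
    if len(seq) <= period:
        raise ValueError("need at least two copies (the second may be partial)")
    cols: List[Counter] = [Counter() for _ in range(period)]
    for i, ch in enumerate(seq):
        cols[i % period][ch] += 1
    consensus = "".join(
        sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0][0] for c in cols)
    identities = []
    for start in range(0, len(seq), period):
        chunk = seq[start: start + period]
        match = sum(a == b for a, b in zip(chunk, consensus))
        identities.append(match / len(chunk))
    return consensus, identities


# ---------------------------------------------------------------------------
# tandem repeat detection


def find_tandem_repeats(transcript: str, period_range: Tuple[int, int] = (2, 200),
                        min_copies: float = 2.0, min_identity: float = 0.8,
                        vote_k: int = 5, min_votes: int = 4,
                        alpha: float = 0.01) -> List[RepeatRegion]:
    """Maximal non-overlapping tandem-repeat regions of the transcript.

    Smaller periods are tried first, so an array is reported at its true
    period rather than a multiple.  Trailing partial copies count
    fractionally toward the copy number.  Besides the identity threshold, a
    region must be statistically surprising: its lag-period self-match count
    is tested against the 1/4 background rate, Bonferroni-corrected for the
    positions and candidate periods searched, at level ``alpha`` — this is
    what keeps short-period chance matches in random sequence out.
    """
    lo, hi = period_range
    if not 2 <= lo <= hi <= 500:
        raise ValueError("period_range must lie within [2, 500]")
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0.5, 1.0]")
    seq = check_dna(transcript, "transcript")
    n = len(seq)
    if n < 2 * lo:
        return []
    arr = seq_to_array(seq)

    # k-mer distance histogram: consecutive recurrences vote for periods
    votes: Counter = Counter()
    last_seen: Dict[str, int] = {}
    for i in range(n - vote_k + 1):
        kmer = seq[i: i + vote_k]
        j = last_seen.get(kmer)
        if j is not None and lo <= i - j <= hi:
            votes[i - j] += 1
        last_seen[kmer] = i
    candidates = sorted(p for p, c in votes.items() if c >= min_votes)

    claimed = np.zeros(n, dtype=bool)
    regions: List[RepeatRegion] = []
    tau = 2 * min_identity - 1          # expected self-match rate at period p
    for p in candidates:
        m = (arr[:-p] == arr[p:]).astype(np.int32)
        if len(m) < p:
            continue
        win = np.convolve(m, np.ones(p, dtype=np.int32), mode="valid") / p
        good = win >= max(tau, 0.5)
        for run_start, run_end in _runs(good, merge_gap=p):
            anchor = run_start + int(np.argmax(win[run_start:run_end]))
            a, b = _refine(arr, p, run_start, min(n, run_end + 2 * p), anchor)
            # allow 0.2 copies of slack: a planted edge base destroyed by
            # divergence is indistinguishable from background
            if b - a < round((min_copies - 0.2) * p):
                continue
            if claimed[a:b].any():
                continue
            region_seq = seq[a:b]
            consensus, idents = build_consensus(region_seq, p)
            full = idents[:-1] if (b - a) % p else idents
            if not full or float(np.mean(full)) < min_identity:
                continue
            lag_m = int((arr[a: b - p] == arr[a + p: b]).sum())
            pval = float(binom.sf(lag_m - 1, b - a - p, 0.25))
            if pval * (n - p) * max(1, len(candidates)) > alpha:
                continue
            claimed[a:b] = True
            copies = []
            for ci, start in enumerate(range(a, b, p)):
                end = min(start + p, b)
                copies.append(((start + 1, end), idents[ci]))
            regions.append(RepeatRegion(
                interval=(a + 1, b),
                period=p,
                copy_number=round_half_up((b - a) / p, 1),
                consensus=consensus,
                mean_identity=float(np.mean(idents)),
                copies=copies,
            ))
    return sorted(regions, key=lambda r: r.interval)


def _runs(mask: np.ndarray, merge_gap: int) -> List[Tuple[int, int]]:
    """Start/end (exclusive) of True runs, merging runs closer than merge_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    out = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > merge_gap:
            out.append((int(start), int(prev) + 1))
            start = i
        prev = i
    out.append((int(start), int(prev) + 1))
    return out


def _refine(arr: np.ndarray, p: int, rough_a: int, rough_b: int, anchor: int,
            mismatch_penalty: int = 3, margin: int = 16) -> Tuple[int, int]:
    """Snap rough array bounds to the maximal-scoring extent.

    ``anchor`` is the position of the strongest windowed self-match signal, so
    ``[anchor, anchor + 2p)`` lies inside the array and fixes the consensus
    phase.  Boundaries are the maximum-sum subarray of a +1 match /
    -``mismatch_penalty`` mismatch score against the consensus phase; a second
    pass rebuilds the consensus from all full copies of the first-pass region.
    """
    n = len(arr)
    a0 = min(anchor, n - 2 * p)
    if a0 < 0:
        return rough_a, rough_a
    lo = max(0, rough_a - p - margin)
    hi = min(n, rough_b + p + margin)

    def kadane(cons: np.ndarray, phase_origin: int) -> Tuple[int, int]:
        idx = np.arange(lo, hi)
        match = arr[lo:hi] == cons[(idx - phase_origin) % p]
        scores = np.where(match, 1, -mismatch_penalty)
        best_sum, best = None, (rough_a, rough_a)
        cur, cur_start = 0, lo
        for i, s in enumerate(scores, start=lo):
            if cur < 0:
                cur, cur_start = 0, i
            cur += int(s)
            if best_sum is None or cur > best_sum:
                best_sum, best = cur, (cur_start, i + 1)
        return best

    m0 = max(2, min(8, (min(rough_b, n) - a0) // p))
    m0 = min(m0, (n - a0) // p)
    cons = seq_to_array(build_consensus(
        arr[a0: a0 + m0 * p].tobytes().decode(), p)[0])
    a1, b1 = kadane(cons, a0)
    m = (b1 - a1) // p
    if m >= 2:
        cons = seq_to_array(build_consensus(
            arr[a1: a1 + m * p].tobytes().decode(), p)[0])
        return kadane(cons, a1)
    return a1, b1


def search_monomer(transcript: str, probe: str, threshold: float = 0.7
                   ) -> Tuple[float, int, bool]:
    """Best gapless identity of a query monomer anywhere in the transcript.

    Returns (best identity, 1-based best start, present?); "absent" (as for
    the mouse C-repeat in the porcine transcript) means best identity is below
    the threshold.
    """
    seq = check_dna(transcript, "transcript")
    probe = check_dna(probe, "probe")
    if len(probe) > len(seq):
        raise ValueError("probe longer than transcript")
    arr, parr = seq_to_array(seq), seq_to_array(probe)
    n_off = len(seq) - len(probe) + 1
    matches = np.zeros(n_off, dtype=np.int32)
    for j in range(len(probe)):
        matches += arr[j: j + n_off] == parr[j]
    best = int(matches.argmax())
    ident = matches[best] / len(probe)
    return float(ident), best + 1, bool(ident >= threshold)


# ---------------------------------------------------------------------------
# folding


_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def fold_monomer(monomer: str, min_loop: int = 3) -> FoldResult:
    """Maximum base-pair secondary structure of a monomer (as RNA) by the
    Nussinov recursion, Watson-Crick plus GU wobble pairs.

    Traceback deterministically prefers pairing the leftmost admissible base.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    rna = check_dna(monomer, "monomer").replace("T", "U")
    n = len(rna)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if (rna[i], rna[k]) in _PAIRS:
                    left = dp[i + 1][k - 1] if k - i > min_loop + 1 else 0
                    right = dp[k + 1][j] if k < j else 0
                    best = max(best, 1 + left + right)
            dp[i][j] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        # pair i with its leftmost admissible partner whenever that is optimal,
        # otherwise leave i unpaired
        while i < j:
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if (rna[i], rna[k]) in _PAIRS:
                    left = dp[i + 1][k - 1] if k - i > min_loop + 1 else 0
                    right = dp[k + 1][j] if k < j else 0
                    if 1 + left + right == dp[i][j]:
                        structure[i], structure[k] = "(", ")"
                        trace(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    if n > min_loop + 1:
        trace(0, n - 1)
    s = "".join(structure)
    return FoldResult(s, s.count("("), count_stem_loops(s))


def count_stem_loops(structure: str) -> int:
    """Number of hairpin loops: pairs enclosing only unpaired bases."""
    depth = 0
    for ch in structure:
        depth += {"(": 1, ")": -1}.get(ch, 0)
        if depth < 0:
            raise ValueError("unbalanced structure")
    if depth != 0:
        raise ValueError("unbalanced structure")
    return len(re.findall(r"\(\.*\)", structure))
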