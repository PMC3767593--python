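"""Candidate-region selection by cross-species local alignment.

Reference-species exon sequences are aligned to the scaffold with a
seed-and-extend heuristic (exact k-mer seeds grouped by diagonal, then an
affine-gap Smith-Waterman extension over the seeded window), and scaffold
regions are kept when they carry above-threshold hits from enough distinct
species — the classic "score over 300, matched at least two species" filter
used to nominate lncRNA-encoding regions.

Scores are defined by :class:`ScoringScheme` (default megablast-like:
match +2, mismatch -3, gap of length L costing -5 - 2L); the threshold is a
parameter because raw aligner scores are tool-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from ._util import check_dna, revcomp, seq_to_array


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class AlignmentHit:
    species_id: str
    query_interval: Tuple[int, int]      # 1-based inclusive, on the input query
    scaffold_interval: Tuple[int, int]   # 1-based inclusive, forward scaffold
    strand: str
    score: int
    identity: float


@dataclass
class CandidateRegion:
    scaffold_interval: Tuple[int, int]
    supporting_species: Set[str] = field(default_factory=set)
    max_score: int = 0


# ---------------------------------------------------------------------------
# affine local alignment (Gotoh), vectorised by query row


def local_align(query: str, target: str, scheme: ScoringScheme = ScoringScheme()
                ) -> Tuple[int, Tuple[int, int], Tuple[int, int], float]:
    """Optimal local alignment score with traceback.

    Returns ``(score, query_interval, target_interval, identity)``, intervals
    1-based inclusive; identity is matches over alignment columns.  A gap of
    length L costs ``gap_open + L * gap_extend``.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return 0, (0, 0), (0, 0), 0.0
    if n * m > 40_000_000:
        raise ValueError("alignment problem too large; split the query")
    q = seq_to_array(query)
    t = seq_to_array(target)
    NEG = -(10 ** 9)
    go, ge, ma, mi = scheme.gap_open, scheme.gap_extend, scheme.match, scheme.mismatch

    M = np.full((n + 1, m + 1), 0, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap consuming target
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap consuming query
    jj = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(t == q[i - 1], ma, mi)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub + np.maximum(best_prev[:-1], 0)
        Iy[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Ix[i - 1, 1:]) + go + ge,
                               Iy[i - 1, 1:] + ge)
        src = np.maximum(M[i], Iy[i]) - ge * jj
        run = np.maximum.accumulate(src)
        Ix[i, 1:] = ge * jj[1:] + go + run[:-1]

    score = int(M.max())
    if score <= 0:
        return 0, (0, 0), (0, 0), 0.0
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    qi_end, tj_end = int(i), int(j)

    # traceback by recurrence equality
    matches = cols = 0
    state = "M"
    while True:
        if state == "M":
            cols += 1
            matches += int(q[i - 1] == t[j - 1])
            sub = ma if q[i - 1] == t[j - 1] else mi
            prev = M[i][j] - sub
            i, j = i - 1, j - 1
            if prev <= 0:
                break
            if M[i][j] == prev:
                state = "M"
            elif Ix[i][j] == prev:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            cols += 1
            v = Ix[i][j]
            j -= 1
            if Ix[i][j] == v - ge:
                state = "Ix"
            elif M[i][j] == v - go - ge:
                state = "M"
            else:
                state = "Iy"
        else:
            cols += 1
            v = Iy[i][j]
            i -= 1
            if Iy[i][j] == v - ge:
                state = "Iy"
            elif M[i][j] == v - go - ge:
                state = "M"
            else:
                state = "Ix"
    return score, (int(i) + 1, qi_end), (int(j) + 1, tj_end), matches / cols


# ---------------------------------------------------------------------------
# seed and extend


def _kmer_index(seq: str, k: int) -> Dict[str, List[int]]:
    idx: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def seed_extend_align(query: str, scaffold: str, k: int = 11,
                      scheme: ScoringScheme = ScoringScheme(),
                      min_score: int = 50, species_id: str = "query",
                      band: int = 48, pad: int = 80) -> List[AlignmentHit]:
    """Local-alignment hits of ``query`` against both strands of ``scaffold``.

    Exact k-mer seeds are grouped by diagonal; each diagonal cluster defines a
    scaffold window over which the full affine local alignment is computed, so
    reported scores equal the optimal local-alignment score of their intervals.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    query = check_dna(query, "query")
    scaffold = check_dna(scaffold, "scaffold")
    if not query or not scaffold:
        raise ValueError("query and scaffold must be non-empty")
    index = _kmer_index(scaffold, k)

    hits: Dict[Tuple, AlignmentHit] = {}
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        diags: List[int] = []
        for qpos in range(len(q) - k + 1):
            for spos in index.get(q[qpos: qpos + k], ()):
                diags.append(spos - qpos)
        if not diags:
            continue
        diags.sort()
        clusters: List[List[int]] = [[diags[0]]]
        for d in diags[1:]:
            if d - clusters[-1][-1] <= band:
                clusters[-1].append(d)
            else:
                clusters.append([d])
        for cl in clusters:
            lo = max(0, cl[0] - pad)
            hi = min(len(scaffold), cl[-1] + len(q) + pad)
            score, q_iv, t_iv, ident = local_align(q, scaffold[lo:hi], scheme)
            if score < min_score or score <= 0:
                continue
            s_iv = (lo + t_iv[0], lo + t_iv[1])
            if strand == "-":
                q_iv = (len(q) - q_iv[1] + 1, len(q) - q_iv[0] + 1)
            key = (strand, s_iv, q_iv)
            if key not in hits or hits[key].score < score:
                hits[key] = AlignmentHit(species_id, q_iv, s_iv, strand,
                                         score, ident)
    return sorted(hits.values(), key=lambda h: (-h.score, h.scaffold_interval))


def select_candidates(hits: Iterable[AlignmentHit], min_score: int = 300,
                      min_species: int = 2) -> List[CandidateRegion]:
    """Merge overlapping hit intervals on the scaffold and keep merged regions
    supported by a score strictly above ``min_score`` from at least
    ``min_species`` distinct species."""
    if min_score < 0 or min_species < 1:
        raise ValueError("min_score >= 0 and min_species >= 1 required")
    hits = sorted(hits, key=lambda h: h.scaffold_interval)
    if not hits:
        return []
    regions: List[List[AlignmentHit]] = [[hits[0]]]
    end = hits[0].scaffold_interval[1]
    for h in hits[1:]:
        s, e = h.scaffold_interval
        if s <= end:                       # 0-bp tolerance interval union
            regions[-1].append(h)
            end = max(end, e)
        else:
            regions.append([h])
            end = e
    out = []
    for group in regions:
        species = {h.species_id for h in group if h.score > min_score}
        if len(species) >= min_species:
            iv = (min(h.scaffold_interval[0] for h in group),
                  max(h.scaffold_interval[1] for h in group))
            out.append(CandidateRegion(iv, species,
                                       max(h.score for h in group)))
    return out


def candidates_as_hits(regions: Sequence[CandidateRegion]) -> List[AlignmentHit]:
    """Re-express candidate regions as hits (one per supporting species), e.g.
    to check that candidate selection is idempotent."""
    out = []
    for r in regions:
        for sp in sorted(r.supporting_species):
            out.append(AlignmentHit(sp, (1, r.scaffold_interval[1] -
                                         r.scaffold_interval[0] + 1),
                                    r.scaffold_interval, "+", r.max_score, 1.0))
    return out
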