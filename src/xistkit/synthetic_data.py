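"""Synthetic XIST-like locus generator with full ground truth.

Builds a minus-strand, multi-exon lncRNA locus on a scaffold-scale sequence and
simulates every experimental readout the analysis pipeline consumes: spliced
cDNA amplicons, 5'/3' RACE clone sequences, bisulfite-converted clones, and
paired-end short reads.  Every planted feature (exons, GT..AG introns, tandem
repeat arrays, promoter CpG sites, an N-gap with a known fill, transcript ends,
TF motifs, a poly-A signal) is recorded in a truth table so each pipeline stage
can be tested for exact parameter recovery without any external data.

Two presets are provided: :func:`desk_spec` (a ~6 kb gene for fast tests) and
:func:`porcine_scale_spec` (a 32,817-bp gene span producing a 25,215-bp, 7-exon
transcript, the geometry of the porcine XIST locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import DNA_BASES, check_dna, random_dna, revcomp
from .coords import index_to_promoter, locus_to_scaffold, promoter_to_index


class ConflictError(ValueError):
    """Two planted features claim the same bases."""


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class RepeatSpec:
    """A tandem-repeat array to plant, in transcript coordinates.

    ``copies`` may be fractional (the array ends mid-monomer); the planted span
    is ``round(copies * monomer_length)`` bases.
    """

    monomer_length: int
    copies: float
    transcript_start: int
    divergence: float = 0.0
    spacer_length: int = 0
    monomer: Optional[str] = None

    def __post_init__(self):
        if self.monomer_length < 2:
            raise ValueError("monomer_length must be >= 2")
        if self.copies < 2:
            raise ValueError("plantable arrays need copies >= 2")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")

    @property
    def span(self) -> int:
        n_full = int(self.copies)
        base = round(self.copies * self.monomer_length)
        return base + self.spacer_length * max(0, n_full - 1)

    @property
    def transcript_end(self) -> int:
        return self.transcript_start + self.span - 1


@dataclass(frozen=True)
class GapSpec:
    """An assembly gap: ``fill_len`` true bases at gene position ``gene_start``
    (+1 = TSS base, counted along the transcribed strand through introns) are
    replaced by ``placeholder_len`` Ns in the released scaffold."""

    gene_start: int
    fill_len: int = 626
    placeholder_len: int = 100


@dataclass(frozen=True)
class GeneSpec:
    exon_lengths: Tuple[int, ...]
    intron_lengths: Tuple[int, ...]
    strand: str = "-"
    flank_lengths: Tuple[int, int] = (3000, 2500)
    repeat_specs: Tuple[RepeatSpec, ...] = ()
    promoter_cpg_offsets: Tuple[int, ...] = ()
    methyl_profile: Dict[str, float] = field(
        default_factory=lambda: {"male": 0.96, "female": 0.50})
    gap: Optional[GapSpec] = None
    splice_donor: str = "GT"
    splice_acceptor: str = "AG"
    polya_signal: Tuple[str, int] = ("AATAAA", 21)
    motif_plants: Tuple[Tuple[str, int], ...] = ()
    tss_offsets: Tuple[int, ...] = (-5, -3, 1, 16, 48, 72, 143, 211)
    terminus_expected_shift: int = 10
    cpg_window: int = 2000

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def gene_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def validate(self) -> None:
        if len(self.exon_lengths) != len(self.intron_lengths) + 1:
            raise ValueError("need len(exon_lengths) == len(intron_lengths) + 1")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("all exon/intron lengths must be > 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        offs = self.promoter_cpg_offsets
        if any(o == 0 for o in offs):
            raise ValueError("promoter coordinate 0 does not exist")
        if list(offs) != sorted(offs):
            raise ValueError("promoter_cpg_offsets must be strictly increasing")
        tssi = self.flank_lengths[0]
        idx = [promoter_to_index(o, tssi) for o in offs]
        if any(b - a < 2 for a, b in zip(idx, idx[1:])):
            raise ValueError("CpG offsets must be >= 2 bp apart")
        if any(abs(o) > self.cpg_window for o in offs):
            raise ValueError("CpG offset outside the promoter window")
        # repeat arrays: disjoint, inside exons
        prev_end = 0
        bounds = _exon_transcript_bounds(self.exon_lengths)
        for r in sorted(self.repeat_specs, key=lambda r: r.transcript_start):
            if r.transcript_start <= prev_end:
                raise ConflictError("repeat arrays overlap in transcript coordinates")
            prev_end = r.transcript_end
            if not any(s <= r.transcript_start and r.transcript_end <= e
                       for s, e in bounds):
                raise ConflictError(
                    f"repeat array at +{r.transcript_start} crosses an exon boundary")
        if len(self.splice_donor) != 2 or len(self.splice_acceptor) != 2:
            raise ValueError("splice donor/acceptor must be dinucleotides")


def _exon_transcript_bounds(exon_lengths) -> List[Tuple[int, int]]:
    """1-based inclusive transcript interval of each exon."""
    out, t = [], 0
    for L in exon_lengths:
        out.append((t + 1, t + L))
        t += L
    return out


def porcine_promoter_cpg_offsets() -> Tuple[int, ...]:
    """78 CpG offsets in the +/-2 kb window: 13 dense in -284..+53, 54 dense in
    +285..+1727, 11 in sparse clusters that fall below the dense-region
    threshold.  The -5 site is the CpG inside the planted YY1 match."""
    sparse_up = [-1980, -1950, -1500, -1470, -1440, -900, -600, -560]
    dense1 = [-284, -260, -230, -200, -170, -140, -110, -80, -50, -5, 10, 30, 53]
    dense2 = [285, 305, 325] + [519 + round(i * 1208 / 50) for i in range(51)]
    sparse_down = [1930, 1960, 1990]
    return tuple(sparse_up + dense1 + dense2 + sparse_down)


_DEFAULT_MOTIFS = (("TTAAAG", -30), ("CCGCCATATT", -6))


def desk_spec() -> GeneSpec:
    """Fast desk-scale preset: 7 exons, 4,606-bp transcript, 6,021-bp span."""
    return GeneSpec(
        exon_lengths=(3000, 89, 136, 209, 329, 129, 714),
        intron_lengths=(800, 227, 214, 36, 39, 99),
        repeat_specs=(
            RepeatSpec(24, 8.0, 327, divergence=0.02),
            RepeatSpec(96, 9.7, 2050, divergence=0.08),
            RepeatSpec(6, 23.0, 3900),
            RepeatSpec(149, 2.0, 4100),
        ),
        promoter_cpg_offsets=porcine_promoter_cpg_offsets(),
        gap=GapSpec(gene_start=3080, fill_len=626, placeholder_len=100),
        motif_plants=_DEFAULT_MOTIFS,
    )


def porcine_scale_spec() -> GeneSpec:
    """Porcine XIST locus geometry: exon/intron lengths summing to a 25,215-bp
    transcript and a 32,817-bp gene span; 8x24-mer, 23x6-mer, 91.7x96-mer and
    2x149-mer arrays at the reported porcine transcript offsets."""
    return GeneSpec(
        exon_lengths=(17184, 89, 136, 209, 329, 129, 7139),
        intron_lengths=(1460, 2271, 2136, 356, 390, 989),
        repeat_specs=(
            RepeatSpec(24, 8.0, 327, divergence=0.02),
            RepeatSpec(6, 23.0, 2723),
            RepeatSpec(96, 91.7, 4302, divergence=0.08),
            RepeatSpec(149, 2.0, 24059),
        ),
        promoter_cpg_offsets=porcine_promoter_cpg_offsets(),
        gap=GapSpec(gene_start=15000, fill_len=626, placeholder_len=100),
        motif_plants=_DEFAULT_MOTIFS,
    )


# ---------------------------------------------------------------------------
# truth table / bundle


@dataclass
class RepeatTruth:
    transcript_start: int
    transcript_end: int
    period: int
    copies: float
    monomer: str


@dataclass
class TruthTable:
    spec: GeneSpec
    strand: str
    locus_seq: str                      # gene-forward (transcribed-strand), gap filled
    transcript_seq: str
    tss_locus_index: int                # 0-based index of the TSS base in locus_seq
    exon_locus: List[Tuple[int, int]]   # 0-based half-open, transcribed order
    intron_locus: List[Tuple[int, int]]
    t_to_g: np.ndarray                  # transcript pos t (1-based) -> locus index
    repeats: List[RepeatTruth]
    cpg_offsets: Tuple[int, ...]
    gap_locus: Optional[Tuple[int, int]]      # fill interval, 0-based half-open
    fill_seq: str
    placeholder_len: int
    terminus_transcript: int
    expected_terminus_transcript: int

    # -- derived geometry -------------------------------------------------
    @property
    def locus_len(self) -> int:
        return len(self.locus_seq)

    @property
    def tss_scaffold_pos(self) -> int:
        return locus_to_scaffold(self.tss_locus_index, self.locus_len, self.strand)

    @property
    def terminus_scaffold_pos(self) -> int:
        g = int(self.t_to_g[self.terminus_transcript - 1])
        return locus_to_scaffold(g, self.locus_len, self.strand)

    @property
    def expected_terminus_scaffold_pos(self) -> int:
        g = int(self.t_to_g[self.expected_terminus_transcript - 1])
        return locus_to_scaffold(g, self.locus_len, self.strand)

    @property
    def filled_scaffold(self) -> str:
        return revcomp(self.locus_seq) if self.strand == "-" else self.locus_seq

    def locus_interval_to_scaffold(self, a: int, b: int) -> Tuple[int, int]:
        """0-based half-open locus interval -> 1-based inclusive forward-scaffold."""
        if self.strand == "+":
            return a + 1, b
        return self.locus_len - b + 1, self.locus_len - a

    @property
    def exon_scaffold_intervals(self) -> List[Tuple[int, int]]:
        ivs = [self.locus_interval_to_scaffold(a, b) for a, b in self.exon_locus]
        return sorted(ivs)

    @property
    def intron_scaffold_intervals(self) -> List[Tuple[int, int]]:
        ivs = [self.locus_interval_to_scaffold(a, b) for a, b in self.intron_locus]
        return sorted(ivs)

    def promoter_window_seq(self, window: Optional[int] = None) -> Tuple[str, int]:
        """(sequence, 1-based TSS position within it) for the +/-window region,
        in transcribed-strand orientation."""
        w = window or self.spec.cpg_window
        a = self.tss_locus_index - w
        b = self.tss_locus_index + w
        return self.locus_seq[a:b], w + 1

    def transcript_pos_of_promoter(self, p: int) -> int:
        if p < 1:
            raise ValueError("upstream positions are not transcribed")
        return p


@dataclass
class ScaffoldBundle:
    scaffold_seq: str        # released scaffold, forward strand, N-run at the gap
    transcript_seq: str
    truth: TruthTable


# ---------------------------------------------------------------------------
# builder internals


class _Canvas:
    """Mutable locus with a lock mask naming which feature owns each base."""

    def __init__(self, seq: str):
        self.seq = list(seq)
        self.owner: Dict[int, str] = {}

    def plant(self, start: int, piece: str, label: str,
              allow_same: bool = False) -> None:
        for k, ch in enumerate(piece):
            pos = start + k
            prev = self.owner.get(pos)
            if prev is not None and not (allow_same and self.seq[pos] == ch):
                raise ConflictError(
                    f"feature {label!r} overlaps feature {prev!r} at locus index {pos}")
            self.seq[pos] = ch
            self.owner[pos] = label

    def safe_set(self, pos: int, disallow: str, rng: np.random.Generator) -> None:
        """Resample an unowned background base avoiding the given bases and any
        CG dinucleotide with its current neighbours."""
        if pos in self.owner or pos < 0 or pos >= len(self.seq):
            return
        bad = set(disallow)
        if pos > 0 and self.seq[pos - 1] == "C":
            bad.add("G")
        if pos + 1 < len(self.seq) and self.seq[pos + 1] == "G":
            bad.add("C")
        choices = [b for b in DNA_BASES if b not in bad]
        self.seq[pos] = choices[rng.integers(len(choices))]


def _random_monomer(rng: np.random.Generator, length: int, cg_free: bool) -> str:
    """A monomer with no internal periodicity (and optionally no CG, including
    across the head-to-tail junction)."""
    for _ in range(200):
        m = random_dna(rng, length)
        if cg_free and ("CG" in m or m[-1] + m[0] == "CG"):
            continue
        if m[0] == "C":      # keeps a later planted CpG just right of an array
            continue         # from extending the array phase
        if _max_circular_periodicity(m) >= 0.55:
            continue
        return m
    raise RuntimeError("could not draw an acceptable monomer")


def _max_circular_periodicity(m: str) -> float:
    """Max over lags of the circular self-match rate: in a head-to-tail array
    a monomer with high circular self-similarity at lag L looks like a tandem
    repeat of period L, so planted monomers must avoid it."""
    n = len(m)
    best = 0.0
    for lag in range(1, n):
        frac = sum(m[i] == m[(i + lag) % n] for i in range(n)) / n
        best = max(best, frac)
    return best


def _mutate_array(arr: List[str], rng: np.random.Generator, divergence: float,
                  cg_safe: bool) -> None:
    if divergence <= 0:
        return
    for i in range(len(arr)):
        if rng.random() >= divergence:
            continue
        options = [b for b in DNA_BASES if b != arr[i]]
        if cg_safe:
            if i > 0 and arr[i - 1] == "C":
                options = [b for b in options if b != "G"]
            if i + 1 < len(arr) and arr[i + 1] == "G":
                options = [b for b in options if b != "C"]
        if options:
            arr[i] = options[rng.integers(len(options))]


# ---------------------------------------------------------------------------
# build_scaffold


def build_scaffold(spec: GeneSpec, seed: int) -> ScaffoldBundle:
    """Deterministically build the locus, transcript, and released scaffold.

    Raises :class:`ConflictError` when planted features overlap or when the
    promoter-window CpG layout cannot be realised exactly.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    up, down = spec.flank_lengths
    span = spec.gene_span
    total = up + span + down
    g0 = up                                  # locus index of the TSS base
    if up < spec.cpg_window:
        raise ValueError("upstream flank shorter than the CpG window")

    canvas = _Canvas(random_dna(rng, total))

    # exon/intron layout in locus coordinates (0-based half-open)
    exon_locus, intron_locus = [], []
    g = g0
    for i, eL in enumerate(spec.exon_lengths):
        exon_locus.append((g, g + eL))
        g += eL
        if i < len(spec.intron_lengths):
            intron_locus.append((g, g + spec.intron_lengths[i]))
            g += spec.intron_lengths[i]

    # transcript position (1-based) -> locus index
    t_to_g = np.concatenate([np.arange(a, b) for a, b in exon_locus])
    L = spec.transcript_length

    # canonical splice sites on the transcribed strand
    for i, (a, b) in enumerate(intron_locus):
        if b - a < 4:
            raise ValueError("introns must be at least 4 bp")
        canvas.plant(a, spec.splice_donor, f"intron{i + 1}_donor")
        canvas.plant(b - 2, spec.splice_acceptor, f"intron{i + 1}_acceptor")

    # junction-adjacent exon bases avoid 'G' so spliced reads cannot also match
    # across a GT..AG intron boundary (keeps intronic depth identically zero)
    for i, (a, b) in enumerate(exon_locus):
        if i < len(intron_locus):
            canvas.safe_set(b - 1, "G" + spec.splice_donor[0], rng)
        if i > 0:
            canvas.safe_set(a, "G", rng)

    # transcript landmarks: TSS base and terminal base
    canvas.plant(g0, "T", "tss_base", allow_same=True)
    term_g = int(t_to_g[L - 1])
    if term_g not in canvas.owner:
        canvas.plant(term_g, "A", "terminus_base")

    # tandem-repeat arrays
    window_lo, window_hi = g0 - spec.cpg_window, g0 + spec.cpg_window
    repeats: List[RepeatTruth] = []
    for r in spec.repeat_specs:
        g_start = int(t_to_g[r.transcript_start - 1])
        in_window = g_start < window_hi and g_start + r.span > window_lo
        monomer = r.monomer or _random_monomer(rng, r.monomer_length, in_window)
        if r.spacer_length:
            n_full = int(r.copies)
            pieces = []
            for c in range(n_full):
                pieces.append(monomer)
                if c < n_full - 1:
                    pieces.append(random_dna(rng, r.spacer_length))
            tail = round((r.copies - n_full) * r.monomer_length)
            pieces.append(monomer[:tail])
            arr = list("".join(pieces))
        else:
            reps = -(-r.span // r.monomer_length)
            arr = list((monomer * reps)[: r.span])
        _mutate_array(arr, rng, r.divergence, cg_safe=in_window)
        canvas.plant(g_start, "".join(arr), f"repeat_p{r.monomer_length}")
        # make the planted span maximal: the two transcript-adjacent bases on
        # each side must break the consensus phase
        for dt, phase in ((-2, -2), (-1, -1), (r.span, r.span), (r.span + 1, r.span + 1)):
            t_adj = r.transcript_start + dt
            if 1 <= t_adj <= L:
                canvas.safe_set(int(t_to_g[t_adj - 1]),
                                monomer[phase % r.monomer_length], rng)
        repeats.append(RepeatTruth(r.transcript_start, r.transcript_end,
                                   r.monomer_length, r.copies, monomer))

    # promoter motifs
    for pat, p_start in spec.motif_plants:
        canvas.plant(promoter_to_index(p_start, g0), check_dna(pat), f"motif_{pat}",
                     allow_same=True)

    # poly-A signal ending `dist` bp upstream of the terminus; the base after
    # the terminus must not be 'A' (a genomic A-run would make the RACE-called
    # end ambiguous) and no chance signal may sit nearer the terminus
    hexamer, dist = spec.polya_signal
    end_t = L - dist
    polya_g0 = int(t_to_g[end_t - len(hexamer)])
    for k, ch in enumerate(hexamer):
        canvas.plant(polya_g0 + k, ch, "polya_signal", allow_same=True)
    canvas.safe_set(term_g + 1, "A", rng)
    _scrub_spurious(canvas, hexamer, term_g - dist - 40, term_g + 1,
                    {polya_g0}, rng)

    # gap fill region (records the interval; plants a DraI site in its centre)
    gap_locus = None
    fill_seq = ""
    placeholder_len = 0
    if spec.gap is not None:
        a = g0 + spec.gap.gene_start - 1
        b = a + spec.gap.fill_len
        if b > g0 + span:
            raise ValueError("gap extends past the gene span")
        mid = (a + b) // 2 - 3
        canvas.plant(mid, "TTTAAA", "gap_dral_site")
        gap_locus = (a, b)
        placeholder_len = spec.gap.placeholder_len

    # CpG window: scrub background CGs, then plant the offsets
    _scrub_window_cg(canvas, window_lo, window_hi, spec, g0, rng)
    for off in spec.promoter_cpg_offsets:
        pos = promoter_to_index(off, g0)
        canvas.plant(pos, "CG", f"cpg_{off}", allow_same=True)

    # final exactness check
    seq = "".join(canvas.seq)
    found = [index_to_promoter(i, g0)
             for i in range(window_lo, window_hi)
             if seq[i] == "C" and seq[i + 1] == "G"]
    if tuple(found) != tuple(spec.promoter_cpg_offsets):
        extra = set(found) - set(spec.promoter_cpg_offsets)
        missing = set(spec.promoter_cpg_offsets) - set(found)
        raise ConflictError(
            f"promoter CpG layout not realisable: extra={sorted(extra)}, "
            f"missing={sorted(missing)}")

    if spec.gap is not None:
        fill_seq = seq[gap_locus[0]: gap_locus[1]]

    transcript = "".join(seq[g] for g in t_to_g)
    truth = TruthTable(
        spec=spec, strand=spec.strand, locus_seq=seq, transcript_seq=transcript,
        tss_locus_index=g0, exon_locus=exon_locus, intron_locus=intron_locus,
        t_to_g=t_to_g, repeats=repeats, cpg_offsets=spec.promoter_cpg_offsets,
        gap_locus=gap_locus, fill_seq=fill_seq, placeholder_len=placeholder_len,
        terminus_transcript=L,
        expected_terminus_transcript=L - spec.terminus_expected_shift + 1,
    )

    released_locus = seq
    if gap_locus is not None:
        a, b = gap_locus
        released_locus = seq[:a] + "N" * placeholder_len + seq[b:]
    scaffold = revcomp(released_locus) if spec.strand == "-" else released_locus
    return ScaffoldBundle(scaffold_seq=scaffold, transcript_seq=transcript,
                          truth=truth)


def _scrub_spurious(canvas: _Canvas, motif: str, lo: int, hi: int,
                    keep_starts: set, rng: np.random.Generator) -> None:
    """Break chance occurrences of a planted motif within a locus range so the
    planted occurrence is the unambiguous nearest one."""
    lo = max(0, lo)
    for _ in range(20):
        dirty = False
        seq = "".join(canvas.seq[lo: hi + len(motif)])
        for k in range(len(seq) - len(motif) + 1):
            i = lo + k
            if seq[k: k + len(motif)] == motif and i not in keep_starts:
                free = [i + d for d in range(len(motif))
                        if (i + d) not in canvas.owner]
                if not free:
                    raise ConflictError(
                        f"cannot break spurious {motif} at locus index {i}")
                pos = free[len(free) // 2]
                canvas.safe_set(pos, canvas.seq[pos], rng)
                dirty = True
        if not dirty:
            return


def _scrub_window_cg(canvas: _Canvas, lo: int, hi: int, spec: GeneSpec,
                     g0: int, rng: np.random.Generator) -> None:
    wanted = {promoter_to_index(o, g0) for o in spec.promoter_cpg_offsets}
    for i in range(lo, hi):
        if canvas.seq[i] == "C" and canvas.seq[i + 1] == "G" and i not in wanted:
            if i not in canvas.owner:
                canvas.safe_set(i, "CG", rng)     # not C (re-pairing), not G (left C)
            elif (i + 1) not in canvas.owner:
                canvas.safe_set(i + 1, "G", rng)
            else:
                raise ConflictError(
                    f"planted features {canvas.owner[i]!r}/{canvas.owner[i + 1]!r} "
                    f"create an unplanted CpG at locus index {i}")


# ---------------------------------------------------------------------------
# simulated readouts


def simulate_race_clones(bundle: ScaffoldBundle, end: str,
                         offsets: Optional[Sequence[int]] = None,
                         clones_per_offset: int = 3, seed: int = 0,
                         clone_len: int = 400,
                         polya_len: int = 16) -> List[Tuple[str, str]]:
    """RACE-style clone sequences.

    ``end='five'``: ``offsets`` are promoter coordinates of clone 5' ends (default:
    the spec's planted TSS set); each clone runs ``clone_len`` bases into the
    transcript.  ``end='three'``: ``offsets`` are transcript coordinates of clone
    3' ends (default: the planted terminus); a poly-A tract is appended.
    """
    truth = bundle.truth
    L = len(truth.transcript_seq)
    clones: List[Tuple[str, str]] = []
    if end == "five":
        offsets = list(truth.spec.tss_offsets) if offsets is None else list(offsets)
        g0 = truth.tss_locus_index
        for p in offsets:
            if p == 0 or not (-truth.spec.cpg_window <= p <= L):
                raise ValueError(f"5' offset {p} outside the gene span")
            start_g = promoter_to_index(p, g0)
            lead = truth.locus_seq[start_g:g0] if p < 0 else ""
            t0 = 0 if p < 0 else p - 1
            body = truth.transcript_seq[t0: t0 + clone_len - len(lead)]
            for c in range(clones_per_offset):
                clones.append((f"race5_{p}_{c}", lead + body))
    elif end == "three":
        offsets = [L] if offsets is None else list(offsets)
        for t_end in offsets:
            if not 1 <= t_end <= L:
                raise ValueError(f"3' offset {t_end} outside the gene span")
            body = truth.transcript_seq[max(0, t_end - clone_len): t_end]
            for c in range(clones_per_offset):
                clones.append((f"race3_{t_end}_{c}", body + "A" * polya_len))
    else:
        raise ValueError("end must be 'five' or 'three'")
    return clones


@dataclass
class BisulfiteSimResult:
    clones: List[Tuple[str, str]]            # (clone id, converted sequence)
    regions: List[Tuple[int, int]]           # promoter-coordinate intervals
    clone_regions: Dict[str, Tuple[int, int]]
    states: Dict[str, Dict[int, bool]]       # clone id -> {site offset: methylated}


def default_bisulfite_regions(bundle: ScaffoldBundle, max_chunk: int = 13,
                              pad: int = 20) -> List[Tuple[int, int]]:
    """Amplicon-style regions tiling the dense CpG clusters (250-450 bp,
    8-16 sites each), mirroring a six-primer-set bisulfite design."""
    from .methylome import dense_regions, scan_cpg

    win, tss = bundle.truth.promoter_window_seq()
    cpg_map = scan_cpg(win, tss, bundle.truth.spec.cpg_window)
    regions = []
    for dr in dense_regions(cpg_map):
        sites = [s for s in cpg_map.sites if dr.interval[0] <= s <= dr.interval[1]]
        k = -(-len(sites) // max_chunk)
        for grp in np.array_split(np.array(sites), k):
            lo = promoter_to_index(int(grp[0]), 0) - pad
            hi = promoter_to_index(int(grp[-1]), 0) + 1 + pad
            regions.append((index_to_promoter(lo, 0), index_to_promoter(hi, 0)))
    return regions


def simulate_bisulfite_clones(bundle: ScaffoldBundle, sex: str, n_clones: int,
                              conversion_rate: float = 0.99, seed: int = 0,
                              regions: Optional[List[Tuple[int, int]]] = None,
                              ) -> BisulfiteSimResult:
    """Bisulfite-converted clone sequences for each amplified region, plus the
    true per-clone methylation states.

    Each CpG site is methylated with the sex's per-site probability; every
    unprotected C (CpG or not) converts to T with probability
    ``conversion_rate`` (top-strand model).
    """
    truth = bundle.truth
    if sex not in truth.spec.methyl_profile:
        raise ValueError(f"no methylation profile for sex {sex!r}")
    if not 0.9 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in (0.9, 1.0]")
    p_meth = truth.spec.methyl_profile[sex]
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = default_bisulfite_regions(bundle)

    win, tss = truth.promoter_window_seq()
    site_idx = {o: promoter_to_index(o, tss - 1) for o in truth.cpg_offsets}

    clones: List[Tuple[str, str]] = []
    clone_regions: Dict[str, Tuple[int, int]] = {}
    states: Dict[str, Dict[int, bool]] = {}
    for ri, (p_lo, p_hi) in enumerate(regions):
        a = promoter_to_index(p_lo, tss - 1)
        b = promoter_to_index(p_hi, tss - 1) + 1
        region_sites = [o for o in truth.cpg_offsets if a <= site_idx[o] < b]
        for c in range(n_clones):
            cid = f"bs_{sex}_r{ri}_{c}"
            meth = {o: bool(rng.random() < p_meth) for o in region_sites}
            protected = {site_idx[o] for o, m in meth.items() if m}
            out = []
            for i in range(a, b):
                ch = win[i]
                if ch == "C" and i not in protected:
                    ch = "T" if rng.random() < conversion_rate else "C"
                out.append(ch)
            clones.append((cid, "".join(out)))
            clone_regions[cid] = (p_lo, p_hi)
            states[cid] = meth
    return BisulfiteSimResult(clones, list(regions), clone_regions, states)


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual: str = ""

    def __post_init__(self):
        if not self.qual:
            self.qual = "I" * len(self.seq1)


def simulate_rnaseq(bundle: ScaffoldBundle, sex: str, n_pairs: int,
                    read_len: int = 90, insert: int = 200,
                    seed: int = 0) -> List[ReadPair]:
    """Paired-end reads from the spliced transcript (female) or nothing (male):
    the gene is expressed from the inactive-X in females only."""
    truth = bundle.truth
    L = len(truth.transcript_seq)
    if insert > L:
        raise ValueError(f"insert {insert} exceeds transcript length {L}")
    if read_len > insert:
        raise ValueError("read_len must be <= insert")
    if sex == "male" or n_pairs == 0:
        return []
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        s = int(rng.integers(0, L - insert + 1))
        frag = truth.transcript_seq[s: s + insert]
        pairs.append(ReadPair(f"frag{i}_{s + 1}", frag[:read_len],
                              revcomp(frag[-read_len:])))
    return pairs


def simulate_amplicons(bundle: ScaffoldBundle,
                       primer_pairs: Sequence[Tuple[str, str]],
                       template: str) -> List[str]:
    """PCR amplicons from the spliced transcript (``cdna``) or the true (gap
    filled) genomic sequence in transcribed orientation (``gdna``).  Primer
    pairs spanning introns therefore give shorter cDNA than gDNA products."""
    if template == "cdna":
        tmpl = bundle.transcript_seq
    elif template == "gdna":
        tmpl = bundle.truth.locus_seq
    else:
        raise ValueError("template must be 'cdna' or 'gdna'")
    out = []
    for fwd, rev in primer_pairs:
        fwd = check_dna(fwd, "forward primer")
        site2 = revcomp(check_dna(rev, "reverse primer"))
        i = _unique_find(tmpl, fwd, f"forward primer {fwd}")
        j = _unique_find(tmpl, site2, f"reverse primer {rev}")
        if j + len(site2) <= i:
            raise ValueError(f"primer pair ({fwd}, {rev}) faces the wrong way")
        out.append(tmpl[i: j + len(site2)])
    return out


def design_primer_pair(bundle: ScaffoldBundle, template: str, start: int,
                       end: int, length: int = 20) -> Tuple[str, str]:
    """Primer pair amplifying [start, end] (1-based inclusive) of the template."""
    tmpl = bundle.transcript_seq if template == "cdna" else bundle.truth.locus_seq
    return tmpl[start - 1: start - 1 + length], revcomp(tmpl[end - length: end])


def _unique_find(tmpl: str, probe: str, label: str) -> int:
    i = tmpl.find(probe)
    if i < 0:
        raise ValueError(f"{label} not found in template")
    if tmpl.find(probe, i + 1) >= 0:
        raise ValueError(f"{label} matches the template more than once")
    return i
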