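"""File interchange: FASTA/FASTQ via Biopython, BED / GFF3 / TSV writers, and
flat key-value serialization of a GeneSpec.

BED intervals are 0-based half-open; GFF3 and the tabular summaries are
1-based inclusive, matching the coordinate conventions in :mod:`.coords`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_model import ExonIntronModel
from .repeat_finder import RepeatRegion
from .synthetic_data import GapSpec, GeneSpec, RepeatSpec, ReadPair, ScaffoldBundle


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


def read_fasta(path) -> List[Tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq_pairs(pairs: Sequence[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual}\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def write_bed(intervals: Iterable[Tuple[str, int, int, str]], path) -> None:
    """Rows of (chrom, start0, end, name), 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def model_to_gff3(model: ExonIntronModel, seqid: str, path,
                  gene_id: str = "gene1") -> None:
    lines = ["##gff-version 3"]
    a, b = model.exons[0][0], model.exons[-1][1]
    lines.append(f"{seqid}\txistkit\tgene\t{a}\t{b}\t.\t{model.strand}\t.\t"
                 f"ID={gene_id}")
    for i, (ea, eb) in enumerate(model.exons):
        lines.append(f"{seqid}\txistkit\texon\t{ea}\t{eb}\t.\t{model.strand}\t.\t"
                     f"ID={gene_id}.exon{i + 1};Parent={gene_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def repeats_to_gff3(regions: Sequence[RepeatRegion], seqid: str, path) -> None:
    lines = ["##gff-version 3"]
    for i, r in enumerate(regions):
        lines.append(
            f"{seqid}\txistkit\ttandem_repeat\t{r.interval[0]}\t{r.interval[1]}"
            f"\t.\t+\t.\tID=repeat{i + 1};period={r.period};"
            f"copies={r.copy_number};consensus={r.consensus}")
    Path(path).write_text("\n".join(lines) + "\n")


def truth_to_bed(bundle: ScaffoldBundle, path, chrom: str = "scaffold") -> None:
    """Planted features as BED on the filled forward scaffold."""
    truth = bundle.truth
    rows = []
    for i, (a, b) in enumerate(truth.exon_scaffold_intervals):
        rows.append((chrom, a - 1, b, f"exon{i + 1}"))
    for i, (a, b) in enumerate(truth.intron_scaffold_intervals):
        rows.append((chrom, a - 1, b, f"intron{i + 1}"))
    for r in truth.repeats:
        g1 = int(truth.t_to_g[r.transcript_start - 1])
        g2 = int(truth.t_to_g[r.transcript_end - 1])
        a, b = truth.locus_interval_to_scaffold(min(g1, g2), max(g1, g2) + 1)
        rows.append((chrom, a - 1, b, f"repeat_p{r.period}"))
    write_bed(sorted(rows, key=lambda r: r[1]), path)


# ---------------------------------------------------------------------------
# GeneSpec flat config


def spec_to_config(spec: GeneSpec, path) -> None:
    def fmt(xs):
        return ",".join(str(x) for x in xs)

    lines = [
        f"exon_lengths={fmt(spec.exon_lengths)}",
        f"intron_lengths={fmt(spec.intron_lengths)}",
        f"strand={spec.strand}",
        f"flank_lengths={fmt(spec.flank_lengths)}",
        f"promoter_cpg_offsets={fmt(spec.promoter_cpg_offsets)}",
        f"methyl_profile={fmt(f'{k}:{v}' for k, v in spec.methyl_profile.items())}",
        f"splice_donor={spec.splice_donor}",
        f"splice_acceptor={spec.splice_acceptor}",
        f"polya_signal={spec.polya_signal[0]},{spec.polya_signal[1]}",
        f"tss_offsets={fmt(spec.tss_offsets)}",
        f"terminus_expected_shift={spec.terminus_expected_shift}",
        f"cpg_window={spec.cpg_window}",
    ]
    for r in spec.repeat_specs:
        lines.append(f"repeat={r.monomer_length},{r.copies},{r.transcript_start},"
                     f"{r.divergence},{r.spacer_length}")
    if spec.gap is not None:
        lines.append(f"gap={spec.gap.gene_start},{spec.gap.fill_len},"
                     f"{spec.gap.placeholder_len}")
    for pat, p in spec.motif_plants:
        lines.append(f"motif={pat},{p}")
    Path(path).write_text("\n".join(lines) + "\n")


def spec_from_config(path) -> GeneSpec:
    kv: dict = {}
    repeats, motifs, gap = [], [], None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if key == "repeat":
            m, c, t, d, s = val.split(",")
            repeats.append(RepeatSpec(int(m), float(c), int(t), float(d), int(s)))
        elif key == "motif":
            pat, p = val.split(",")
            motifs.append((pat, int(p)))
        elif key == "gap":
            g, f, pl = val.split(",")
            gap = GapSpec(int(g), int(f), int(pl))
        else:
            kv[key] = val

    def ints(key):
        return tuple(int(x) for x in kv[key].split(","))

    profile = dict(item.split(":") for item in kv["methyl_profile"].split(","))
    polya = kv["polya_signal"].split(",")
    return GeneSpec(
        exon_lengths=ints("exon_lengths"),
        intron_lengths=ints("intron_lengths"),
        strand=kv["strand"],
        flank_lengths=ints("flank_lengths"),
        repeat_specs=tuple(repeats),
        promoter_cpg_offsets=ints("promoter_cpg_offsets"),
        methyl_profile={k: float(v) for k, v in profile.items()},
        gap=gap,
        splice_donor=kv["splice_donor"],
        splice_acceptor=kv["splice_acceptor"],
        polya_signal=(polya[0], int(polya[1])),
        motif_plants=tuple(motifs),
        tss_offsets=ints("tss_offsets"),
        terminus_expected_shift=int(kv["terminus_expected_shift"]),
        cpg_window=int(kv["cpg_window"]),
    )


def alignments_to_sam(alignments, reference_length: int, path) -> None:
    """Minimal single-reference SAM (header + mandatory fields)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{alignments.reference_name}\tLN:{reference_length}\n")
        L = alignments.read_length
        for p in alignments.placements:
            flag = 16 if p.strand == "-" else 0
            fh.write(f"{p.read_id}\t{flag}\t{p.reference}\t{p.start}\t255\t"
                     f"{L}M\t*\t0\t0\t*\t*\tNM:i:{p.mismatches}\n")
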