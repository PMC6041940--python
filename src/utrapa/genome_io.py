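"""Genome/annotation I/O, gene models, and shared sequence primitives.

All internal coordinates are 0-based half-open genomic intervals ``(start, end)``.
Reports and tabular outputs use 1-based inclusive coordinates to match TAIR-style
printed positions. Strand is ``"+"`` or ``"-"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger("utrapa")

#: chromosome names treated as organellar and excluded from analysis
DEFAULT_ORGANELLAR_CHROMS = ("ChrM", "ChrC")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def max_a_run(seq: str) -> int:
    """Length of the longest run of consecutive A's in ``seq`` (case-insensitive)."""
    best = run = 0
    for base in seq.upper():
        if base == "A":
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


def has_a_run(seq: str, threshold: int) -> bool:
    """True iff ``seq`` contains >= ``threshold`` consecutive adenines.

    Single source of truth for the internal-priming filter and the 3'-RACE
    mimic classifier: an A-tract of this length in the genomic sense strand
    can anneal oligo-dT and fake a poly(A) tail.
    """
    return max_a_run(seq) >= threshold


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of the PAC-calling pipeline.

    min_pat_reads
        minimum supporting 3'-end tags for a poly(A) site (default 3).
    a_run_threshold
        genomic adenine-run length that flags internal priming (default 8).
    cluster_gap_nt
        maximum gap between neighbouring sites co-clustered into one PAC,
        reflecting cleavage microheterogeneity (default 24).
    three_prime_extension_nt
        downstream extension of each transcript 3' end used to rescue
        unannotated 3'-UTR sites (default 120).
    a_scan_window_nt
        half-width of the sense-strand window scanned for A-runs around a
        cleavage position (default 10).
    """

    min_pat_reads: int = 3
    a_run_threshold: int = 8
    cluster_gap_nt: int = 24
    three_prime_extension_nt: int = 120
    a_scan_window_nt: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_pat_reads",
            "a_run_threshold",
            "cluster_gap_nt",
            "three_prime_extension_nt",
            "a_scan_window_nt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GenomeSequence:
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"chromosome {self.chrom_id} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sub-sequence on the requested strand, clipped at chromosome edges."""
        start = max(0, start)
        end = min(len(self.sequence), end)
        if end <= start:
            return ""
        seg = self.sequence[start:end]
        return seg if strand == "+" else reverse_complement(seg)


@dataclass
class TranscriptModel:
    """A transcript: ordered genomic exons plus an optional CDS span.

    UTRs are derived from exons minus CDS (strand-aware) rather than read from
    explicit UTR features, to tolerate GFF3 dialects.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s1, e1)} {(s2, e2)}"
                )

    # ---- derived structure -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def _exon_parts(self, lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if b > a:
                out.append((a, b))
        return out

    @property
    def five_utr_intervals(self) -> list[tuple[int, int]]:
        if self.cds_span is None:
            return []
        cs, ce = self.cds_span
        if self.strand == "+":
            return self._exon_parts(0, cs)
        return self._exon_parts(ce, self.span[1])

    @property
    def three_utr_intervals(self) -> list[tuple[int, int]]:
        if self.cds_span is None:
            return []
        cs, ce = self.cds_span
        if self.strand == "+":
            return self._exon_parts(ce, self.span[1])
        return self._exon_parts(0, cs)

    @property
    def cds_intervals(self) -> list[tuple[int, int]]:
        if self.cds_span is None:
            return []
        return self._exon_parts(*self.cds_span)

    def intron_region(self, intron: tuple[int, int]) -> str:
        """Which transcript region an intron interrupts: '5UTR'/'CDS'/'3UTR'."""
        if self.cds_span is None:
            return "5UTR"
        cs, ce = self.cds_span
        s, e = intron
        if e <= cs:
            return "5UTR" if self.strand == "+" else "3UTR"
        if s >= ce:
            return "3UTR" if self.strand == "+" else "5UTR"
        return "CDS"

    @property
    def three_prime_end(self) -> int:
        """0-based coordinate of the last transcribed base."""
        return self.span[1] - 1 if self.strand == "+" else self.span[0]

    # ---- coordinate mapping ------------------------------------------------

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a 0-based transcript (spliced) position to a 0-based genomic one."""
        if not 0 <= tpos < self.transcript_length:
            raise IndexError(f"transcript position {tpos} out of range")
        remaining = tpos
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in exons:
            n = e - s
            if remaining < n:
                return s + remaining if self.strand == "+" else e - 1 - remaining
            remaining -= n
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.sequence[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def five_utr_sequence(self, genome: GenomeSequence) -> str:
        if self.cds_span is None:
            return ""
        n = sum(e - s for s, e in self.five_utr_intervals)
        return self.spliced_sequence(genome)[:n]

    def cds_sequence(self, genome: GenomeSequence) -> str:
        if self.cds_span is None:
            return ""
        n5 = sum(e - s for s, e in self.five_utr_intervals)
        nc = sum(e - s for s, e in self.cds_intervals)
        return self.spliced_sequence(genome)[n5 : n5 + nc]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_organellar: bool = False

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start of the longest transcript."""
        t = longest_transcript(self)
        return t.span[0] if self.strand == "+" else t.span[1] - 1


def longest_transcript(gene: GeneModel) -> TranscriptModel:
    """Reference isoform: maximal summed exon length, ties to smallest id."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(gene.transcripts, key=lambda t: (-t.transcript_length, t.transcript_id))


def extend_three_prime(
    transcript: TranscriptModel,
    params: PipelineParams,
    chrom_length: int,
) -> tuple[int, int]:
    """Interval (0-based half-open) immediately downstream of the transcript 3' end.

    Used to rescue poly(A) sites falling just past an annotated 3'-UTR; clipped
    at the chromosome edge so a transcript near the end yields a short interval.
    """
    ext = params.three_prime_extension_nt
    if transcript.strand == "+":
        start = transcript.span[1]
        return start, min(chrom_length, start + ext)
    end = transcript.span[0]
    return max(0, end - ext), end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def load_genome(fasta_path: str | Path) -> dict[str, GenomeSequence]:
    """Load a (multi-)FASTA into uppercase GenomeSequence records."""
    fasta_path = Path(fasta_path)
    with open(fasta_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{fasta_path}: not FASTA (line {lineno} lacks '>')"
                    )
                break
        else:
            raise ValueError(f"{fasta_path}: empty FASTA file")
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genome:
        raise ValueError(f"{fasta_path}: no FASTA records")
    return genome


def write_genome(genome: dict[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.values():
            fh.write(f">{chrom.chrom_id}\n")
            seq = chrom.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def load_annotation(
    gff3_path: str | Path,
    organellar_chroms: Iterable[str] = DEFAULT_ORGANELLAR_CHROMS,
) -> list[GeneModel]:
    """Assemble gene models from a GFF3 with gene/mRNA/exon/CDS features."""
    import gffutils

    organellar = set(organellar_chroms)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            is_organellar=g.seqid in organellar,
        )
        for t in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            if not exons:
                warnings.warn(f"transcript {t.id} has no exons; skipped")
                continue
            cds_span = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else None
            gene.transcripts.append(
                TranscriptModel(t.id, g.seqid, g.strand, exons, cds_span)
            )
        if gene.transcripts:
            genes.append(gene)
        else:
            warnings.warn(f"gene {g.id} has no usable transcripts; skipped")
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (gene/mRNA/exon/CDS; 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        gs, ge = gene.span
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    "utrapa",
                    "gene",
                    str(gs + 1),
                    str(ge),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for t in gene.transcripts:
            ts, te = t.span
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        "utrapa",
                        "mRNA",
                        str(ts + 1),
                        str(te),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={t.transcript_id};Parent={gene.gene_id}",
                    ]
                )
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "utrapa",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}",
                        ]
                    )
                )
            if t.cds_span is not None:
                for i, (s, e) in enumerate(t.cds_intervals, 1):
                    lines.append(
                        "\t".join(
                            [
                                gene.chrom,
                                "utrapa",
                                "CDS",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                "0",
                                f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}",
                            ]
                        )
                    )
    Path(path).write_text("\n".join(lines) + "\n")
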