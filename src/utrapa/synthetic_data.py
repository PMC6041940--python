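"""Synthetic genomes, PAT tags, 3'-RACE reads and planted 5'-UTR duplications.

Every generator records ground truth so each pipeline stage can be scored
without external data. The stated world:

* background composition is uniform (25% per base) with homopolymer runs
  capped below the internal-priming threshold, so adenine tracts exist only
  where planted and the A-run filter's background false-positive rate is ~0;
* planted 5'-UTR cleavage sites receive tags with truncated jitter (|dx| <= 12)
  so one planted site yields exactly one 24-nt cluster;
* contaminant tags sit immediately 5' of planted >= 8-nt genomic A-tracts, so
  the internal-priming filter removes them by construction;
* per-PAC expression spans the ~26-646 tag range seen for confirmed 5'-UTR
  PACs;
* planted duplications copy the mORF 5' end into the 5'-UTR at an exact
  percent identity (substitution mask, no indels), install stop-creating codon
  edits (e.g. TAC->TAA, TGA->TAA) and place an intron at a controlled offset
  from the tract's 3' margin.

All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    longest_transcript,
    reverse_complement,
    write_annotation,
    write_genome,
)
from .race_validate import Locus, RaceRead
from .uorf_evolution import find_uorfs

BASES = "ACGT"
FORBIDDEN_3MERS = ("ATG", "TAA", "TAG", "TGA")
MAX_HOMOPOLYMER = 4  # for A and T: keeps both strands free of priming tracts
A_TRACT_LEN = 12  # planted contaminant tracts; >= 8 triggers the filter,
#                   >= 10 lets a mimic read pass tail detection


# ---------------------------------------------------------------------------
# constrained sequence generation
# ---------------------------------------------------------------------------


def _constrained_seq(rng: np.random.Generator, length: int, context: str = "") -> str:
    """Random sequence avoiding ATG, stop-codon 3-mers and long A/T runs.

    ``context`` is the already-generated sequence immediately 5' of the new
    segment, so constraints hold across segment junctions.
    """
    out: list[str] = []

    def tail(k: int) -> str:
        joint = context + "".join(out)
        return joint[-k:]

    while len(out) < length:
        placed = False
        for k in rng.permutation(4):
            b = BASES[k]
            t3 = tail(2) + b
            if any(t3.endswith(p) for p in FORBIDDEN_3MERS):
                continue
            if b in "AT":
                run = 1
                for c in reversed(tail(MAX_HOMOPOLYMER)):
                    if c == b:
                        run += 1
                    else:
                        break
                if run > MAX_HOMOPOLYMER:
                    continue
            out.append(b)
            placed = True
            break
        if not placed:  # pragma: no cover - constraints always leave an option
            out.pop()
    return "".join(out)


def _has_forbidden(seq: str, allowed_atg: set[int], allowed_stop: set[int]) -> bool:
    """Scan for ATG/stop 3-mers or >=5 A-runs outside the allowed start positions."""
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri == "ATG" and i not in allowed_atg:
            return True
        if tri in ("TAA", "TAG", "TGA") and i not in allowed_stop:
            return True
    return "AAAAA" in seq


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass
class PlantedPac:
    gene_id: str
    chrom: str
    strand: str
    region: str  # 'UTR' or 'UTR_intron'
    cleavage_position: int  # 1-based genomic, last transcribed base
    expression: int


@dataclass
class ContaminantSite:
    gene_id: str
    chrom: str
    strand: str
    cleavage_position: int  # 1-based genomic position tags anchor to
    tract_start: int  # 1-based genomic start of the planted A-tract (sense 5' end)
    tract_len: int = A_TRACT_LEN


@dataclass
class PlantedDuplication:
    gene_id: str
    tract_utr_interval: tuple[int, int]  # 1-based, spliced 5'-UTR coordinates
    tract_len: int
    substitution_mask: list[int]  # 0-based tract offsets, stop edits included
    stop_substitutions: list[tuple[str, str, int]]  # (mORF codon, uORF codon, tract offset)
    intron_offset: int
    identity_percent: float
    pseudogene_interval: Optional[tuple[int, int]] = None


@dataclass
class TruthSet:
    rng_seed: int
    planted_pacs: list[PlantedPac] = field(default_factory=list)
    contaminant_sites: list[ContaminantSite] = field(default_factory=list)
    planted_duplications: list[PlantedDuplication] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            rng_seed=raw["rng_seed"],
            planted_pacs=[PlantedPac(**r) for r in raw["planted_pacs"]],
            contaminant_sites=[ContaminantSite(**r) for r in raw["contaminant_sites"]],
            planted_duplications=[
                PlantedDuplication(
                    **{
                        **r,
                        "tract_utr_interval": tuple(r["tract_utr_interval"]),
                        "stop_substitutions": [tuple(s) for s in r["stop_substitutions"]],
                        "pseudogene_interval": tuple(r["pseudogene_interval"])
                        if r["pseudogene_interval"]
                        else None,
                    }
                )
                for r in raw["planted_duplications"]
            ],
        )


@dataclass
class LayoutSpec:
    """Fractions of gene-structure features in the synthetic genome."""

    frac_utr_intron: float = 0.4
    frac_same_strand_upstream: float = 0.2
    frac_convergent_upstream: float = 0.2
    frac_minus_strand: float = 0.5
    frac_two_transcripts: float = 0.2


@dataclass
class SyntheticWorld:
    genome: dict[str, GenomeSequence]
    genes: list[GeneModel]
    truth: TruthSet
    #: reserved genomic interval per main gene (room for in-place rewrites)
    slots: dict[str, tuple[int, int]] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def locus_for_gene(self, gene_id: str, flank: int = 200) -> Locus:
        gene = self.gene(gene_id)
        chrom = self.genome[gene.chrom]
        s, e = gene.span
        s = max(0, s - flank)
        e = min(len(chrom), e + flank)
        return Locus(gene.chrom, gene.strand, s, chrom.fetch(s, e, gene.strand))

    def duplication_sequences(self, gene_id: str) -> tuple[str, str]:
        """(spliced 5'-UTR, CDS) sense sequences of a gene's reference isoform."""
        gene = self.gene(gene_id)
        t = longest_transcript(gene)
        chrom = self.genome[gene.chrom]
        return t.five_utr_sequence(chrom), t.cds_sequence(chrom)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, outdir / "genome.fa")
        write_annotation(self.genes, outdir / "annotation.gff3")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# gene assembly
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    label: str  # utr5_exon | utr5_intron | cds_exon | cds_intron | utr3_exon
    sequence: str


def _sense_to_genomic(start: int, length: int, strand: str, s: int, e: int) -> tuple[int, int]:
    if strand == "+":
        return start + s, start + e
    return start + length - e, start + length - s


def _gene_from_layout(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    segments: Sequence[_Segment],
    second_transcript: bool = False,
) -> tuple[GeneModel, str]:
    """Build a GeneModel from sense-ordered segments; returns the genomic-strand
    sequence to splice into the chromosome at ``start``."""
    sense = "".join(seg.sequence for seg in segments)
    length = len(sense)
    # sense offsets per segment
    offs = []
    pos = 0
    for seg in segments:
        offs.append((pos, pos + len(seg.sequence), seg.label))
        pos += len(seg.sequence)
    # merge adjacent non-intron stretches into exons (sense space)
    exon_sense: list[tuple[int, int]] = []
    for s, e, label in offs:
        if label.endswith("intron"):
            continue
        if exon_sense and exon_sense[-1][1] == s:
            exon_sense[-1] = (exon_sense[-1][0], e)
        else:
            exon_sense.append((s, e))
    exons = sorted(
        _sense_to_genomic(start, length, strand, s, e) for s, e in exon_sense
    )
    cds_parts = [(s, e) for s, e, label in offs if label == "cds_exon"]
    cds_span = None
    if cds_parts:
        lo = min(s for s, _ in cds_parts)
        hi = max(e for _, e in cds_parts)
        cds_span = tuple(sorted(_sense_to_genomic(start, length, strand, lo, hi)))
    transcripts = [TranscriptModel(f"{gene_id}.1", chrom, strand, exons, cds_span)]
    if second_transcript:
        # shorter isoform: 50 nt trimmed from the 3'-UTR end
        exons2 = [list(e) for e in exons]
        if strand == "+":
            exons2[-1][1] -= 50
        else:
            exons2[0][0] += 50
        transcripts.append(
            TranscriptModel(
                f"{gene_id}.2", chrom, strand, [tuple(e) for e in exons2], cds_span
            )
        )
    gene = GeneModel(gene_id, chrom, strand, transcripts)
    genomic_seq = sense if strand == "+" else reverse_complement(sense)
    return gene, genomic_seq


# ---------------------------------------------------------------------------
# make_genome
# ---------------------------------------------------------------------------


def _exact_flags(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    k = int(round(frac * n))
    flags = np.array([True] * k + [False] * (n - k))
    rng.shuffle(flags)
    return flags


def make_genome(
    n_genes: int,
    layout: Optional[LayoutSpec] = None,
    seed: int = 0,
    chrom_name: str = "Chr1",
    n_utr_pacs: Optional[int] = None,
    n_contaminants: Optional[int] = None,
    slot_spare: int = 1500,
) -> SyntheticWorld:
    """Deterministic synthetic chromosome with known gene structures and truth.

    ``n_utr_pacs`` genes (default: all) carry one planted 5'-UTR cleavage site;
    ``n_contaminants`` genes (default: n_genes // 5) carry a 12-nt genomic
    A-tract in their CDS that mimics a poly(A) site via internal priming.
    """
    layout = layout or LayoutSpec()
    rng = np.random.default_rng(seed)
    if n_utr_pacs is None:
        n_utr_pacs = n_genes
    if n_contaminants is None:
        n_contaminants = n_genes // 5
    if n_utr_pacs > n_genes or n_contaminants > n_genes:
        raise ValueError("cannot plant more features than genes")
    if layout.frac_same_strand_upstream + layout.frac_convergent_upstream > 1:
        raise ValueError("infeasible layout: neighbour fractions exceed 1")

    truth = TruthSet(rng_seed=int(seed))
    if n_genes == 0:
        seq = _constrained_seq(rng, 500)
        genome = {chrom_name: GenomeSequence(chrom_name, seq)}
        return SyntheticWorld(genome, [], truth)

    intron_flags = _exact_flags(rng, n_genes, layout.frac_utr_intron)
    two_tx_flags = _exact_flags(rng, n_genes, layout.frac_two_transcripts)
    neighbor_kind = (
        ["same"] * int(round(layout.frac_same_strand_upstream * n_genes))
        + ["conv"] * int(round(layout.frac_convergent_upstream * n_genes))
    )
    neighbor_kind += [None] * (n_genes - len(neighbor_kind))
    neighbor_arr = np.array(neighbor_kind, dtype=object)
    rng.shuffle(neighbor_arr)
    pac_genes = set(int(i) for i in rng.permutation(n_genes)[:n_utr_pacs])
    contaminant_genes = set(int(i) for i in rng.permutation(n_genes)[:n_contaminants])

    pieces: list[str] = []
    genes: list[GeneModel] = []
    slots: dict[str, tuple[int, int]] = {}
    cursor = 0

    def emit(seq: str) -> None:
        nonlocal cursor
        pieces.append(seq)
        cursor += len(seq)

    for i in range(n_genes):
        gene_id = f"SYNG{i + 1:04d}"
        strand = "-" if rng.random() < layout.frac_minus_strand else "+"
        emit(_constrained_seq(rng, int(rng.integers(2200, 3001))))

        # neighbour genomically left of the gene = upstream for '+' genes
        kind = neighbor_arr[i]
        n_strand = None
        if kind is not None:
            n_strand = strand if kind == "same" else ("-" if strand == "+" else "+")
        if kind is not None and strand == "+":
            _emit_neighbor(rng, genes, emit, cursor, chrom_name, gene_id, n_strand)
            emit(_constrained_seq(rng, int(rng.integers(300, 1201))))

        gene_start = cursor
        segments, pac_info, tract_info = _build_main_gene(
            rng,
            utr_intron=bool(intron_flags[i]),
            plant_pac=i in pac_genes,
            plant_tract=i in contaminant_genes,
        )
        gene, genomic_seq = _gene_from_layout(
            gene_id, chrom_name, strand, gene_start, segments, bool(two_tx_flags[i])
        )
        emit(genomic_seq)
        genes.append(gene)
        slots[gene_id] = (gene_start, cursor)

        if kind is not None and strand == "-":
            # neighbour occupies the spare region; no room for in-place rewrites
            del slots[gene_id]
            emit(_constrained_seq(rng, int(rng.integers(300, 1201))))
            _emit_neighbor(rng, genes, emit, cursor, chrom_name, gene_id, n_strand)
            emit(_constrained_seq(rng, slot_spare))
        else:
            emit(_constrained_seq(rng, slot_spare))
            slots[gene_id] = (slots[gene_id][0], cursor)

        gene_len = len(genomic_seq)
        if pac_info is not None:
            off, region = pac_info
            g0 = _sense_offset_to_genomic(gene_start, gene_len, strand, off)
            truth.planted_pacs.append(
                PlantedPac(
                    gene_id=gene_id,
                    chrom=chrom_name,
                    strand=strand,
                    region=region,
                    cleavage_position=g0 + 1,
                    expression=int(round(math.exp(rng.uniform(math.log(26), math.log(646))))),
                )
            )
        if tract_info is not None:
            tract_off = tract_info
            cleave0 = _sense_offset_to_genomic(gene_start, gene_len, strand, tract_off - 1)
            tract_g0 = _sense_offset_to_genomic(gene_start, gene_len, strand, tract_off)
            truth.contaminant_sites.append(
                ContaminantSite(
                    gene_id=gene_id,
                    chrom=chrom_name,
                    strand=strand,
                    cleavage_position=cleave0 + 1,
                    tract_start=tract_g0 + 1,
                )
            )

    emit(_constrained_seq(rng, 1000))
    genome = {chrom_name: GenomeSequence(chrom_name, "".join(pieces))}
    return SyntheticWorld(genome, genes, truth, slots)


def _sense_offset_to_genomic(start: int, length: int, strand: str, off: int) -> int:
    """0-based genomic coordinate of a 0-based sense offset within a gene."""
    return start + off if strand == "+" else start + length - 1 - off


def _emit_neighbor(rng, genes, emit, cursor, chrom_name, host_id, strand) -> None:
    segments = [
        _Segment("utr5_exon", _constrained_seq(rng, 60)),
        _Segment("cds_exon", "ATG" + _constrained_seq(rng, 240) + "TAA"),
        _Segment("utr3_exon", _constrained_seq(rng, 80)),
    ]
    gene, seq = _gene_from_layout(f"{host_id}N", chrom_name, strand, cursor, segments)
    emit(seq)
    genes.append(gene)


def _build_main_gene(
    rng: np.random.Generator,
    utr_intron: bool,
    plant_pac: bool,
    plant_tract: bool,
) -> tuple[list[_Segment], Optional[tuple[int, str]], Optional[int]]:
    """Sense-ordered segments for one gene plus planted-feature sense offsets."""
    context = ""

    def grow(label: str, length: int, literal: Optional[str] = None) -> _Segment:
        nonlocal context
        seq = literal if literal is not None else _constrained_seq(rng, length, context)
        context += seq
        return _Segment(label, seq)

    segments: list[_Segment] = []
    segments.append(grow("utr5_exon", int(rng.integers(150, 401))))
    if utr_intron:
        intron = "GT" + _constrained_seq(rng, int(rng.integers(90, 180)), context + "GT")
        segments.append(grow("utr5_intron", 0, intron + "AG"))
        segments.append(grow("utr5_exon", int(rng.integers(80, 201))))
    n_cod = int(rng.integers(90, 221))
    cds = "ATG" + _constrained_seq(rng, 3 * n_cod, context + "ATG") + "TAA"
    segments.append(grow("cds_exon", 0, cds))
    segments.append(grow("utr3_exon", int(rng.integers(100, 251))))

    pac_info: Optional[tuple[int, str]] = None
    if plant_pac:
        # pick the cleavage inside a 5'-UTR exon or intron, >= 15 nt from
        # segment borders so the whole jittered cluster stays in one region
        choices = []
        pos = 0
        for seg in segments:
            if seg.label == "utr5_exon":
                choices.append(("UTR", pos, pos + len(seg.sequence)))
            elif seg.label == "utr5_intron":
                choices.append(("UTR_intron", pos, pos + len(seg.sequence)))
            pos += len(seg.sequence)
        intron_choices = [c for c in choices if c[0] == "UTR_intron"]
        if intron_choices and rng.random() < 0.5:
            region, lo, hi = intron_choices[0]
        else:
            region, lo, hi = choices[0]
        off = int(rng.integers(lo + 15, hi - 15))
        pac_info = (off, region)

    tract_off: Optional[int] = None
    if plant_tract:
        pos = 0
        for seg in segments:
            if seg.label == "cds_exon":
                lo, hi = pos + 30, pos + len(seg.sequence) - 30
                tract_off = int(rng.integers(lo, hi - A_TRACT_LEN))
                rel = tract_off - pos
                s = seg.sequence
                seg.sequence = (
                    s[: rel - 1] + "C" + "A" * A_TRACT_LEN + "C" + s[rel + A_TRACT_LEN + 1 :]
                )
                break
            pos += len(seg.sequence)
    return segments, pac_info, tract_off


# ---------------------------------------------------------------------------
# PAT tag simulation
# ---------------------------------------------------------------------------


def simulate_pat_tags(
    world: SyntheticWorld,
    depth_per_pac: Optional[int] = None,
    jitter_sd: float = 5.0,
    contamination_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-read tag rows (chrom, position, strand, count=1).

    Each planted PAC receives ``depth_per_pac`` tags (default: its recorded
    expression level) jittered around the cleavage site with truncation at
    +/- 12 nt, so one planted site produces exactly one 24-nt cluster.
    Contaminant tags (a ``contamination_rate`` fraction of the genuine total)
    anchor at planted genomic A-tracts.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, str]] = []
    total_genuine = 0
    for pac in world.truth.planted_pacs:
        n = depth_per_pac if depth_per_pac is not None else pac.expression
        total_genuine += n
        jit = np.clip(
            np.rint(rng.normal(0.0, jitter_sd, size=n)).astype(int), -12, 12
        )
        for dx in jit:
            rows.append((pac.chrom, pac.cleavage_position + int(dx), pac.strand))
    sites = world.truth.contaminant_sites
    if sites and contamination_rate > 0:
        n_cont = int(round(contamination_rate * total_genuine))
        alloc = rng.multinomial(n_cont, [1.0 / len(sites)] * len(sites))
        for site, k in zip(sites, alloc):
            jit = np.clip(rng.integers(-2, 3, size=int(k)), -2, 2)
            for dx in jit:
                rows.append((site.chrom, site.cleavage_position + int(dx), site.strand))
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand"])
    df["count"] = 1
    return df


def split_cluster_sites(
    chrom: str, strand: str, position: int, gap: int, counts: tuple[int, int] = (5, 5)
) -> pd.DataFrame:
    """Two tag pile-ups ``gap`` nt apart: exercises the >cluster-gap split case."""
    rows = [(chrom, position, strand)] * counts[0] + [
        (chrom, position + gap, strand)
    ] * counts[1]
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand"])
    df["count"] = 1
    return df


# ---------------------------------------------------------------------------
# 3'-RACE read simulation
# ---------------------------------------------------------------------------


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def simulate_race_reads(
    world: SyntheticWorld,
    n_reads_per_site: int = 3,
    body_len: int = 150,
    tail_len_range: tuple[int, int] = (15, 40),
    error_rate: float = 0.0,
    mimic_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[RaceRead], pd.DataFrame]:
    """Simulated Sanger-style 3'-RACE reads plus a per-read truth table.

    Genuine reads: sense locus prefix ending at a planted cleavage site plus a
    poly(A) tail (length uniform in ``tail_len_range``). Mimic reads: sense
    locus prefix running into a planted genomic A-tract with NO added tail —
    the tract itself mimics one. Substitution errors at ``error_rate`` apply
    to the whole read.
    """
    rng = np.random.default_rng(seed)
    pacs = world.truth.planted_pacs
    tracts = world.truth.contaminant_sites
    total = n_reads_per_site * max(len(pacs), 1)
    n_mimic = int(round(mimic_fraction * total))
    n_genuine = total - n_mimic
    if n_mimic > 0 and not tracts:
        raise ValueError("mimic_fraction > 0 requires planted contaminant tracts")
    if n_genuine > 0 and not pacs:
        raise ValueError("genuine reads require planted PACs")
    reads: list[RaceRead] = []
    truth_rows = []

    for k in range(n_genuine):
        pac = pacs[k % len(pacs)]
        chrom = world.genome[pac.chrom]
        p0 = pac.cleavage_position - 1
        if pac.strand == "+":
            body = chrom.fetch(p0 + 1 - body_len, p0 + 1, "+")
        else:
            body = chrom.fetch(p0, p0 + body_len, "-")
        tail = "A" * int(rng.integers(tail_len_range[0], tail_len_range[1] + 1))
        seq = _apply_errors(rng, body + tail, error_rate)
        rid = f"race{k + 1:05d}"
        reads.append(RaceRead(rid, seq, target_gene=pac.gene_id))
        truth_rows.append(
            {
                "read_id": rid,
                "true_status": "genuine",
                "true_cleavage": pac.cleavage_position,
                "gene": pac.gene_id,
            }
        )

    for k in range(n_mimic):
        site = tracts[k % len(tracts)]
        chrom = world.genome[site.chrom]
        c0 = site.cleavage_position - 1
        ext = site.tract_len
        if site.strand == "+":
            seq = chrom.fetch(c0 + 1 - body_len, c0 + 1 + ext, "+")
        else:
            seq = chrom.fetch(c0 - ext, c0 + body_len, "-")
        seq = _apply_errors(rng, seq, error_rate)
        rid = f"race{n_genuine + k + 1:05d}"
        reads.append(RaceRead(rid, seq, target_gene=site.gene_id))
        truth_rows.append(
            {
                "read_id": rid,
                "true_status": "internal_mimic",
                "true_cleavage": site.cleavage_position,
                "gene": site.gene_id,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def write_reads_fasta(reads: Sequence[RaceRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            header = f">{r.read_id}"
            if r.target_gene:
                header += f" target={r.target_gene}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# planted duplication
# ---------------------------------------------------------------------------

_UORF1_STOP = 45  # frame-1 stop-codon start within the tract (TAC there)
_UORF2_ATG = 10  # frame-2 ATG start
_UORF2_STOP = 100  # frame-2 stop-codon start (TGA there)
_PREFIX_LEN = 80
_EXON2_LEN = 60
_INTRON_LEN = 120
_MISMATCH_FLANK = 12


def _build_morf_tract(
    rng: np.random.Generator, tract_len: int, with_motifs: bool
) -> str:
    """mORF 5'-end tract: starts ATG; free of other ATG/stop 3-mers and of long
    A-runs; optionally carries the TAC / frame-2 ATG / frame-2 TGA motifs whose
    later mutation creates the dual uORFs."""
    template: list[Optional[str]] = [None] * tract_len
    template[0:3] = list("ATG")
    allowed_atg = {0}
    allowed_stop: set[int] = set()
    if with_motifs:
        template[_UORF2_ATG : _UORF2_ATG + 3] = list("ATG")
        template[_UORF1_STOP : _UORF1_STOP + 3] = list("TAC")
        template[_UORF2_STOP : _UORF2_STOP + 3] = list("TGA")
        allowed_atg.add(_UORF2_ATG)
        allowed_stop.add(_UORF2_STOP)
    for attempt in range(200):
        sub = np.random.default_rng(rng.integers(0, 2**31))
        chars = list(template)
        ok = True
        for p in range(tract_len):
            if chars[p] is not None:
                continue
            placed = False
            for k in sub.permutation(4):
                b = BASES[k]
                chars[p] = b
                if _window_clean(chars, p, allowed_atg, allowed_stop):
                    placed = True
                    break
                chars[p] = None
            if not placed:
                ok = False
                break
        if not ok:
            continue
        seq = "".join(chars)
        if not _has_forbidden(seq, allowed_atg, allowed_stop):
            return seq
    raise RuntimeError("could not build a constrained mORF tract")


def _window_clean(
    chars: list[Optional[str]], p: int, allowed_atg: set[int], allowed_stop: set[int]
) -> bool:
    """Check fully-determined 3-mers and A-runs in the window around position p."""
    n = len(chars)
    for i in range(max(0, p - 2), min(n - 2, p + 1)):
        tri = chars[i : i + 3]
        if None in tri:
            continue
        s = "".join(tri)
        if s == "ATG" and i not in allowed_atg:
            return False
        if s in ("TAA", "TAG", "TGA") and i not in allowed_stop:
            return False
    lo = max(0, p - 4)
    window = chars[lo : min(n, p + 5)]
    run = 0
    for c in window:
        if c == "A":
            run += 1
            if run >= 5:
                return False
        else:
            run = 0
    return True


def plant_duplication(
    world: SyntheticWorld,
    gene_id: str,
    identity_target: float,
    stop_subs: Sequence[tuple[str, str]] = (("TAC", "TAA"), ("TGA", "TAA")),
    intron_offset: int = 10,
    seed: int = 0,
    tract_len: int = 200,
    emit_pseudogene: bool = False,
) -> PlantedDuplication:
    """Rebuild ``gene_id`` so its 5'-UTR carries a copy of its own mORF 5' end.

    The copy differs from the mORF tract by exactly
    ``round((1 - identity_target) * tract_len)`` substitutions (no indels); the
    stop-creating codon edits named in ``stop_subs`` (single-nucleotide changes
    such as TAC->TAA and TGA->TAA) are counted inside that mask, so the realized
    identity equals ``100 * identity_target`` exactly. An intron is placed
    ``intron_offset`` nt downstream of the tract's 3' margin. The spliced-UTR
    bases flanking the copy are chosen to mismatch the mORF continuation, so a
    local alignment terminates exactly at the tract boundaries.
    """
    if not 0 < identity_target <= 1:
        raise ValueError("identity_target must be in (0, 1]")
    stop_subs = [tuple(s) for s in stop_subs]
    for sub in stop_subs:
        if sub not in (("TAC", "TAA"), ("TGA", "TAA")):
            raise ValueError(f"unsupported stop substitution {sub}")
    with_motifs = bool(stop_subs)
    if with_motifs and tract_len < _UORF2_STOP + 10:
        raise ValueError("tract too short to host the dual-uORF motifs")
    gene = world.gene(gene_id)
    slot = world.slots.get(gene_id)
    if slot is None:
        raise ValueError(f"{gene_id} has no reserved slot for rewriting")
    rng = np.random.default_rng(seed)

    n_sub = int(round((1 - identity_target) * tract_len))
    forced_edits: list[tuple[int, str]] = []
    recorded_subs: list[tuple[str, str, int]] = []
    if ("TAC", "TAA") in stop_subs:
        forced_edits.append((_UORF1_STOP + 2, "A"))
        recorded_subs.append(("TAC", "TAA", _UORF1_STOP))
    if ("TGA", "TAA") in stop_subs:
        forced_edits.append((_UORF2_STOP + 1, "A"))
        recorded_subs.append(("TGA", "TAA", _UORF2_STOP))
    if n_sub < len(forced_edits):
        raise ValueError("identity_target too high to install the stop substitutions")

    protected = {0, 1, 2, tract_len - 2, tract_len - 1}
    if with_motifs:
        protected |= set(range(_UORF2_ATG, _UORF2_ATG + 3))
        protected |= set(range(_UORF1_STOP, _UORF1_STOP + 3))
        protected |= set(range(_UORF2_STOP, _UORF2_STOP + 3))
    pool = [p for p in range(tract_len) if p not in protected]

    # Construct-and-verify: the substitution mask is evenly spread, so the
    # planted register is almost always the unique local-alignment optimum;
    # on the rare random tract where a gapped detour scores higher, the whole
    # tract is re-drawn (deterministic for a fixed seed).
    from .uorf_evolution import self_duplication_scan

    # the G-spacer after the tract cannot match the C-spacer that follows the
    # UTR copy under any register shift, so the local alignment cannot creep
    # past the tract boundary even with gaps
    spacer = "G" * _MISMATCH_FLANK
    rest_len = 3 * 40 + (3 - (tract_len + len(spacer)) % 3) % 3
    cont_len = intron_offset + _EXON2_LEN
    for attempt in range(100):
        tract = _build_morf_tract(rng, tract_len, with_motifs)
        cds = tract + spacer + _constrained_seq(rng, rest_len, tract + spacer) + "TAA"
        mutated = _mutate_tract(
            rng, tract, forced_edits, n_sub - len(forced_edits), pool, with_motifs
        )
        if mutated is None:
            continue
        copy, mask = mutated
        prefix = _constrained_seq(rng, _PREFIX_LEN)
        continuation = "C" * min(_MISMATCH_FLANK, cont_len) + _constrained_seq(
            rng, cont_len - _MISMATCH_FLANK, prefix + copy + "C" * _MISMATCH_FLANK
        )
        rep = self_duplication_scan(prefix + copy + continuation, cds)
        if (
            rep is not None
            and rep.utr_interval == (_PREFIX_LEN + 1, _PREFIX_LEN + tract_len)
            and rep.morf_interval == (1, tract_len)
            and rep.n_columns == tract_len
            and rep.n_matches == tract_len - len(mask)
        ):
            break
    else:
        raise RuntimeError("could not plant a cleanly recoverable duplication")
    margin = continuation[:intron_offset]
    exon2 = continuation[intron_offset:]
    intron = "GT" + _constrained_seq(rng, _INTRON_LEN - 4) + "AG"
    utr3 = _constrained_seq(rng, 100)

    segments = [
        _Segment("utr5_exon", prefix + copy + margin),
        _Segment("utr5_intron", intron),
        _Segment("utr5_exon", exon2),
        _Segment("cds_exon", cds),
        _Segment("utr3_exon", utr3),
    ]
    sense_len = sum(len(s.sequence) for s in segments)
    gs, slot_end = slot
    pseudo_interval = None
    pad_len = slot_end - gs - sense_len
    pseudo_seq = ""
    if emit_pseudogene:
        pseudo_seq = _constrained_seq(rng, 40) + tract
        if pad_len < len(pseudo_seq) + 100:
            raise ValueError("slot too small for gene plus pseudogene copy")
    if pad_len < 0:
        raise ValueError(
            f"slot of {gene_id} too small ({slot_end - gs} nt) for a "
            f"{sense_len}-nt duplication gene"
        )

    new_gene, genomic_seq = _gene_from_layout(
        gene_id, gene.chrom, gene.strand, gs, segments
    )
    if pseudo_seq:
        pstart = gs + sense_len  # padding begins here: 40 nt filler, then tract
        pseudo_interval = (pstart + 41, pstart + 40 + tract_len)  # 1-based
    padding = pseudo_seq + _constrained_seq(rng, pad_len - len(pseudo_seq))

    chrom = world.genome[gene.chrom]
    seq = chrom.sequence
    chrom.sequence = seq[:gs] + genomic_seq + padding + seq[slot_end:]
    assert len(chrom.sequence) == len(seq)

    world.genes[[g.gene_id for g in world.genes].index(gene_id)] = new_gene
    world.truth.planted_pacs = [
        p for p in world.truth.planted_pacs if p.gene_id != gene_id
    ]
    world.truth.contaminant_sites = [
        c for c in world.truth.contaminant_sites if c.gene_id != gene_id
    ]

    # defensive check: the rebuilt gene must expose the planted tract and uORFs
    utr_seq, cds_seq = world.duplication_sequences(gene_id)
    if utr_seq[_PREFIX_LEN : _PREFIX_LEN + tract_len] != "".join(copy):
        raise RuntimeError("planted tract not recovered from the rebuilt gene")
    if with_motifs:
        stops = {
            u.end - 3 - _PREFIX_LEN
            for u in find_uorfs(utr_seq)
            if u.has_stop and u.end - 3 - _PREFIX_LEN in (_UORF1_STOP, _UORF2_STOP)
        }
        expected = set()
        if ("TAC", "TAA") in stop_subs:
            expected.add(_UORF1_STOP)
        if ("TGA", "TAA") in stop_subs:
            expected.add(_UORF2_STOP)
        if not expected <= stops:
            raise RuntimeError("planted uORF stops not recovered")

    entry = PlantedDuplication(
        gene_id=gene_id,
        tract_utr_interval=(_PREFIX_LEN + 1, _PREFIX_LEN + tract_len),
        tract_len=tract_len,
        substitution_mask=sorted(mask),
        stop_substitutions=recorded_subs,
        intron_offset=intron_offset,
        identity_percent=100.0 * (tract_len - len(mask)) / tract_len,
        pseudogene_interval=pseudo_interval,
    )
    world.truth.planted_duplications.append(entry)
    return entry


def _spread_mask_positions(
    n_total: int,
    tract_len: int,
    forced: list[int],
    protected: set[int],
) -> list[int]:
    """Evenly spread mask positions over the tract interior.

    Even spread keeps every terminal window of the tract below 40% local
    mismatch density, which makes the full ungapped tract the optimal local
    alignment under the default scoring (match +2, mismatch -3): trimming k
    terminal columns with x mismatches changes the score by -(2k - 5x), which
    stays <= 0 whenever x <= 0.4 k. The reported identity then equals the
    planted 100 x (1 - |mask|/L) exactly. The outermost 4 positions on each
    side stay untouched so the alignment ends are anchored by matches.
    """
    if n_total == 0:
        return []
    lo, hi = 4, tract_len - 4
    span = hi - lo
    if n_total > span:
        raise ValueError("identity_target too low for the tract length")
    pts = [lo + int((i + 0.5) * span / n_total) for i in range(n_total)]
    for fpos in forced:
        j = min(range(n_total), key=lambda i: abs(pts[i] - fpos))
        pts[j] = fpos
    taken = set(forced)
    out = list(forced)
    for p in pts:
        if p in forced:
            continue
        q = None
        for delta in (0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
            cand = p + delta
            if lo <= cand < hi and cand not in taken and cand not in protected:
                q = cand
                break
        if q is None:
            raise ValueError("identity_target too low for an evenly spread mask")
        taken.add(q)
        out.append(q)
    return sorted(out)


def _mutate_tract(
    rng: np.random.Generator,
    tract: str,
    forced_edits: list[tuple[int, str]],
    n_random: int,
    pool: list[int],
    with_motifs: bool,
) -> tuple[str, list[int]]:
    """Apply the forced stop edits plus ``n_random`` evenly spread substitutions
    without creating or destroying ATG/stop codons that would confuse the uORF
    analysis."""
    if n_random > len(pool):
        raise ValueError("identity_target too low for the tract length")
    tract_len = len(tract)
    allowed_atg = {0} | ({_UORF2_ATG} if with_motifs else set())
    allowed_stop = {_UORF1_STOP, _UORF2_STOP} if with_motifs else set()
    protected = set(range(tract_len)) - set(pool)
    forced_pos = [p for p, _ in forced_edits]
    n_total = n_random + len(forced_edits)
    positions = _spread_mask_positions(n_total, tract_len, forced_pos, protected)
    forced_by_pos = dict(forced_edits)
    for attempt in range(20):
        sub = np.random.default_rng(rng.integers(0, 2**31))
        chars = list(tract)
        mask: list[int] = []
        ok = True
        taken = set(positions)
        for p in positions:
            if p in forced_by_pos:
                chars[p] = forced_by_pos[p]
                mask.append(p)
                continue
            placed = False
            # a position where every alternative base forms a forbidden motif
            # may be nudged sideways by up to 2 nt
            for delta in (0, 1, -1, 2, -2):
                q = p + delta
                if delta != 0 and (
                    q < 4 or q >= tract_len - 4 or q in taken or q in protected
                ):
                    continue
                for k in sub.permutation(4):
                    b = BASES[k]
                    if b == tract[q]:
                        continue
                    chars[q] = b
                    if _window_clean(chars, q, allowed_atg, allowed_stop):
                        mask.append(q)
                        placed = True
                        break
                    chars[q] = tract[q]
                if placed:
                    if q != p:
                        taken.discard(p)
                        taken.add(q)
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        seq = "".join(chars)
        if not _has_forbidden(seq, allowed_atg, allowed_stop):
            return seq, mask
    return None  # caller re-draws the tract
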