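"""In-silico 3'-RACE validation of predicted 5'-UTR poly(A) sites.

Each Sanger-style read is an adapter-primed 3'-RACE product in sense
orientation: transcript body followed by a poly(A) tail. Validation:

1. detect and trim the 3'-terminal poly(A) tail (tolerating rare base-call
   errors inside the homopolymer);
2. locally align the trimmed body to the candidate locus; the 3'-most aligned
   base is the observed cleavage position;
3. a cleavage call is an ``internal_mimic`` when the genomic sense strand
   immediately downstream carries a long adenine run (the "tail" was genomic),
   otherwise ``genuine``;
4. a predicted PAC is confirmed when at least one genuine call falls within a
   tolerance of its span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .genome_io import GenomeSequence, PipelineParams, has_a_run
from .pat_pac import PAC

logger = logging.getLogger("utrapa")

DEFAULT_MIN_TAIL = 10
DEFAULT_MIN_COVERAGE = 0.90
DEFAULT_MIN_IDENTITY = 0.95

STATUS_GENUINE = "genuine"
STATUS_MIMIC = "internal_mimic"
STATUS_NO_TAIL = "no_tail"
STATUS_UNALIGNED = "unaligned"


@dataclass(frozen=True)
class RaceRead:
    read_id: str
    sequence: str
    target_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class Locus:
    """Sense-oriented locus sequence (candidate gene +/- flanks) with its
    genomic anchor, so alignment coordinates map back to the genome."""

    chrom: str
    strand: str
    start: int  # 0-based genomic start of the locus on the reference
    sequence: str  # sense-strand sequence (revcomp of reference for '-')

    def genomic_position(self, sense_index: int) -> int:
        """1-based genomic coordinate of a 0-based sense-sequence index."""
        if self.strand == "+":
            return self.start + sense_index + 1
        return self.start + len(self.sequence) - sense_index


@dataclass
class CleavageCall:
    read_id: str
    status: str
    cleavage_position: Optional[int] = None  # 1-based genomic
    tail_length: int = 0
    matched_pac: Optional[PAC] = None
    chrom: Optional[str] = None
    strand: Optional[str] = None


def load_reads(fasta_path: str | Path) -> list[RaceRead]:
    """Read 3'-RACE reads from FASTA; a ``target=GENE`` token in the description
    assigns the read to a candidate locus."""
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        target = None
        for token in rec.description.split():
            if token.startswith("target="):
                target = token.split("=", 1)[1]
        reads.append(RaceRead(rec.id, str(rec.seq).upper(), target))
    return reads


# ---------------------------------------------------------------------------
# poly(A) tail detection
# ---------------------------------------------------------------------------


def detect_polya_tail(
    sequence: str, min_tail: int = DEFAULT_MIN_TAIL
) -> Optional[tuple[str, int]]:
    """Find the maximal 3'-terminal poly(A) tail; returns (body, tail_length).

    The tail is the longest suffix that starts with an A and carries at most
    one non-A per 10 tail bases, i.e. non-A positions are isolated at least
    10 nt apart (Sanger base-calls inside homopolymers are error-prone; an
    all-A rule would truncate real tails, while clustered non-A's mark the
    transcript body). Returns None when no qualifying suffix reaches
    ``min_tail``.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < min_tail:
        return None
    best = 0
    last_non_a = None  # offset from the 3' end of the most recent non-A
    for k in range(n):
        if seq[n - 1 - k] != "A":
            if last_non_a is not None and k - last_non_a < 10:
                break  # two non-A's within one 10-base window: body reached
            last_non_a = k
        else:
            best = k + 1  # suffix of this length starts with an A
    if best >= min_tail:
        return seq[: n - best], best
    return None


# ---------------------------------------------------------------------------
# body alignment
# ---------------------------------------------------------------------------


def make_aligner(
    match: float = 2, mismatch: float = -3, gap_open: float = -5, gap_extend: float = -2
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(alignment, seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(matches, columns, aligned_b_bases) for a local alignment of a vs b."""
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_b = 0
    columns = 0
    prev_a = prev_b = None
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            columns += (a_s - prev_a) + (b_s - prev_b)  # gap columns
        columns += a_e - a_s
        aligned_b += b_e - b_s
        for i, j in zip(range(a_s, a_e), range(b_s, b_e)):
            if seq_a[i] == seq_b[j]:
                matches += 1
        prev_a, prev_b = a_e, b_e
    return matches, columns, aligned_b


def align_body(
    body: str,
    locus: Locus,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[int]:
    """Local-align the trimmed read body to the locus sense sequence.

    Returns the 1-based genomic coordinate of the body's 3'-most aligned base
    (the observed cleavage position), or None when the alignment covers less
    than ``min_coverage`` of the body or falls below ``min_identity``.
    """
    if not body:
        return None
    aligner = aligner or make_aligner()
    alignments = aligner.align(locus.sequence, body)
    try:
        best = alignments[0]
    except IndexError:
        return None
    matches, columns, aligned_body = _alignment_stats(best, locus.sequence, body)
    if columns == 0:
        return None
    if aligned_body / len(body) < min_coverage or matches / columns < min_identity:
        return None
    locus_end = int(best.aligned[0][-1][1]) - 1  # last aligned locus index
    return locus.genomic_position(locus_end)


# ---------------------------------------------------------------------------
# cleavage classification
# ---------------------------------------------------------------------------


def classify_cleavage(
    cleavage_position: int,
    chrom: GenomeSequence,
    strand: str,
    params: PipelineParams,
) -> str:
    """'internal_mimic' iff the sense-strand genomic window immediately
    downstream of the cleavage position contains a >= ``a_run_threshold`` A-run
    (the apparent tail was templated by the genome, not added post-transcriptionally)."""
    w = params.a_scan_window_nt
    pos0 = cleavage_position - 1
    if strand == "+":
        window = chrom.fetch(pos0 + 1, pos0 + 1 + w, "+")
    else:
        window = chrom.fetch(pos0 - w, pos0, "-")
    return STATUS_MIMIC if has_a_run(window, params.a_run_threshold) else STATUS_GENUINE


def validate_read(
    read: RaceRead,
    locus: Locus,
    genome: dict[str, GenomeSequence],
    params: Optional[PipelineParams] = None,
    min_tail: int = DEFAULT_MIN_TAIL,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> CleavageCall:
    """Tail-trim, align and classify one 3'-RACE read against its locus."""
    params = params or PipelineParams()
    tail = detect_polya_tail(read.sequence, min_tail)
    if tail is None:
        return CleavageCall(read.read_id, STATUS_NO_TAIL)
    body, tail_len = tail
    pos = align_body(body, locus, aligner=aligner)
    if pos is None:
        return CleavageCall(read.read_id, STATUS_UNALIGNED, tail_length=tail_len)
    status = classify_cleavage(pos, genome[locus.chrom], locus.strand, params)
    return CleavageCall(
        read.read_id,
        status,
        cleavage_position=pos,
        tail_length=tail_len,
        chrom=locus.chrom,
        strand=locus.strand,
    )


def validate_reads(
    reads: Iterable[RaceRead],
    loci: dict[str, Locus],
    genome: dict[str, GenomeSequence],
    params: Optional[PipelineParams] = None,
    min_tail: int = DEFAULT_MIN_TAIL,
) -> list[CleavageCall]:
    """Validate reads against their per-read target loci (``target_gene``)."""
    aligner = make_aligner()
    calls = []
    for read in reads:
        locus = loci.get(read.target_gene) if read.target_gene else None
        if locus is None:
            calls.append(CleavageCall(read.read_id, STATUS_UNALIGNED))
            continue
        calls.append(validate_read(read, locus, genome, params, min_tail, aligner))
    return calls


# ---------------------------------------------------------------------------
# PAC confirmation
# ---------------------------------------------------------------------------


def confirm_pacs(
    calls: Sequence[CleavageCall],
    predicted_pacs: Sequence[PAC],
    tolerance: Optional[int] = None,
    params: Optional[PipelineParams] = None,
) -> pd.DataFrame:
    """Per-PAC confirmation table: a PAC is confirmed iff >= 1 genuine call lies
    within ``tolerance`` nt (default: the cluster gap) of its span."""
    if tolerance is None:
        tolerance = (params or PipelineParams()).cluster_gap_nt
    rows = []
    for pac in predicted_pacs:
        n_genuine = n_mimic = 0
        for call in calls:
            if call.cleavage_position is None:
                continue
            if call.chrom is not None and call.chrom != pac.chrom:
                continue
            if call.strand is not None and call.strand != pac.strand:
                continue
            near = pac.start - tolerance <= call.cleavage_position <= pac.end + tolerance
            if not near:
                continue
            if call.status == STATUS_GENUINE:
                n_genuine += 1
            elif call.status == STATUS_MIMIC:
                n_mimic += 1
        rows.append(
            {
                "gene": pac.gene_id or ".",
                "location": pac.chrom,
                "start": pac.start,
                "end": pac.end,
                "pac": pac.representative_position,
                "n_genuine": n_genuine,
                "n_mimic": n_mimic,
                "verdict": "confirmed" if n_genuine >= 1 else "unconfirmed",
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[CleavageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "status": c.status,
                "chrom": c.chrom or ".",
                "strand": c.strand or ".",
                "cleavage_position": c.cleavage_position or 0,
                "tail_length": c.tail_length,
            }
            for c in calls
        ]
    )
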