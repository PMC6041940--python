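"""uORF discovery and the exon-shuffling self-duplication analysis.

A 5'-UTR that harbours its own polyadenylated transcript may have arisen by
duplication of the downstream major ORF's 5' end into the UTR. The scan:

* finds all ATG-initiated ORFs (uORFs) in the spliced 5'-UTR, in all three
  reading frames;
* locally aligns the 5'-UTR against the 5' end of its own mORF and reports
  percent identity over the aligned region (gap columns included in the
  denominator);
* reads, through the alignment trace, the mORF codons opposite each uORF stop
  codon, exposing the substitutions that created the new stops (e.g. TAC->TAA,
  TGA->TAA);
* checks whether an annotated intron sits at the 3' margin of the duplicated
  tract — the signature expected if the duplicate was installed by
  exon shuffling (misalignment + recombination within flanking introns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .genome_io import TranscriptModel
from .race_validate import make_aligner

STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MORF_WINDOW = 600
DEFAULT_MIN_ALIGN_COLUMNS = 50
DEFAULT_MIN_IDENTITY_PCT = 40.0
DEFAULT_INTRON_TOLERANCE = 30


@dataclass
class UorfRecord:
    transcript_id: str
    start: int  # 1-based, inclusive, transcript coordinates
    end: int  # 1-based, inclusive; includes the stop codon when has_stop
    frame: int  # 1..3 relative to transcript position 1
    peptide: str
    has_stop: bool


@dataclass
class StopSubstitution:
    morf_codon: Optional[str]  # None when the codon spans an alignment gap
    uorf_codon: str
    uorf_stop_position: int  # 1-based UTR coordinate of the stop codon start

    @property
    def indeterminate(self) -> bool:
        return self.morf_codon is None


@dataclass
class DuplicationReport:
    utr_interval: tuple[int, int]  # 1-based inclusive, spliced 5'-UTR coords
    morf_interval: tuple[int, int]  # 1-based inclusive, mORF coords
    percent_identity: float  # matches / all columns (gaps included) * 100
    n_columns: int
    n_matches: int
    trace: list[tuple[Optional[int], Optional[int]]]  # 0-based (utr, morf) pairs
    stop_substitutions: list[StopSubstitution] = field(default_factory=list)
    intron_at_margin: Optional[bool] = None
    intron_distance: float = math.inf


# ---------------------------------------------------------------------------
# uORF discovery
# ---------------------------------------------------------------------------


def find_uorfs(
    five_utr_sequence: str,
    min_peptide_len: int = 2,
    transcript_id: str = ".",
) -> list[UorfRecord]:
    """All ATG-initiated ORFs in the spliced 5'-UTR, in all three frames.

    An ORF runs from its ATG to the first in-frame stop codon (``has_stop``);
    ORFs still open at the sequence end are reported with ``has_stop=False``.
    Peptides shorter than ``min_peptide_len`` are discarded.
    """
    seq = five_utr_sequence.upper()
    n = len(seq)
    out: list[UorfRecord] = []
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        for codon_start in range(start + 3, n - 2, 3):
            if seq[codon_start : codon_start + 3] in STOP_CODONS:
                end = codon_start + 3
                break
        has_stop = end is not None
        if not has_stop:
            end = start + 3 * ((n - start) // 3)
        coding = seq[start : end - 3] if has_stop else seq[start:end]
        peptide = str(Seq(coding).translate())
        if len(peptide) < min_peptide_len:
            continue
        out.append(
            UorfRecord(
                transcript_id=transcript_id,
                start=start + 1,
                end=end,
                frame=start % 3 + 1,
                peptide=peptide,
                has_stop=has_stop,
            )
        )
    return out


def frame_usage(records: Sequence[UorfRecord]) -> dict:
    """Frame of each ORF and whether any pair uses distinct reading frames."""
    frames = [r.frame for r in records]
    return {
        "frames": frames,
        "distinct_frames": len(set(frames)) > 1,
    }


# ---------------------------------------------------------------------------
# self-duplication scan
# ---------------------------------------------------------------------------


def _alignment_trace(alignment) -> list[tuple[Optional[int], Optional[int]]]:
    blocks_a, blocks_b = alignment.aligned
    trace: list[tuple[Optional[int], Optional[int]]] = []
    prev_a = prev_b = None
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            for i in range(prev_a, a_s):
                trace.append((int(i), None))
            for j in range(prev_b, b_s):
                trace.append((None, int(j)))
        for i, j in zip(range(a_s, a_e), range(b_s, b_e)):
            trace.append((int(i), int(j)))
        prev_a, prev_b = a_e, b_e
    return trace


def self_duplication_scan(
    five_utr_sequence: str,
    morf_sequence: str,
    window_5prime: int = DEFAULT_MORF_WINDOW,
    min_columns: int = DEFAULT_MIN_ALIGN_COLUMNS,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    match: float = 2,
    mismatch: float = -3,
    gap_open: float = -5,
    gap_extend: float = -2,
) -> Optional[DuplicationReport]:
    """Best local alignment of a gene's 5'-UTR against its own mORF 5' end.

    Percent identity is matched columns over all alignment columns, gap columns
    included. A report is returned only when the alignment spans at least
    ``min_columns`` columns at ``min_identity_pct`` identity or better.
    """
    utr = five_utr_sequence.upper()
    morf = morf_sequence.upper()[:window_5prime]
    if len(utr) < min_columns or len(morf) < min_columns:
        return None
    aligner = make_aligner(match, mismatch, gap_open, gap_extend)
    alignments = aligner.align(utr, morf)
    try:
        best = alignments[0]
    except IndexError:
        return None
    trace = _alignment_trace(best)
    if not trace:
        return None
    matches = sum(
        1
        for u, m in trace
        if u is not None and m is not None and utr[u] == morf[m]
    )
    columns = len(trace)
    identity = 100.0 * matches / columns
    if columns < min_columns or identity < min_identity_pct:
        return None
    utr_pos = [u for u, _ in trace if u is not None]
    morf_pos = [m for _, m in trace if m is not None]
    return DuplicationReport(
        utr_interval=(utr_pos[0] + 1, utr_pos[-1] + 1),
        morf_interval=(morf_pos[0] + 1, morf_pos[-1] + 1),
        percent_identity=identity,
        n_columns=columns,
        n_matches=matches,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# stop-codon origin
# ---------------------------------------------------------------------------


def stop_codon_origin(
    report: DuplicationReport,
    uorfs: Sequence[UorfRecord],
    five_utr_sequence: str,
    morf_sequence: str,
) -> list[StopSubstitution]:
    """Substitutions that created uORF stop codons, read through the alignment.

    For each uORF stop codon lying inside the aligned region, the three mORF
    bases aligned to the codon's columns are read back; a differing mORF codon
    is a stop-creating substitution. Codons interrupted by an alignment gap are
    reported as indeterminate. The report's list is also updated in place.
    """
    utr = five_utr_sequence.upper()
    morf = morf_sequence.upper()
    utr_to_morf = {u: m for u, m in report.trace if u is not None}
    subs: list[StopSubstitution] = []
    seen: set[int] = set()
    for uorf in uorfs:
        if not uorf.has_stop:
            continue
        stop_start0 = uorf.end - 3  # 0-based UTR index of stop codon start
        if stop_start0 in seen:
            continue  # several uORFs can share one stop codon
        codon_idx = [stop_start0, stop_start0 + 1, stop_start0 + 2]
        if not all(i in utr_to_morf for i in codon_idx):
            if any(i in utr_to_morf for i in codon_idx):
                seen.add(stop_start0)
                subs.append(
                    StopSubstitution(None, utr[stop_start0 : stop_start0 + 3], stop_start0 + 1)
                )
            continue  # stop codon entirely outside the aligned region
        seen.add(stop_start0)
        morf_idx = [utr_to_morf[i] for i in codon_idx]
        if morf_idx[1] != morf_idx[0] + 1 or morf_idx[2] != morf_idx[1] + 1:
            subs.append(
                StopSubstitution(None, utr[stop_start0 : stop_start0 + 3], stop_start0 + 1)
            )
            continue
        morf_codon = morf[morf_idx[0] : morf_idx[0] + 3]
        uorf_codon = utr[stop_start0 : stop_start0 + 3]
        if morf_codon != uorf_codon:
            subs.append(StopSubstitution(morf_codon, uorf_codon, stop_start0 + 1))
    report.stop_substitutions = subs
    return subs


# ---------------------------------------------------------------------------
# intron-at-margin check
# ---------------------------------------------------------------------------


def intron_margin_check(
    report: DuplicationReport,
    transcript: TranscriptModel,
    tolerance_nt: int = DEFAULT_INTRON_TOLERANCE,
) -> tuple[bool, float]:
    """Exon-shuffling signature: an annotated intron boundary within
    ``tolerance_nt`` of the duplicated tract's 3' genomic end.

    The tract's 3' end (spliced 5'-UTR coordinate, which equals the transcript
    coordinate since the 5'-UTR opens the transcript) is mapped to the genome
    through the exon structure. Intronless genes yield (False, inf).
    """
    introns = transcript.introns
    if not introns:
        report.intron_at_margin = False
        report.intron_distance = math.inf
        return False, math.inf
    tract_end_t = report.utr_interval[1] - 1  # 0-based transcript coordinate
    g = transcript.transcript_to_genomic(tract_end_t)  # 0-based genomic
    distance = min(
        min(abs(g - (s - 1)), abs(g - s), abs(g - (e - 1)), abs(g - e))
        for s, e in introns
    )
    flag = distance <= tolerance_nt
    report.intron_at_margin = flag
    report.intron_distance = float(distance)
    return flag, float(distance)


# ---------------------------------------------------------------------------
# human-readable alignment
# ---------------------------------------------------------------------------


def format_alignment_text(
    report: DuplicationReport,
    five_utr_sequence: str,
    morf_sequence: str,
    width: int = 60,
) -> str:
    """Pairwise alignment with vertical bars marking matches."""
    utr = five_utr_sequence.upper()
    morf = morf_sequence.upper()
    top = mid = bot = ""
    for u, m in report.trace:
        a = utr[u] if u is not None else "-"
        b = morf[m] if m is not None else "-"
        top += a
        bot += b
        mid += "|" if (u is not None and m is not None and a == b) else " "
    lines = [
        f"5'-UTR {report.utr_interval[0]}..{report.utr_interval[1]} vs "
        f"mORF {report.morf_interval[0]}..{report.morf_interval[1]} "
        f"({report.percent_identity:.1f}% identity over {report.n_columns} columns)"
    ]
    for i in range(0, len(top), width):
        lines.append("UTR  " + top[i : i + width])
        lines.append("     " + mid[i : i + width])
        lines.append("mORF " + bot[i : i + width])
        lines.append("")
    return "\n".join(lines)
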