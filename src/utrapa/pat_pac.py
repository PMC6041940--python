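"""Poly(A)-site calling, internal-priming filtering, PAC clustering, classification.

PAT-seq 3'-end tags mark candidate cleavage positions. The pipeline:

1. aggregate tags per (chrom, position, strand) and keep positions with
   >= ``min_pat_reads`` supporting tags;
2. drop sites whose surrounding sense-strand genomic window contains a run of
   >= ``a_run_threshold`` adenines (internal-priming artifacts: oligo-dT can
   anneal on a genomic A-tract instead of a real tail);
3. single-linkage cluster the survivors into PACs, joining sites connected by
   gaps <= ``cluster_gap_nt`` (cleavage microheterogeneity);
4. classify each PAC by its position in the longest transcript of the
   overlapping gene (5'-UTR exon/intron, CDS exon/intron, 3'-UTR, downstream
   extension, antisense, intergenic).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeSequence,
    PipelineParams,
    TranscriptModel,
    extend_three_prime,
    has_a_run,
    longest_transcript,
)

logger = logging.getLogger("utrapa")

#: every PAC receives exactly one of these labels
REGION_LABELS = (
    "UTR",
    "UTR_intron",
    "CDS",
    "CDS_intron",
    "3UTR",
    "extended_3UTR",
    "antisense",
    "intergenic",
)

FIVE_UTR_REGIONS = ("UTR", "UTR_intron")


@dataclass(frozen=True)
class PolyASite:
    chrom: str
    strand: str
    position: int  # 1-based cleavage coordinate
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.position < 1:
            raise ValueError("position must be 1-based")


@dataclass
class PAC:
    """A cluster of nearby poly(A) sites treated as one polyadenylation event."""

    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    representative_position: int
    expression: int
    member_sites: list[PolyASite] = field(default_factory=list)
    gene_id: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start <= self.representative_position <= self.end:
            raise ValueError("representative position outside PAC span")


@dataclass
class PacCatalog:
    pacs: list[PAC]

    @property
    def strand_counts(self) -> Counter:
        return Counter(p.strand for p in self.pacs)

    @property
    def region_counts(self) -> Counter:
        return Counter(p.region for p in self.pacs)

    def five_utr_partition(self) -> tuple[int, int, int]:
        """(exon-located, intron-located, total) sense 5'-UTR PAC counts."""
        exon = sum(1 for p in self.pacs if p.region == "UTR")
        intron = sum(1 for p in self.pacs if p.region == "UTR_intron")
        return exon, intron, exon + intron

    def __len__(self) -> int:
        return len(self.pacs)

    def __iter__(self):
        return iter(self.pacs)


# ---------------------------------------------------------------------------
# tag tables
# ---------------------------------------------------------------------------


def read_tag_table(path: str | Path) -> pd.DataFrame:
    """Read a tag table TSV with columns chrom, position, strand[, count]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"tag table must have columns {sorted(required)}")
    if "count" not in df.columns:
        df["count"] = 1
    return df


def read_tag_bed(path: str | Path) -> pd.DataFrame:
    """Read per-tag BED6; the cleavage position is the 3'-most base of each tag."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    position = bed["end"].where(bed["strand"] == "+", bed["start"] + 1)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "position": position,
            "strand": bed["strand"],
            "count": 1,
        }
    )


def call_sites(
    tags: pd.DataFrame,
    params: PipelineParams,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[PolyASite]:
    """Aggregate tags per position and keep sites with >= ``min_pat_reads`` tags.

    Rows whose position falls outside the chromosome are rejected with a warning.
    """
    df = tags.copy()
    if "count" not in df.columns:
        df["count"] = 1
    if chrom_lengths is not None:
        limits = df["chrom"].map(chrom_lengths)
        ok = (df["position"] >= 1) & (df["position"] <= limits)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("rejected %d tag rows outside chromosome bounds", n_bad)
            df = df[ok]
    grouped = (
        df.groupby(["chrom", "strand", "position"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    grouped = grouped[grouped["count"] >= params.min_pat_reads]
    return [
        PolyASite(r.chrom, r.strand, int(r.position), int(r["count"]))
        for _, r in grouped.iterrows()
    ]


# ---------------------------------------------------------------------------
# internal-priming filter
# ---------------------------------------------------------------------------


def sense_window(
    site: PolyASite, genome: dict[str, GenomeSequence], params: PipelineParams
) -> str:
    """Gene-sense genomic sequence in the scan window around the cleavage site."""
    chrom = genome[site.chrom]
    w = params.a_scan_window_nt
    pos0 = site.position - 1
    return chrom.fetch(pos0 - w, pos0 + w + 1, site.strand)


def internal_priming_filter(
    site: PolyASite, genome: dict[str, GenomeSequence], params: PipelineParams
) -> bool:
    """True = keep the site; False = drop it as a likely internal-priming artifact."""
    return not has_a_run(sense_window(site, genome, params), params.a_run_threshold)


def filter_sites(
    sites: Iterable[PolyASite],
    genome: dict[str, GenomeSequence],
    params: PipelineParams,
) -> list[PolyASite]:
    return [s for s in sites if internal_priming_filter(s, genome, params)]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _representative(sites: Sequence[PolyASite], strand: str) -> PolyASite:
    # highest read count; ties go to the most 3'-distal site in the
    # transcription direction (largest position on +, smallest on -)
    if strand == "+":
        return max(sites, key=lambda s: (s.read_count, s.position))
    return max(sites, key=lambda s: (s.read_count, -s.position))


def cluster_pacs(sites: Sequence[PolyASite], params: PipelineParams) -> list[PAC]:
    """Single-linkage clustering of sites within ``cluster_gap_nt`` per (chrom, strand)."""
    by_group: dict[tuple[str, str], list[PolyASite]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    pacs: list[PAC] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group = sorted(group, key=lambda s: s.position)
        cluster: list[PolyASite] = []
        for site in group:
            if cluster and site.position - cluster[-1].position > params.cluster_gap_nt:
                pacs.append(_finish_cluster(cluster, chrom, strand))
                cluster = []
            cluster.append(site)
        if cluster:
            pacs.append(_finish_cluster(cluster, chrom, strand))
    return pacs


def _finish_cluster(cluster: list[PolyASite], chrom: str, strand: str) -> PAC:
    rep = _representative(cluster, strand)
    return PAC(
        chrom=chrom,
        strand=strand,
        start=cluster[0].position,
        end=cluster[-1].position,
        representative_position=rep.position,
        expression=sum(s.read_count for s in cluster),
        member_sites=list(cluster),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _region_in_transcript(
    pos0: int, transcript: TranscriptModel, extension: tuple[int, int]
) -> Optional[str]:
    """Region label for a 0-based position relative to one (sense) transcript."""
    for s, e in transcript.five_utr_intervals:
        if s <= pos0 < e:
            return "UTR"
    for s, e in transcript.cds_intervals:
        if s <= pos0 < e:
            return "CDS"
    for s, e in transcript.three_utr_intervals:
        if s <= pos0 < e:
            return "3UTR"
    for intron in transcript.introns:
        s, e = intron
        if s <= pos0 < e:
            reg = transcript.intron_region(intron)
            if reg == "5UTR":
                return "UTR_intron"
            if reg == "CDS":
                return "CDS_intron"
            return "3UTR"
    s, e = extension
    if s <= pos0 < e:
        return "extended_3UTR"
    if transcript.cds_span is None:
        ts, te = transcript.span
        if ts <= pos0 < te:
            return "CDS"  # no CDS annotated: treat transcript body as coding-like
    return None


def classify_pac(
    pac: PAC,
    gene_models: Sequence[GeneModel],
    genome: dict[str, GenomeSequence],
    params: PipelineParams,
) -> PAC:
    """Assign region label and gene to a PAC using each gene's longest transcript.

    Sense assignment requires matching strand. When several sense genes overlap,
    preference goes to the gene whose 5'-UTR contains the site, then to the gene
    with the smallest distance from the site to its transcription start.
    """
    pos0 = pac.representative_position - 1
    chrom_len = len(genome[pac.chrom]) if pac.chrom in genome else None
    sense_hits: list[tuple[int, int, str, str]] = []  # (priority, dist, gene, region)
    antisense = False
    for gene in gene_models:
        if gene.chrom != pac.chrom or gene.is_organellar:
            continue
        t = longest_transcript(gene)
        clen = chrom_len if chrom_len is not None else t.span[1] + params.three_prime_extension_nt
        ext = extend_three_prime(t, params, clen)
        lo = min(t.span[0], ext[0])
        hi = max(t.span[1], ext[1])
        if not lo <= pos0 < hi:
            continue
        if gene.strand == pac.strand:
            region = _region_in_transcript(pos0, t, ext)
            if region is not None:
                in_utr = region in FIVE_UTR_REGIONS
                dist = abs(pos0 - gene.tss)
                sense_hits.append((0 if in_utr else 1, dist, gene.gene_id, region))
        else:
            if t.span[0] <= pos0 < t.span[1]:
                antisense = True
    if sense_hits:
        sense_hits.sort()
        _, _, gene_id, region = sense_hits[0]
        pac.gene_id = gene_id
        pac.region = region
    elif antisense:
        pac.gene_id = None
        pac.region = "antisense"
    else:
        pac.gene_id = None
        pac.region = "intergenic"
    return pac


def classify_catalog(
    pacs: Iterable[PAC],
    gene_models: Sequence[GeneModel],
    genome: dict[str, GenomeSequence],
    params: PipelineParams,
) -> PacCatalog:
    return PacCatalog([classify_pac(p, gene_models, genome, params) for p in pacs])


def call_pacs(
    tags: pd.DataFrame,
    genome: dict[str, GenomeSequence],
    gene_models: Sequence[GeneModel],
    params: PipelineParams | None = None,
) -> PacCatalog:
    """Full tag-table -> classified PAC catalog pipeline."""
    params = params or PipelineParams()
    chrom_lengths = {c: len(g) for c, g in genome.items()}
    sites = call_sites(tags, params, chrom_lengths)
    kept = filter_sites(sites, genome, params)
    logger.info(
        "called %d sites (%d dropped as internal priming)",
        len(kept),
        len(sites) - len(kept),
    )
    pacs = cluster_pacs(kept, params)
    return classify_catalog(pacs, gene_models, genome, params)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def catalog_to_frame(catalog: PacCatalog) -> pd.DataFrame:
    """PAC catalog in the confirmed-PAC table column layout."""
    rows = []
    for p in catalog:
        rows.append(
            {
                "location": p.chrom,
                "start": p.start,
                "end": p.end,
                "pac": p.representative_position,
                "expression": p.expression,
                "gene": p.gene_id or ".",
                "region": p.region or ".",
                "strand": p.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "location",
            "start",
            "end",
            "pac",
            "expression",
            "gene",
            "region",
            "strand",
        ],
    )


def write_pac_table(catalog: PacCatalog, path: str | Path) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def write_pac_bed(catalog: PacCatalog, path: str | Path) -> None:
    """BED6+ export: name=gene, score=expression, extra columns rep/region."""
    with open(path, "w") as fh:
        for p in catalog:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start - 1),
                        str(p.end),
                        p.gene_id or ".",
                        str(p.expression),
                        p.strand,
                        str(p.representative_position),
                        p.region or ".",
                    ]
                )
                + "\n"
            )
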