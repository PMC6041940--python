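"""Candidate-gene selection for experimental verification of 5'-UTR PACs.

From a classified PAC catalog, keep sense PACs located in 5'-UTR exons or
introns, drop genes flanked by a same-strand upstream neighbour (whose 3'-UTR
poly(A) site could masquerade as a 5'-UTR site of the candidate), and rank the
survivors for verification, primarily by expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .genome_io import GeneModel, longest_transcript
from .pat_pac import FIVE_UTR_REGIONS, PAC, PacCatalog

#: default maximum distance (nt) at which an upstream neighbour is "flanking"
DEFAULT_MAX_UPSTREAM_DISTANCE = 2000


@dataclass
class CandidateRecord:
    pac: PAC
    gene_id: str
    five_utr_length: int
    distance_to_upstream_gene: float  # nt, math.inf when no neighbour in range
    upstream_neighbor_strand: Optional[str]  # None when no neighbour in range

    @property
    def rank_key(self) -> tuple:
        # descending expression, then farther upstream neighbour, then longer
        # 5'-UTR; gene id last for a deterministic total order
        return (
            -self.pac.expression,
            -self.distance_to_upstream_gene,
            -self.five_utr_length,
            self.gene_id,
        )


def extract_5utr_sense(catalog: PacCatalog) -> list[PAC]:
    """Sense-orientation PACs in 5'-UTR exons or introns (classification is
    sense-only for these labels, antisense hits carry the 'antisense' label)."""
    return [p for p in catalog if p.region in FIVE_UTR_REGIONS]


def nearest_upstream_gene(
    gene: GeneModel, gene_models: Sequence[GeneModel]
) -> tuple[Optional[GeneModel], float]:
    """Nearest non-overlapping gene on the 5' side of ``gene``'s transcription start.

    Returns (neighbour, gap in nt); (None, inf) when no gene lies upstream.
    """
    gs, ge = gene.span
    best: Optional[GeneModel] = None
    best_gap = math.inf
    for other in gene_models:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        os, oe = other.span
        if gene.strand == "+":
            gap = gs - oe
        else:
            gap = os - ge
        if gap >= 0 and gap < best_gap:
            best, best_gap = other, gap
    return best, best_gap


def upstream_neighbor_filter(
    gene: GeneModel,
    gene_models: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_UPSTREAM_DISTANCE,
) -> bool:
    """True = retain the candidate gene; False = exclude it.

    A gene is excluded iff its nearest upstream neighbour within ``max_distance``
    is transcribed on the same strand (a short transcript could then come from
    that neighbour's 3' end instead of the candidate's 5'-UTR). A convergent
    (opposite-strand) upstream neighbour retains the candidate.
    """
    neighbor, gap = nearest_upstream_gene(gene, gene_models)
    if neighbor is None or gap > max_distance:
        return True
    return neighbor.strand != gene.strand


def build_candidates(
    catalog: PacCatalog,
    gene_models: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_UPSTREAM_DISTANCE,
) -> list[CandidateRecord]:
    """Apply the 5'-UTR sense filter and the upstream-neighbour exclusion."""
    by_id = {g.gene_id: g for g in gene_models}
    records: list[CandidateRecord] = []
    for pac in extract_5utr_sense(catalog):
        gene = by_id.get(pac.gene_id)
        if gene is None:
            continue
        if not upstream_neighbor_filter(gene, gene_models, max_distance):
            continue
        neighbor, gap = nearest_upstream_gene(gene, gene_models)
        in_range = neighbor is not None and gap <= max_distance
        t = longest_transcript(gene)
        utr_len = sum(e - s for s, e in t.five_utr_intervals)
        records.append(
            CandidateRecord(
                pac=pac,
                gene_id=gene.gene_id,
                five_utr_length=utr_len,
                distance_to_upstream_gene=gap if in_range else math.inf,
                upstream_neighbor_strand=neighbor.strand if in_range else None,
            )
        )
    return records


def rank_candidates(candidates: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Deterministic verification order: expression first, then tie-breaks."""
    return sorted(candidates, key=lambda c: c.rank_key)


def candidates_to_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "location": c.pac.chrom,
                "start": c.pac.start,
                "end": c.pac.end,
                "pac": c.pac.representative_position,
                "expression": c.pac.expression,
                "gene": c.gene_id,
                "region": c.pac.region,
                "strand": c.pac.strand,
                "five_utr_length": c.five_utr_length,
                "distance_to_upstream_gene": c.distance_to_upstream_gene,
                "upstream_neighbor_strand": c.upstream_neighbor_strand or ".",
            }
        )
    return pd.DataFrame(rows)


def write_candidates(
    candidates: Sequence[CandidateRecord], path: str | Path, top_n: Optional[int] = None
) -> None:
    ranked = rank_candidates(candidates)
    if top_n is not None:
        ranked = ranked[:top_n]
    candidates_to_frame(ranked).to_csv(path, sep="\t", index=False)
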