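"""Site calling, internal-priming filtering, PAC clustering and classification."""

import re
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from utrapa import (
    GenomeSequence,
    PipelineParams,
    PolyASite,
    call_sites,
    cluster_pacs,
    internal_priming_filter,
    call_pacs,
)
from utrapa.pat_pac import classify_pac, sense_window
from utrapa.synthetic_data import simulate_pat_tags, split_cluster_sites
from utrapa.genome_io import longest_transcript, reverse_complement


def _tags(rows):
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand"])
    df["count"] = 1
    return df


class TestCallSites:
    def test_min_read_threshold_boundary(self, params):
        tags = _tags([("c", 100, "+")] * 3 + [("c", 200, "+")] * 2)
        sites = call_sites(tags, params)
        assert [(s.position, s.read_count) for s in sites] == [(100, 3)]

    def test_aggregation_matches_brute_force_tally(self, params):
        rng = np.random.default_rng(0)
        positions = rng.integers(1, 11, size=100)  # 100 reads over 10 positions
        tags = _tags([("c", int(p), "+") for p in positions])
        expected = Counter(int(p) for p in positions)
        sites = call_sites(tags, PipelineParams(min_pat_reads=1))
        assert {s.position: s.read_count for s in sites} == dict(expected)

    def test_out_of_bounds_rows_rejected(self, params):
        tags = _tags([("c", 5, "+")] * 3 + [("c", 99, "+")] * 3)
        sites = call_sites(tags, params, chrom_lengths={"c": 50})
        assert [s.position for s in sites] == [5]


class TestInternalPrimingFilter:
    def _site_genome(self, window_seq):
        # place the window so the site sits mid-sequence
        seq = "CGCG" * 10 + window_seq + "CGCG" * 10
        pos = 40 + len(window_seq) // 2 + 1  # 1-based center of window
        genome = {"c": GenomeSequence("c", seq)}
        return PolyASite("c", "+", pos, 5), genome

    def test_run_of_eight_drops_site(self, params):
        site, genome = self._site_genome("CCCCAAAAAAAACCCC")
        assert internal_priming_filter(site, genome, params) is False

    def test_run_of_seven_keeps_site(self, params):
        site, genome = self._site_genome("CCCCAAAAAAACCCCC")
        assert internal_priming_filter(site, genome, params) is True

    def test_agrees_with_regex_oracle_on_random_windows(self, params):
        rng = np.random.default_rng(42)
        # sprinkle genuine A-tracts into random sequence
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        seq = seq[:5000] + "A" * 9 + seq[5000:]
        genome = {"c": GenomeSequence("c", seq)}
        for _ in range(300):
            pos = int(rng.integers(1, len(seq) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = PolyASite("c", strand, pos, 3)
            window = sense_window(site, genome, params)
            oracle_keep = re.search("A{8,}", window) is None
            assert internal_priming_filter(site, genome, params) == oracle_keep

    def test_minus_strand_scans_sense_sequence(self, params):
        # genomic T-tract = sense A-tract for a minus-strand site
        seq = "CGCG" * 10 + "TTTTTTTTTT" + "CGCG" * 10
        genome = {"c": GenomeSequence("c", seq)}
        site_minus = PolyASite("c", "-", 45, 5)
        site_plus = PolyASite("c", "+", 45, 5)
        assert internal_priming_filter(site_minus, genome, params) is False
        assert internal_priming_filter(site_plus, genome, params) is True


def _brute_force_clusters(positions, gap):
    """Transitive closure of the <= gap relation on sorted positions."""
    clusters, current = [], []
    for p in sorted(positions):
        if current and p - current[-1] > gap:
            clusters.append(current)
            current = []
        current.append(p)
    if current:
        clusters.append(current)
    return clusters


class TestClusterPacs:
    def test_empty_input(self, params):
        assert cluster_pacs([], params) == []

    def test_documented_example(self, params):
        sites = [
            PolyASite("c", "+", 100, 5),
            PolyASite("c", "+", 110, 3),
            PolyASite("c", "+", 160, 4),
        ]
        pacs = cluster_pacs(sites, params)
        assert [(p.start, p.end, p.representative_position, p.expression) for p in pacs] == [
            (100, 110, 100, 8),
            (160, 160, 160, 4),
        ]

    def test_matches_brute_force_transitive_closure(self, params):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            positions = sorted(set(int(p) for p in rng.integers(1, 2000, size=n)))
            sites = [PolyASite("c", "+", p, int(rng.integers(1, 20))) for p in positions]
            pacs = cluster_pacs(sites, params)
            expected = _brute_force_clusters(positions, params.cluster_gap_nt)
            assert [[s.position for s in p.member_sites] for p in pacs] == expected
            for pac in pacs:
                assert pac.start <= pac.representative_position <= pac.end
                assert pac.expression == sum(s.read_count for s in pac.member_sites)

    def test_gap_boundary_24_vs_25(self, params):
        at_gap = split_cluster_sites("c", "+", 100, gap=24)
        past_gap = split_cluster_sites("c", "+", 100, gap=25)
        one = cluster_pacs(call_sites(at_gap, params), params)
        two = cluster_pacs(call_sites(past_gap, params), params)
        assert len(one) == 1 and len(two) == 2

    @pytest.mark.parametrize("strand,expected", [("+", 110), ("-", 100)])
    def test_representative_tie_breaks_three_prime_distal(self, params, strand, expected):
        sites = [PolyASite("c", strand, 100, 5), PolyASite("c", strand, 110, 5)]
        (pac,) = cluster_pacs(sites, params)
        assert pac.representative_position == expected


class TestClassification:
    def test_planted_regions_recovered(self, world, params):
        tags = simulate_pat_tags(world, depth_per_pac=50, contamination_rate=0.0, seed=5)
        catalog = call_pacs(tags, world.genome, world.genes, params)
        truth = {
            (p.chrom, p.strand, p.region): 1 for p in world.truth.planted_pacs
        }
        assert len(catalog) == len(world.truth.planted_pacs)
        by_gene_truth = {p.gene_id: p.region for p in world.truth.planted_pacs}
        for pac in catalog:
            assert pac.region == by_gene_truth[pac.gene_id]

    def test_extension_boundary_120_vs_121(self, world, params):
        gene = next(g for g in world.genes if g.strand == "+" and not g.gene_id.endswith("N"))
        t = longest_transcript(gene)
        end = t.span[1]  # 0-based exclusive = last base 1-based
        inside = PolyASite(gene.chrom, "+", end + 120, 5)
        outside = PolyASite(gene.chrom, "+", end + 121, 5)

        def region_of(site):
            pac = cluster_pacs([site], params)[0]
            return classify_pac(pac, [gene], world.genome, params).region

        assert region_of(inside) == "extended_3UTR"
        assert region_of(outside) == "intergenic"

    def test_antisense_and_sense_labels(self, world, params):
        gene = next(g for g in world.genes if g.strand == "+" and not g.gene_id.endswith("N"))
        t = longest_transcript(gene)
        cds_mid = (t.cds_intervals[0][0] + t.cds_intervals[0][1]) // 2
        sense = PolyASite(gene.chrom, "+", cds_mid + 1, 5)
        anti = PolyASite(gene.chrom, "-", cds_mid + 1, 5)

        def classify(site):
            pac = cluster_pacs([site], params)[0]
            return classify_pac(pac, [gene], world.genome, params)

        assert classify(sense).region == "CDS"
        assert classify(sense).gene_id == gene.gene_id
        assert classify(anti).region == "antisense"

    def test_catalog_partition_invariants(self, world, params):
        tags = simulate_pat_tags(world, depth_per_pac=50, contamination_rate=0.1, seed=6)
        catalog = call_pacs(tags, world.genome, world.genes, params)
        counts = catalog.strand_counts
        assert counts["+"] + counts["-"] == len(catalog)
        exon, intron, total = catalog.five_utr_partition()
        assert exon + intron == total
        assert all(p.region is not None for p in catalog)
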