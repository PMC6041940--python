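"""Determinism, ground-truth bookkeeping and constraints of the simulators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from utrapa import (
    LayoutSpec,
    PipelineParams,
    has_a_run,
    make_genome,
    plant_duplication,
    simulate_pat_tags,
    simulate_race_reads,
)
from utrapa.genome_io import load_annotation, load_genome
from utrapa.synthetic_data import TruthSet, write_reads_fasta


class TestMakeGenome:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_genome(8, seed=4, n_contaminants=2).write(a)
        make_genome(8, seed=4, n_contaminants=2).write(b)
        for name in ("genome.fa", "annotation.gff3", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_layout_fractions_realized_exactly(self):
        spec = LayoutSpec(frac_same_strand_upstream=0.2, frac_convergent_upstream=0.2)
        world = make_genome(20, layout=spec, seed=5)
        by_id = {g.gene_id: g for g in world.genes}
        same = conv = 0
        for g in world.genes:
            nb = by_id.get(g.gene_id + "N")
            if nb is None:
                continue
            if nb.strand == g.strand:
                same += 1
            else:
                conv += 1
        assert same == 4 and conv == 4  # 20% each of 20 genes

    def test_empty_genome(self):
        world = make_genome(0, seed=1)
        assert world.genes == []
        assert len(world.genome["Chr1"]) > 0

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            make_genome(
                10,
                layout=LayoutSpec(
                    frac_same_strand_upstream=0.7, frac_convergent_upstream=0.7
                ),
                seed=1,
            )

    def test_written_world_reloads_cleanly(self, world, tmp_path):
        world.write(tmp_path)
        genome = load_genome(tmp_path / "genome.fa")
        genes = load_annotation(tmp_path / "annotation.gff3")
        assert genome["Chr1"].sequence == world.genome["Chr1"].sequence
        assert {g.gene_id for g in genes} == {g.gene_id for g in world.genes}

    def test_contaminant_windows_contain_a_run_by_construction(self, world, params):
        assert world.truth.contaminant_sites
        for site in world.truth.contaminant_sites:
            chrom = world.genome[site.chrom]
            pos0 = site.cleavage_position - 1
            window = chrom.fetch(pos0 - 10, pos0 + 11, site.strand)
            assert has_a_run(window, 8)

    def test_planted_pac_windows_are_clean(self, world, params):
        for pac in world.truth.planted_pacs:
            chrom = world.genome[pac.chrom]
            pos0 = pac.cleavage_position - 1
            window = chrom.fetch(pos0 - 10, pos0 + 11, pac.strand)
            assert not has_a_run(window, params.a_run_threshold)


class TestSimulatePatTags:
    def test_depth_conservation_single_pac(self, world):
        tags = simulate_pat_tags(world, depth_per_pac=100, contamination_rate=0.0, seed=2)
        counts = tags.groupby(["chrom", "strand"]).size()
        assert len(tags) == 100 * len(world.truth.planted_pacs)

    def test_zero_contamination_keeps_all_tags_near_planted_sites(self, world):
        tags = simulate_pat_tags(world, depth_per_pac=50, contamination_rate=0.0, seed=3)
        truth = [(p.chrom, p.strand, p.cleavage_position) for p in world.truth.planted_pacs]
        for row in tags.itertuples():
            assert any(
                row.chrom == c and row.strand == s and abs(row.position - p) <= 12
                for c, s, p in truth
            )

    def test_expression_defaults_span_confirmed_range(self, world):
        exprs = [p.expression for p in world.truth.planted_pacs]
        assert min(exprs) >= 26 and max(exprs) <= 646

    def test_deterministic_for_fixed_seed(self, world):
        a = simulate_pat_tags(world, depth_per_pac=30, seed=9)
        b = simulate_pat_tags(world, depth_per_pac=30, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateRaceReads:
    def test_clean_channel_is_all_genuine(self, world):
        from utrapa import validate_reads
        from utrapa.race_validate import calls_to_frame

        reads, truth = simulate_race_reads(world, n_reads_per_site=2, seed=4)
        loci = {g.gene_id: world.locus_for_gene(g.gene_id) for g in world.genes}
        df = calls_to_frame(validate_reads(reads, loci, world.genome))
        assert (df.status == "genuine").all()

    def test_mimic_fraction_one_is_all_mimic(self, world):
        from utrapa import validate_reads
        from utrapa.race_validate import calls_to_frame

        reads, truth = simulate_race_reads(
            world, n_reads_per_site=2, mimic_fraction=1.0, seed=5
        )
        assert (truth.true_status == "internal_mimic").all()
        loci = {g.gene_id: world.locus_for_gene(g.gene_id) for g in world.genes}
        df = calls_to_frame(validate_reads(reads, loci, world.genome))
        assert (df.status == "internal_mimic").all()

    def test_reads_fasta_round_trip(self, world, tmp_path):
        from utrapa.race_validate import load_reads

        reads, _ = simulate_race_reads(world, n_reads_per_site=1, seed=6)
        path = tmp_path / "reads.fa"
        write_reads_fasta(reads, path)
        again = load_reads(path)
        assert [(r.read_id, r.sequence, r.target_gene) for r in again] == [
            (r.read_id, r.sequence, r.target_gene) for r in reads
        ]


class TestTruthSet:
    def test_json_round_trip(self, dup_world, tmp_path):
        world, _ = dup_world
        path = tmp_path / "truth.json"
        world.truth.to_json(path)
        again = TruthSet.from_json(path)
        assert dataclasses.asdict(again) == dataclasses.asdict(world.truth)


class TestPlantDuplication:
    def test_realized_identity_equals_mask_oracle(self, dup_world):
        world, entry = dup_world
        assert entry.identity_percent == 100.0 * (
            entry.tract_len - len(entry.substitution_mask)
        ) / entry.tract_len

    def test_invalid_identity_target_rejected(self):
        world = make_genome(4, seed=8)
        host = next(g.gene_id for g in world.genes if g.gene_id in world.slots)
        with pytest.raises(ValueError):
            plant_duplication(world, host, identity_target=0.0)
        with pytest.raises(ValueError):
            plant_duplication(world, host, identity_target=1.2)

    def test_identity_one_without_edits_is_perfect_copy(self):
        world = make_genome(4, seed=8)
        host = next(g.gene_id for g in world.genes if g.gene_id in world.slots)
        entry = plant_duplication(
            world, host, identity_target=1.0, stop_subs=(), seed=1
        )
        utr, morf = world.duplication_sequences(host)
        assert entry.substitution_mask == []
        s, e = entry.tract_utr_interval
        assert utr[s - 1 : e] == morf[: entry.tract_len]

    def test_chromosome_length_unchanged_by_rewrite(self):
        world = make_genome(4, seed=8)
        before = len(world.genome["Chr1"])
        host = next(g.gene_id for g in world.genes if g.gene_id in world.slots)
        plant_duplication(world, host, identity_target=0.8, seed=2)
        assert len(world.genome["Chr1"]) == before

    def test_pseudogene_copy_emitted_on_request(self):
        world = make_genome(4, seed=8)
        host = next(g.gene_id for g in world.genes if g.gene_id in world.slots)
        entry = plant_duplication(
            world, host, identity_target=0.9, seed=3, emit_pseudogene=True
        )
        s, e = entry.pseudogene_interval
        copy = world.genome["Chr1"].sequence[s - 1 : e]
        utr, morf = world.duplication_sequences(host)
        assert copy == morf[: entry.tract_len]
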