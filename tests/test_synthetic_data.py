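import json

import numpy as np
import pytest

from legsyn.io_formats import read_fasta
from legsyn.synthetic_data import (
    SimConfig,
    derive_species_pair,
    extract_gene,
    generate_ancestor,
    inject_allelic_variants,
    make_queries,
    write_fixture_set,
)


SMALL = dict(
    n_chrom_a=1, genes_per_chrom=12, markers_per_chrom=8, chrom_len=400_000
)


class TestAncestor:
    def test_feature_counts_match_config(self):
        cfg = SimConfig(seed=1, **SMALL)
        anc = generate_ancestor(cfg)
        genes = [f for f in anc.features if f.kind == "gene"]
        markers = [f for f in anc.features if f.kind == "marker"]
        assert len(genes) == 12 and len(markers) == 8

    def test_same_seed_identical_output(self):
        a = generate_ancestor(SimConfig(seed=9, **SMALL))
        b = generate_ancestor(SimConfig(seed=9, **SMALL))
        assert a.sequences == b.sequences
        assert [(f.id, f.start, f.end) for f in a.features] == [
            (f.id, f.start, f.end) for f in b.features
        ]

    def test_excessive_density_rejected(self):
        cfg = SimConfig(seed=1, n_chrom_a=1, genes_per_chrom=100,
                        markers_per_chrom=1, chrom_len=50_000)
        with pytest.raises(ValueError, match="density|fit"):
            generate_ancestor(cfg)

    def test_gene_models_have_long_first_exon(self):
        anc = generate_ancestor(SimConfig(seed=3, **SMALL))
        for f in anc.features:
            if f.model is None:
                continue
            lengths = [e - s + 1 for s, e in f.model.exons]
            assert 4 <= len(lengths) <= 6
            assert lengths[0] == max(lengths)
            assert len(f.model.introns) == len(lengths) - 1

    def test_features_do_not_overlap(self):
        anc = generate_ancestor(SimConfig(seed=4, **SMALL))
        feats = sorted(anc.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end < b.start


class TestSpeciesPair:
    def test_no_loss_no_inversion_gives_two_copies_everywhere(self):
        cfg = SimConfig(seed=2, fractionation_loss=0.0,
                        inversions_per_chrom=0.0, tandem_families=[], **SMALL)
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        for qid, t in pair.truth.anchors.items():
            assert len([b for b in t["b"] if b["surviving"]]) == 2

    def test_tandem_cluster_members_within_window(self):
        cfg = SimConfig(seed=2, tandem_families=[(6, 8000)],
                        fractionation_loss=0.0, inversions_per_chrom=0.0,
                        **SMALL)
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        (cluster,) = pair.truth.clusters
        starts = cluster["member_starts"]
        assert len(starts) == 6
        assert starts[-1] - starts[0] <= 5 * 8000
        # member starts actually index gene-like sequence in the emitted FASTA
        seq = pair.genome_b.sequences[cluster["chrom_b"]]
        assert all(1 <= s <= len(seq) for s in starts)

    def test_inverted_features_marked_reverse_in_truth(self):
        cfg = SimConfig(seed=6, inversions_per_chrom=2.0,
                        fractionation_loss=0.0, tandem_families=[], **SMALL)
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        rev_blocks = [b for b in pair.truth.blocks if b["orientation"] == "reverse"]
        assert rev_blocks
        by_chrom = {
            f.id: f for f in pair.genome_b.features
        }
        for block in rev_blocks:
            # at least the gene features inside an inversion flip strand
            strands = {
                by_chrom[q].strand
                for q in block["queries"]
                if by_chrom[q].chrom == block["chrom_b"]
            }
        # truth blocks and anchors are mutually consistent
        for block in pair.truth.blocks:
            for q in block["queries"]:
                assert any(
                    b["chrom"] == block["chrom_b"] and b["surviving"]
                    for b in pair.truth.anchors[q]["b"]
                )

    def test_realized_substitution_rate_within_3se(self):
        cfg = SimConfig(seed=8, fractionation_loss=0.0,
                        inversions_per_chrom=0.0, tandem_families=[], **SMALL)
        anc = generate_ancestor(cfg)
        pair = derive_species_pair(anc, cfg)
        anc_seq = anc.sequences["anc01"]
        a_seq = pair.genome_a.sequences["A01"]
        n = len(anc_seq)
        diff = sum(1 for x, y in zip(anc_seq, a_seq) if x != y)
        p = cfg.a_divergence
        se = (p * (1 - p) / n) ** 0.5
        assert abs(diff / n - p) <= 3 * se

    def test_fractionation_deletes_sequence_and_records_loss(self):
        cfg = SimConfig(seed=12, fractionation_loss=0.5,
                        inversions_per_chrom=0.0, tandem_families=[], **SMALL)
        anc = generate_ancestor(cfg)
        pair = derive_species_pair(anc, cfg)
        lost = [
            (qid, b)
            for qid, t in pair.truth.anchors.items()
            for b in t["b"]
            if not b["surviving"]
        ]
        assert lost
        for chrom, seq in pair.genome_b.sequences.items():
            assert len(seq) <= cfg.chrom_len

    def test_truth_positions_index_emitted_sequences(self):
        cfg = SimConfig(seed=13, **SMALL)
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        for qid, t in pair.truth.anchors.items():
            assert 1 <= t["a_pos"] <= len(pair.genome_a.sequences[t["a_chrom"]])
            for b in t["b"]:
                if b["surviving"]:
                    assert 1 <= b["pos"] <= len(pair.genome_b.sequences[b["chrom"]])


class TestQueriesAndAlleles:
    def test_queries_cover_all_features(self):
        cfg = SimConfig(seed=2, **SMALL)
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        queries, categories = make_queries(pair)
        assert len(queries) == len(pair.genome_a.features)
        assert set(categories.values()) == {"gene", "g_marker"}
        for q in queries:
            assert len(q.residues) >= 100

    def test_zero_rates_identical_allele(self):
        cfg = SimConfig(
            seed=2,
            snp_rate_by_region={"exon": 0, "intron": 0, "utr": 0},
            indel_rate_by_region={"exon": 0, "intron": 0, "utr": 0},
            **SMALL,
        )
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        gene = next(f for f in pair.genome_a.features if f.kind == "gene")
        record, model = extract_gene(pair, gene)
        alt, truth = inject_allelic_variants(record, model, cfg)
        assert alt.residues == record.residues
        assert truth == []

    def test_forced_intron_deletion_recorded(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(
            seed=2,
            snp_rate_by_region={"exon": 0, "intron": 0, "utr": 0},
            indel_rate_by_region={"exon": 0, "intron": 0.004, "utr": 0},
            **SMALL,
        )
        pair = derive_species_pair(generate_ancestor(cfg), cfg)
        gene = next(f for f in pair.genome_a.features if f.kind == "gene")
        record, model = extract_gene(pair, gene)
        alt, truth = inject_allelic_variants(record, model, cfg, rng)
        assert truth, "expected at least one injected indel"
        for v in truth:
            assert v.region.startswith("I")
            assert v.kind in ("deletion", "insertion")


class TestFixtureBundle:
    def test_bundle_complete_and_consistent(self, tmp_path):
        cfg = SimConfig(seed=2, **SMALL)
        out = write_fixture_set(cfg, tmp_path / "fx")
        names = {p.name for p in out.iterdir()}
        assert {
            "genome_a.fasta", "genome_b.fasta", "genome_a.gff3",
            "genome_b.gff3", "queries.fasta", "truth.json", "manifest.json",
        } <= names
        truth = json.loads((out / "truth.json").read_text())
        seqs = {r.id: r.residues for r in read_fasta(out / "genome_b.fasta")}
        for qid, t in truth["anchors"].items():
            for b in t["b"]:
                if b["surviving"]:
                    assert seqs[b["chrom"]][b["pos"] - 1] in "ACGTN"

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimConfig(seed=2, **SMALL)
        out1 = write_fixture_set(cfg, tmp_path / "fx1")
        out2 = write_fixture_set(cfg, tmp_path / "fx2")
        for p1 in sorted(out1.rglob("*")):
            if p1.is_file():
                p2 = out2 / p1.relative_to(out1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name
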