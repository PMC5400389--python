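"""Synthetic-data generator: ORF validity, planting, ortholog evolution."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from motifsel._kmer import MotifScanner, encode_seq
from motifsel.catalog import MotifSet
from motifsel.divergence import fourfold_sites
from motifsel.simulate import (
    PlantedSet,
    SimulationConfig,
    evolve_ortholog,
    plant_motifs,
    simulate_background_cds,
    simulate_expression_table,
    simulate_study,
)
from conftest import random_motif_set


def small_config(**kw):
    defaults = dict(n_families=12, min_codons=120, max_codons=180, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestBackground:
    def test_orf_structure(self, rng):
        records, families = simulate_background_cds(small_config(), rng)
        for r in records:
            assert len(r.seq) % 3 == 0
            assert r.seq.startswith("ATG")
            prot = str(Seq(r.seq).translate())
            assert prot.endswith("*")
            assert "*" not in prot[:-1]  # no internal stop

    def test_family_structure(self, rng):
        cfg = small_config(n_families=30, p_family_of_two=0.5)
        records, families = simulate_background_cds(cfg, rng)
        sizes = Counter(families.values())
        assert set(sizes.values()) <= {1, 2}
        assert len(sizes) == 30

    def test_family_members_same_protein(self, rng):
        cfg = small_config(n_families=30, p_family_of_two=1.0)
        records, families = simulate_background_cds(cfg, rng)
        by_family = {}
        for r in records:
            by_family.setdefault(families[r.gene_id], []).append(r.seq)
        for seqs in by_family.values():
            prots = {str(Seq(s).translate()) for s in seqs}
            assert len(prots) == 1

    def test_seed_determinism(self):
        a, _ = simulate_background_cds(small_config(), np.random.default_rng(9))
        b, _ = simulate_background_cds(small_config(), np.random.default_rng(9))
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_dinucleotide_frequencies_recovered(self):
        cfg = small_config(n_families=120, min_codons=250, max_codons=350, seed=2)
        records, _ = simulate_background_cds(cfg, np.random.default_rng(2))
        total_bp = sum(len(r.seq) for r in records)
        assert total_bp > 90_000
        counts = Counter()
        for r in records:
            s = r.seq[3:-3]  # interior: start/stop fixed by construction
            counts.update(s[i : i + 2] for i in range(len(s) - 1))
        total = sum(counts.values())
        target = cfg.dinucleotide_freqs
        tv = 0.5 * sum(
            abs(counts.get(d, 0) / total - target.get(d, 0.0))
            for d in set(counts) | set(target)
        )
        assert tv < 0.02


class TestPlanting:
    def test_multiplier_zero_removes_all(self, rng):
        records, _ = simulate_background_cds(small_config(), rng)
        mset = MotifSet("X", frozenset({"ATTTA", "TGTAT"}))
        out, masks = plant_motifs(records, mset, 0.0, rng)
        scanner = MotifScanner(sorted(mset.motifs))
        for r in out:
            assert scanner.covered(encode_seq(r.seq)) == 0
            assert not masks[r.gene_id].any()

    def test_enrichment_raises_coverage(self, rng):
        records, _ = simulate_background_cds(small_config(), rng)
        mset = random_motif_set(rng, rbp_id="P", n=6)
        scanner = MotifScanner(sorted(mset.motifs))
        before = sum(scanner.covered(encode_seq(r.seq)) for r in records)
        out, masks = plant_motifs(records, mset, 3.0, rng)
        after = sum(scanner.covered(encode_seq(r.seq)) for r in out)
        assert after > before
        for r in out:
            prot = str(Seq(r.seq).translate())
            assert "*" not in prot[:-1]

    def test_masks_match_scan(self, rng):
        records, _ = simulate_background_cds(small_config(), rng)
        mset = random_motif_set(rng, rbp_id="P", n=6)
        out, masks = plant_motifs(records, mset, 2.0, rng)
        scanner = MotifScanner(sorted(mset.motifs))
        for r in out:
            assert np.array_equal(masks[r.gene_id], scanner.mask(encode_seq(r.seq)))

    def test_depletion_lowers_coverage(self, rng):
        records, _ = simulate_background_cds(small_config(n_families=20), rng)
        mset = MotifSet("X", frozenset({"TGGAA", "AAGAA", "CTGGA"}))
        records, _ = plant_motifs(records, mset, 2.0, rng)  # ensure some hits
        scanner = MotifScanner(sorted(mset.motifs))
        before = sum(scanner.covered(encode_seq(r.seq)) for r in records)
        out, _ = plant_motifs(records, mset, 0.3, rng)
        after = sum(scanner.covered(encode_seq(r.seq)) for r in out)
        assert after < before


class TestOrtholog:
    def test_zero_rates_identical(self, rng):
        records, _ = simulate_background_cds(small_config(), rng)
        pairs = evolve_ortholog(records, None, 0.0, 0.0, rng=rng)
        assert all(p.focal == p.ortholog for p in pairs)

    def test_protein_preserved_and_gap_free(self, rng):
        records, _ = simulate_background_cds(small_config(), rng)
        pairs = evolve_ortholog(records, None, 0.0, 0.2, rng=rng)
        for p in pairs:
            assert len(p.focal) == len(p.ortholog)
            assert str(Seq(p.focal).translate()) == str(Seq(p.ortholog).translate())

    def test_background_rate_recovered(self, rng):
        records, _ = simulate_background_cds(
            small_config(n_families=40, min_codons=250, max_codons=300), rng
        )
        rate = 0.1
        pairs = evolve_ortholog(records, None, rate, rate, rng=rng)
        n = diff = 0
        for p in pairs:
            for s in fourfold_sites(p.focal):
                n += 1
                diff += p.focal[s] != p.ortholog[s]
        assert n > 4000
        assert diff / n == pytest.approx(rate, abs=0.01)

    def test_full_gain_suppression_blocks_created_occurrences(self, rng):
        records, _ = simulate_background_cds(small_config(n_families=25), rng)
        avoided = random_motif_set(rng, rbp_id="AV", n=8, kmin=5, kmax=6)
        scanner = MotifScanner(sorted(avoided.motifs))
        pairs = evolve_ortholog(
            records, None, 0.15, 0.15, gain_suppression=1.0, avoided=avoided, rng=rng
        )
        for p in pairs:
            focal_hits = {
                (int(s), k)
                for k, starts in scanner.hit_starts(encode_seq(p.focal)).items()
                for s in starts
            }
            orth_hits = {
                (int(s), k)
                for k, starts in scanner.hit_starts(encode_seq(p.ortholog)).items()
                for s in starts
            }
            assert not (orth_hits - focal_hits)


class TestExpression:
    def test_target_breadth_recovered(self, rng):
        genes = [f"g{i}" for i in range(200)]
        table = simulate_expression_table(genes, rng, n_tissues=50, breadth=[0.3] * 200)
        measured = (table.values > 5).mean(axis=1)
        assert abs(measured.mean() - 0.3) < 0.05

    def test_breadth_zero_all_below_threshold(self, rng):
        table = simulate_expression_table(["g1", "g2"], rng, breadth=[0.0, 0.0])
        assert (table.values <= 5).all()

    def test_seeded_reproducibility(self):
        a = simulate_expression_table(["g1"], np.random.default_rng(3))
        b = simulate_expression_table(["g1"], np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)


class TestStudyBundle:
    def test_bundle_shapes(self):
        rng = np.random.default_rng(1)
        mset = random_motif_set(rng, rbp_id="RBP1", n=5)
        cfg = small_config(planted=[PlantedSet(mset, multiplier=2.0, conserved=True)])
        data = simulate_study(cfg)
        assert len(data.pairs) == len(data.records)
        assert set(data.masks) == {"RBP1"}
        assert data.expression.shape == (len(data.records), cfg.n_tissues)

    def test_fasta_roundtrip(self, tmp_path):
        from motifsel import io as msio

        rng = np.random.default_rng(2)
        cfg = small_config()
        records, families = simulate_background_cds(cfg, rng)
        msio.write_fasta(records, tmp_path / "cds.fa")
        back = msio.read_fasta(tmp_path / "cds.fa", families=families)
        assert [(r.gene_id, r.seq) for r in back] == [
            (r.gene_id, r.seq) for r in records
        ]

    def test_pairs_roundtrip(self, tmp_path):
        from motifsel import io as msio

        rng = np.random.default_rng(2)
        records, _ = simulate_background_cds(small_config(), rng)
        pairs = evolve_ortholog(records, None, 0.05, 0.05, rng=rng)
        msio.write_pairs_fasta(pairs, tmp_path / "pairs.fa")
        back = msio.read_pairs_fasta(tmp_path / "pairs.fa")
        assert [(p.gene_id, p.focal, p.ortholog) for p in back] == [
            (p.gene_id, p.focal, p.ortholog) for p in pairs
        ]
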