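"""Synonymous/noncoding divergence estimators and 4-fold site analysis."""

import math
import random

import numpy as np
import pytest

from motifsel.divergence import (
    CodonAlignmentPair,
    FOURFOLD_CODONS,
    NoDataError,
    SaturationError,
    build_codon_pairs,
    conservation_stats,
    estimate_ds,
    fourfold_divergence,
    fourfold_sites,
    is_fourfold_codon,
    kimura_k80,
    ng86_ds,
    noncoding_divergence,
)
from _oracles import brute_fourfold_codons


class TestNG86:
    def test_identical_sequences(self):
        assert ng86_ds([("ACG", "ACG"), ("TTT", "TTT")]) == 0.0

    def test_hand_example_nine_phe_codons(self):
        # 9x TTT with one TTT->TTC: S=3, pS=1/3, dS=-(3/4)ln(5/9)
        pairs = [("TTT", "TTC")] + [("TTT", "TTT")] * 8
        assert ng86_ds(pairs) == pytest.approx(-0.75 * math.log(5 / 9), abs=1e-10)

    def test_nonsynonymous_only_change(self):
        pairs = [("TTT", "CTT")] + [("TTT", "TTT")] * 8
        assert ng86_ds(pairs) == 0.0

    def test_codon_order_invariance(self):
        rng = random.Random(1)
        codons = sorted(FOURFOLD_CODONS)
        # one in three pairs carries a (synonymous) third-position change,
        # keeping the proportion well below saturation
        pairs = [
            (c, c[:2] + rng.choice("ACGT") if i % 3 == 0 else c)
            for c in codons
            for i in range(3)
        ]
        shuffled = pairs[:]
        rng.shuffle(shuffled)
        assert ng86_ds(pairs) == pytest.approx(ng86_ds(shuffled), abs=1e-12)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            ng86_ds([("GGA", "GGC"), ("GGA", "GGG"), ("GGA", "GGT")])

    def test_zero_synonymous_sites(self):
        with pytest.raises(NoDataError):
            ng86_ds([("TGG", "TGG")])  # Trp: no synonymous neighbour

    def test_empty_input(self):
        with pytest.raises(NoDataError):
            ng86_ds([])

    def test_agrees_with_independent_reference(self):
        """NG86 vs Biopython's calculate_dn_ds on random sub-saturation pairs."""
        from Bio.Align import Alignment
        from Bio.Align.analysis import calculate_dn_ds

        rng = np.random.default_rng(8)
        sense = sorted(set("".join(p) for p in FOURFOLD_CODONS))
        from motifsel.divergence import _AA, _CODONS

        sense = [c for c in _CODONS if _AA[c] is not None]
        for _ in range(20):
            n = int(rng.integers(30, 120))
            focal, orth = [], []
            for _ in range(n):
                c = sense[rng.integers(len(sense))]
                d = list(c)
                for i in range(3):
                    if rng.random() < 0.06:
                        d[i] = "ACGT"[rng.integers(4)]
                d = "".join(d)
                if _AA[d] is None:
                    d = c
                focal.append(c)
                orth.append(d)
            s1, s2 = "".join(focal), "".join(orth)
            aln = Alignment([s1, s2], np.array([[0, len(s1)], [0, len(s2)]]))
            try:
                _, ds_ref = calculate_dn_ds(aln, method="NG86")
            except (ValueError, KeyError, ZeroDivisionError):
                continue
            if ds_ref < 0:
                continue  # saturated in reference
            assert ng86_ds(list(zip(focal, orth))) == pytest.approx(ds_ref, abs=1e-6)


class TestCodonPairs:
    def test_mask_overlap_selects_codons(self):
        pair = CodonAlignmentPair("g", "AAACCCGGGTTTAAA", "AAACCCGGGTTTAAA")
        mask = np.zeros(15, dtype=bool)
        mask[3:10] = True  # covers bases 3..9 -> codons 1,2,3 (0-based)
        got = build_codon_pairs(pair, mask)
        assert got == [("CCC", "CCC"), ("GGG", "GGG"), ("TTT", "TTT")]

    def test_all_false_mask_empty(self):
        pair = CodonAlignmentPair("g", "AAACCC", "AAACCC")
        assert build_codon_pairs(pair, np.zeros(6, dtype=bool)) == []

    def test_gap_codons_excluded(self):
        pair = CodonAlignmentPair("g", "AAACCCGGG", "AAA--CGGG")
        mask = np.ones(9, dtype=bool)
        assert build_codon_pairs(pair, mask) == [("AAA", "AAA"), ("GGG", "GGG")]

    def test_gapped_focal_coordinates(self):
        # focal gap: mask is on ungapped focal coordinates
        pair = CodonAlignmentPair("g", "AAA---GGG", "AAACCCGGG")
        mask = np.array([False] * 3 + [True] * 3)
        assert build_codon_pairs(pair, mask) == [("GGG", "GGG")]

    def test_stop_codons_excluded(self):
        pair = CodonAlignmentPair("g", "AAATAAGGG", "AAATAAGGG")
        mask = np.ones(9, dtype=bool)
        assert ("TAA", "TAA") not in build_codon_pairs(pair, mask)


class TestFourfold:
    def test_examples(self):
        assert is_fourfold_codon("GGA")  # Gly
        assert not is_fourfold_codon("TTT")  # Phe
        assert not is_fourfold_codon("ATG")  # Met
        assert not is_fourfold_codon("AAT")  # Asn

    def test_matches_bruteforce_codon_table(self):
        assert FOURFOLD_CODONS == frozenset(brute_fourfold_codons())

    def test_site_positions(self):
        assert list(fourfold_sites("GGTAATAAA")) == [2]
        assert list(fourfold_sites("ATGGGACCT")) == [5, 8]

    def test_identical_sequences_zero_rates(self):
        pair = CodonAlignmentPair("g", "GGAGGCCCA", "GGAGGCCCA")
        fd = fourfold_divergence([pair], [np.zeros(9, dtype=bool)])
        assert (fd.table.rate == 0).all()

    def test_toy_weighted_rates(self):
        # Eight GGA codons separated by ATG spacers; single-site contexts vary,
        # so build a repetitive pair where the strata are easy to count.
        focal = "GGA" * 8
        orth = list(focal)
        # motif sites: positions 2,5 (one diverged); nonmotif: the rest
        mask = np.zeros(24, dtype=bool)
        mask[0:6] = True
        orth[2] = "T"  # diverged motif site (of 2 motif sites)
        orth[8] = "T"
        orth[11] = "T"  # two of six nonmotif sites diverged
        pair = CodonAlignmentPair("g", focal, "".join(orth))
        fd = fourfold_divergence([pair], [mask])
        # strata (by hand): GA -> motif 1/2, nonmotif 2/6; AG -> motif 1/2,
        # nonmotif 2/5 (the last site has no following base); motif-class
        # weights are 1/2 each.
        assert fd.motif_rate == pytest.approx(0.5)
        assert fd.nonmotif_rate == pytest.approx(0.5 * (2 / 6) + 0.5 * (2 / 5), abs=1e-9)

    def test_gapped_alignment_rejected(self):
        pair = CodonAlignmentPair("g", "GGA---", "GGAGGC")
        with pytest.raises(ValueError):
            fourfold_divergence([pair], [np.zeros(3, dtype=bool)])


class TestConservationStats:
    def test_normalized_ds_formula(self):
        st = conservation_stats(0.05, [0.1, 0.1, 0.1, 0.1])
        assert st.ds_norm == pytest.approx(-0.5)

    def test_p_cons_below_all_sims(self):
        sims = np.linspace(0.1, 0.3, 1000)
        st = conservation_stats(0.05, sims)
        assert st.p_cons == pytest.approx(1 / 1001)


class TestNoncoding:
    def test_identical_zero(self):
        assert kimura_k80("ACGTACGT", "ACGTACGT") == 0.0

    def test_one_transition_in_100(self):
        focal = "A" * 100
        orth = "G" + "A" * 99
        expected = -0.5 * math.log(1 - 2 * 0.01) - 0.25 * math.log(1.0)
        assert kimura_k80(focal, orth) == pytest.approx(expected, abs=1e-12)
        assert noncoding_divergence(focal, orth) == pytest.approx(0.0101014, abs=1e-6)

    def test_all_sites_differing_saturates(self):
        with pytest.raises(SaturationError):
            kimura_k80("A" * 50, "G" * 50)

    def test_gap_and_n_excluded(self):
        assert kimura_k80("ACGTN-", "ACGTAC") == 0.0


class TestExternalAdapters:
    def test_missing_codeml_is_explicit(self):
        with pytest.raises(FileNotFoundError):
            estimate_ds([("TTT", "TTC")], method="external_gy94",
                        external_path="codeml-definitely-missing")

    def test_missing_baseml_is_explicit(self):
        with pytest.raises(FileNotFoundError):
            noncoding_divergence("ACGT", "ACGT", method="external_baseml",
                                 external_path="baseml-definitely-missing")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_ds([("TTT", "TTC")], method="gy94")
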