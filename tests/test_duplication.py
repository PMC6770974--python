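import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famevo import duplication as dup
from famevo import synthetic
from util_oracles import (GENETIC_CODE, STOPS, oracle_longest_chain,
                          oracle_pathways, oracle_syn_sites)

SENSE = sorted(set(GENETIC_CODE) - STOPS)


class TestNG86:
    def test_identical_sequences(self):
        r = dup.ng86_kaks("ATGGCT", "ATGGCT")
        assert r.ka == 0 and r.ks == 0 and math.isnan(r.omega)

    def test_single_synonymous_difference(self):
        # TTT and TTC both encode Phe: Sd=1, Nd=0, Ka=0, omega=0
        r = dup.ng86_kaks("TTTGGG", "TTCGGG")
        assert (r.sd, r.nd) == (1.0, 0.0)
        assert r.ka == 0.0 and r.ks > 0 and r.omega == 0.0

    def test_codons_with_ambiguity_skipped_pairwise(self):
        r = dup.ng86_kaks("TTTNNNGGG", "TTCAAAGGG")
        assert r.n_codons == 2 and r.sd == 1.0

    def test_zero_usable_codons_raises(self):
        with pytest.raises(ValueError):
            dup.ng86_kaks("NNN", "NNN")
        with pytest.raises(ValueError):
            dup.ng86_kaks("ATG", "ATGGCT")

    def test_site_counts_match_oracle_for_every_sense_codon(self):
        for codon in SENSE:
            assert dup._syn_sites(codon) == pytest.approx(
                oracle_syn_sites(codon), abs=1e-12)

    def test_pathway_counts_match_oracle_on_all_codon_pairs(self):
        for ca, cb in itertools.product(SENSE, repeat=2):
            got = dup._pathway_differences(ca, cb)
            want = oracle_pathways(ca, cb)
            assert got == pytest.approx(want, abs=1e-12), (ca, cb)

    @given(st.lists(st.sampled_from(SENSE), min_size=10, max_size=60))
    def test_symmetric_in_its_arguments(self, codons):
        a = "".join(codons)
        rng = np.random.default_rng(abs(hash(a)) % 2 ** 31)
        b = "".join(rng.choice(SENSE) if rng.random() < 0.2 else c
                    for c in codons)
        ra, rb = dup.ng86_kaks(a, b), dup.ng86_kaks(b, a)
        assert (ra.sd, ra.nd, ra.s_sites) == (rb.sd, rb.nd, rb.s_sites)

    def test_purifying_selection_recovered(self):
        below = 0
        for seed in range(20):
            a, b, _ = synthetic.evolve_cds_pair(200, 0.4, 0.3, seed=seed)
            r = dup.ng86_kaks(a, b)
            below += r.omega < 1
        assert below >= 19


class TestWgdBinsAndDating:
    @pytest.mark.parametrize("ks,expected", [
        (0.0, "glycine"), (0.2, "glycine"), (0.3, "legume"), (1.0, "legume"),
        (1.4999, "legume"), (1.5, "gamma"), (4.0, "gamma")])
    def test_half_open_bins(self, ks, expected):
        assert dup.assign_wgd_bin(ks) == expected

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            dup.assign_wgd_bin(-0.1)

    @pytest.mark.parametrize("ks,t", [(0.0, 0.0), (0.122, 10.0),
                                      (1.22, 100.0)])
    def test_molecular_clock_dates(self, ks, t):
        assert dup.date_duplication(ks) == pytest.approx(t)

    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            dup.date_duplication(0.5, 0.0)


def make_hits(pairs, evalue=1e-30, score=100.0):
    return pd.DataFrame([{"query": q, "subject": s, "evalue": evalue,
                          "bitscore": score} for q, s in pairs])


class TestDetectBlocks:
    def test_five_consecutive_pairs_one_block(self):
        order = {f"a{i}": ("c1", i) for i in range(5)}
        order |= {f"b{i}": ("c2", i) for i in range(5)}
        hits = make_hits([(f"a{i}", f"b{i}") for i in range(5)])
        blocks = dup.detect_blocks(hits, order)
        assert len(blocks) == 1 and blocks[0].n_anchors == 5
        assert blocks[0].orientation == "same"

    def test_four_pairs_below_threshold(self):
        order = {f"a{i}": ("c1", i) for i in range(4)}
        order |= {f"b{i}": ("c2", i) for i in range(4)}
        hits = make_hits([(f"a{i}", f"b{i}") for i in range(4)])
        assert dup.detect_blocks(hits, order) == []

    def test_inverted_block_detected(self):
        order = {f"a{i}": ("c1", i) for i in range(6)}
        order |= {f"b{i}": ("c2", 10 - i) for i in range(6)}
        hits = make_hits([(f"a{i}", f"b{i}") for i in range(6)])
        blocks = dup.detect_blocks(hits, order)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"
        assert blocks[0].n_anchors == 6

    def test_rank_gap_limit_breaks_chain(self):
        order = {f"a{i}": ("c1", i * 30) for i in range(5)}
        order |= {f"b{i}": ("c2", i * 30) for i in range(5)}
        hits = make_hits([(f"a{i}", f"b{i}") for i in range(5)])
        assert dup.detect_blocks(hits, order, max_rank_gap=25) == []

    def test_missing_gene_in_order_raises(self):
        hits = make_hits([("a0", "b0")])
        with pytest.raises(ValueError, match="b0"):
            dup.detect_blocks(hits, {"a0": ("c1", 0)})

    def test_each_anchor_in_at_most_one_block(self, genome_bundle):
        hits = genome_bundle.homolog_hits
        blocks = dup.detect_blocks(hits, genome_bundle.gene_order())
        seen = set()
        for block in blocks:
            for anchor in block.anchors:
                key = (anchor.gene_a, anchor.gene_b)
                assert key not in seen
                seen.add(key)

    @pytest.mark.parametrize("n_hits", [6, 10, 15])
    def test_best_chain_matches_bruteforce_oracle(self, n_hits, rng):
        for _ in range(10):
            ranks_a = rng.choice(30, size=n_hits, replace=False)
            ranks_b = rng.choice(30, size=n_hits, replace=False)
            order = {f"a{i}": ("c1", int(ranks_a[i]))
                     for i in range(n_hits)}
            order |= {f"b{i}": ("c2", int(ranks_b[i]))
                      for i in range(n_hits)}
            hits = make_hits([(f"a{i}", f"b{i}") for i in range(n_hits)])
            blocks = dup.detect_blocks(hits, order, min_anchors=1,
                                       max_rank_gap=10)
            got = max(b.n_anchors for b in blocks)
            anchors = [(int(ranks_a[i]), int(ranks_b[i]))
                       for i in range(n_hits)]
            want = max(oracle_longest_chain(anchors, 10, inv)
                       for inv in (False, True))
            assert got == want


class TestTandem:
    def test_adjacent_members_are_tandem(self):
        order = {"c": [f"g{i}" for i in range(20)]}
        assert dup.classify_tandem(order, {"g10", "g11"}) == {"g10", "g11"}

    def test_one_intervening_gene_still_tandem(self):
        order = {"c": [f"g{i}" for i in range(20)]}
        assert dup.classify_tandem(order, {"g10", "g12"}) == {"g10", "g12"}

    def test_two_intervening_genes_not_tandem(self):
        order = {"c": [f"g{i}" for i in range(20)]}
        assert dup.classify_tandem(order, {"g10", "g13"}) == set()

    def test_invariant_under_gene_renaming(self, rng):
        genes = [f"g{i}" for i in range(30)]
        family = {"g3", "g4", "g10", "g20", "g22"}
        base = dup.classify_tandem({"c": genes}, family)
        mapping = {g: f"x{i}" for i, g in enumerate(genes)}
        renamed = dup.classify_tandem(
            {"c": [mapping[g] for g in genes]},
            {mapping[g] for g in family})
        assert renamed == {mapping[g] for g in base}


class TestSegmentalAndSummary:
    def _block(self, pairs):
        anchors = [dup.Anchor(a, b, i, i, 100.0)
                   for i, (a, b) in enumerate(pairs)]
        return dup.SyntenyBlock(1, "c1", "c2", "same", anchors)

    def test_family_pair_in_block_is_segmental(self):
        block = self._block([("f1", "f2"), ("x1", "x2"), ("f3", "y1"),
                             ("x3", "x4"), ("x5", "x6")])
        seg, pairs = dup.classify_segmental([block], {"f1", "f2", "f3"})
        assert seg == {"f1", "f2"}
        assert pairs == [("f1", "f2")]

    def test_family_gene_anchored_to_nonfamily_not_segmental(self):
        block = self._block([("f1", "x1"), ("x2", "x3"), ("x4", "x5"),
                             ("x6", "x7"), ("x8", "x9")])
        seg, pairs = dup.classify_segmental([block], {"f1"})
        assert seg == set() and pairs == []

    def test_summary_reproduces_reported_percentages(self):
        bins = ["glycine"] * 22 + ["legume"] * 37 + ["gamma"] * 26
        summary = dup.summarize_duplication(
            bins, set(range(40)), set(range(42)), 93)
        pct = dict(zip(summary.metric, summary.percent))
        assert pct["wgd_glycine"] == 25.9
        assert pct["wgd_legume"] == 43.5
        assert pct["wgd_gamma"] == 30.6
        assert pct["tandem"] == 43.0

    def test_empty_pair_list_zero_percentages(self):
        summary = dup.summarize_duplication([], set(), set(), 93)
        assert (summary["percent"] == 0.0).all()
        assert (summary["count"] == 0).all()

    @given(st.lists(st.sampled_from(["glycine", "legume", "gamma"]),
                    min_size=1, max_size=200))
    def test_bin_percentages_sum_to_about_100(self, bins):
        summary = dup.summarize_duplication(bins, set(), set(), 10)
        wgd = summary[summary.metric.str.startswith("wgd_")]
        assert abs(wgd["percent"].sum() - 100.0) <= 0.1 + 1e-9

    def test_blocks_roundtrip_through_tsv(self, tmp_path):
        block = self._block([(f"f{i}", f"h{i}") for i in range(5)])
        path = str(tmp_path / "blocks.tsv")
        dup.write_blocks([block], path)
        (back,) = dup.read_blocks(path)
        assert [a.gene_a for a in back.anchors] == \
            [a.gene_a for a in block.anchors]
        assert back.orientation == "same"
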