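import numpy as np
import pandas as pd
import pytest

from famevo import selection as sel
from famevo import synthetic
from util_oracles import oracle_pairwise_pi


def make_table(genotypes, positions=None, chrom="c1", samples=None,
               pops=None):
    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples, _ = gt.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    samples = samples or [f"s{i}" for i in range(n_samples)]
    pops = pops or {s: "wild" for s in samples}
    return sel.VariantTable(
        chrom=np.array([chrom] * n_sites), pos=np.array(positions),
        ref=np.array(["A"] * n_sites), alt=np.array(["G"] * n_sites),
        genotypes=gt, samples=samples, populations=pops)


def random_table(rng, n_sites=8, n_samples=5, missing=0.2):
    gt = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    gt[rng.random(gt.shape) < missing] = -1
    pos = np.sort(rng.choice(np.arange(1, 200), size=n_sites,
                             replace=False))
    return make_table(gt, positions=pos)


class TestFilterVariants:
    def test_low_maf_removed(self):
        # 10 diploids, one heterozygote: MAF = 0.05 retained; 1/20 removed
        rare = [[0, 0]] * 9 + [[0, 1]]
        common = [[0, 1]] * 10
        ultra_rare = [[0, 0]] * 10
        table = make_table([rare, common, ultra_rare])
        kept = sel.filter_variants(table)
        assert kept.n_sites == 2  # MAF 0.05 boundary retained

    def test_high_missingness_removed(self):
        missing = [[-1, -1]] * 2 + [[0, 1]] * 8   # 20% missing
        clean = [[0, 1]] * 10
        table = make_table([missing, clean])
        kept = sel.filter_variants(table)
        assert kept.n_sites == 1 and kept.pos[0] == table.pos[1]

    def test_clean_common_site_retained(self):
        table = make_table([[[0, 1]] * 10])
        assert sel.filter_variants(table).n_sites == 1


class TestMakeWindows:
    def test_standard_enumeration(self):
        assert sel.make_windows(30000) == [(0, 20000), (10000, 30000),
                                           (20000, 30000)]

    def test_truncation_short_chromosome(self):
        assert sel.make_windows(15000) == [(0, 15000), (10000, 15000)]

    def test_size_equal_step_tiles(self):
        assert sel.make_windows(30000, 10000, 10000) == \
            [(0, 10000), (10000, 20000), (20000, 30000)]

    def test_gap_leaving_config_rejected(self):
        with pytest.raises(ValueError):
            sel.make_windows(30000, 5000, 10000)

    def test_interior_snp_covered_by_two_windows(self):
        windows = sel.make_windows(100_000)
        for bp in (25_000, 50_000, 73_000):
            cover = sum(1 for s, e in windows if s <= bp < e)
            assert cover == 2


class TestWindowPi:
    def test_no_snps_zero_pi(self):
        table = make_table([[[0, 1]] * 4])
        df = sel.window_pi(table, "wild", {"c1": [(1000, 2000)]})
        assert df.iloc[0]["pi"] == 0.0 and df.iloc[0]["n_snps"] == 0

    def test_single_site_worked_example(self):
        # 4 called alleles split 2/2 in a 100-bp window:
        # h = (4/3)(1 - 1/4 - 1/4) = 2/3, pi = 0.006667
        table = make_table([[[0, 1], [0, 1]]], positions=[50])
        df = sel.window_pi(table, "wild", {"c1": [(0, 100)]})
        assert df.iloc[0]["pi"] == pytest.approx(2 / 3 / 100)

    def test_site_with_single_called_allele_skipped(self):
        table = make_table([[[0, -1], [-1, -1]]], positions=[50])
        df = sel.window_pi(table, "wild", {"c1": [(0, 100)]})
        assert df.iloc[0]["pi"] == 0.0

    def test_matches_bruteforce_pairwise_oracle(self, rng):
        for _ in range(25):
            table = random_table(rng, n_sites=int(rng.integers(2, 10)),
                                 n_samples=int(rng.integers(2, 7)))
            window = (0, 150)
            df = sel.window_pi(table, "wild", {"c1": [window]})
            want = oracle_pairwise_pi(table.genotypes, table.pos, window)
            assert df.iloc[0]["pi"] == pytest.approx(want, abs=1e-12)

    def test_invariant_under_relabeling_and_allele_swap(self, rng):
        table = random_table(rng)
        base = sel.window_pi(table, "wild", {"c1": [(0, 200)]})
        swapped_gt = np.where(table.genotypes >= 0,
                              1 - table.genotypes, -1).astype(np.int8)
        swapped = make_table(swapped_gt, positions=table.pos)
        perm = list(np.random.default_rng(1).permutation(5))
        relabeled = make_table(table.genotypes[:, perm, :],
                               positions=table.pos)
        for other in (swapped, relabeled):
            got = sel.window_pi(other, "wild", {"c1": [(0, 200)]})
            assert got.iloc[0]["pi"] == pytest.approx(base.iloc[0]["pi"],
                                                      abs=1e-15)

    def test_empty_population_raises(self):
        table = make_table([[[0, 1]] * 3])
        with pytest.raises(ValueError):
            sel.window_pi(table, "cultivated", {"c1": [(0, 100)]})


def scan_frame(ratios, chrom="c1"):
    rows = []
    for i, r in enumerate(ratios):
        rows.append({"chrom": chrom, "start": i * 10_000,
                     "end": i * 10_000 + 20_000, "n_snps": 10,
                     "pi_wild": 0.01,
                     "pi_cult": np.nan if r is None else 0.01 * r,
                     "ratio": np.nan if r is None else float(r)})
    return pd.DataFrame(rows)


class TestRatioScan:
    def test_ratio_conventions(self):
        wild = pd.DataFrame({"chrom": ["c"] * 3, "start": [0, 1, 2],
                             "end": [10, 11, 12], "n_snps": [1, 1, 1],
                             "pi": [0.01, 0.02, 0.0]})
        cult = wild.copy()
        cult["pi"] = [0.01, 0.0, 0.05]
        scan = sel.ratio_scan(wild, cult)
        assert scan["ratio"].tolist()[0] == 1.0
        assert scan["ratio"].tolist()[1] == 0.0
        assert np.isnan(scan["ratio"].tolist()[2])

    def test_mismatched_windows_rejected(self):
        wild = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10],
                             "n_snps": [1], "pi": [0.01]})
        cult = wild.copy()
        cult["start"] = [5]
        with pytest.raises(ValueError):
            sel.ratio_scan(wild, cult)


class TestBaselineAndSweeps:
    def test_uniform_ratios_nothing_below_mean(self):
        scan = scan_frame([1.0] * 10)
        genes = pd.DataFrame({"gene_id": ["g"], "chromosome": ["c1"],
                              "start": [15_000], "end": [18_000]})
        report = sel.chromosome_baseline(scan, genes)
        assert not report["below_chromosome_mean"].any()

    def test_low_window_flags_gene_below_mean(self):
        scan = scan_frame([1.0] * 9 + [0.1])
        genes = pd.DataFrame({"gene_id": ["g"], "chromosome": ["c1"],
                              "start": [95_000], "end": [98_000]})
        report = sel.chromosome_baseline(scan, genes)
        assert report["below_chromosome_mean"].all()

    def test_gene_without_defined_windows_raises(self):
        scan = scan_frame([None, None])
        genes = pd.DataFrame({"gene_id": ["g"], "chromosome": ["c1"],
                              "start": [0], "end": [1000]})
        with pytest.raises(ValueError):
            sel.chromosome_baseline(scan, genes)

    def test_zero_ratio_window_selects_exactly_its_gene(self):
        scan = scan_frame([1.0] * 30 + [0.0])
        genes = pd.DataFrame({
            "gene_id": ["hit", "miss"], "chromosome": ["c1", "c1"],
            "start": [305_000, 5_000], "end": [308_000, 8_000]})
        report, threshold = sel.call_sweeps(scan, genes)
        by_id = report.set_index("gene_id")
        assert bool(by_id.loc["hit", "top5_selected"])
        assert not by_id.loc["miss", "top5_selected"]
        assert threshold == 0.0

    def test_no_gene_over_low_windows_empty_selection(self):
        scan = scan_frame([1.0] * 30 + [0.0])
        genes = pd.DataFrame({"gene_id": ["g"], "chromosome": ["c1"],
                              "start": [5_000], "end": [8_000]})
        report, _ = sel.call_sweeps(scan, genes)
        assert not report["top5_selected"].any()

    def test_few_windows_warns(self, caplog):
        scan = scan_frame([1.0] * 5)
        genes = pd.DataFrame({"gene_id": ["g"], "chromosome": ["c1"],
                              "start": [0], "end": [1000]})
        with caplog.at_level("WARNING"):
            sel.call_sweeps(scan, genes)
        assert "unstable" in caplog.text


class TestAccessionTree:
    def test_duplicate_accessions_are_sisters_at_zero_distance(self):
        gt = [[[0, 0], [0, 0], [1, 1]],
              [[1, 1], [1, 1], [0, 0]],
              [[0, 1], [0, 1], [1, 1]]]
        table = make_table(gt, samples=["dup1", "dup2", "other"])
        names, D = sel.ibs_distance_matrix(table)
        assert D[0, 1] == 0.0 and D[0, 2] > 0

    def test_two_fixed_populations_form_two_clades(self):
        n = 4
        gt = []
        for _ in range(6):
            gt.append([[0, 0]] * n + [[1, 1]] * n)
        samples = [f"w{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        table = make_table(gt, samples=samples)
        tree = sel.accession_tree(table)
        from util_trees import dendropy_splits
        splits = dendropy_splits(tree, samples)
        assert frozenset(range(n, 2 * n)) in splits

    def test_no_shared_sites_raises(self):
        gt = [[[0, 0], [-1, -1]], [[-1, -1], [1, 1]]]
        table = make_table(gt, samples=["a", "b"])
        with pytest.raises(ValueError):
            sel.ibs_distance_matrix(table)

    def test_synthetic_panel_separates_populations(self, small_config):
        table, _genes, _truth = synthetic.gen_population(small_config, 3)
        table = sel.filter_variants(table)
        keep = table.chrom == table.chrom[0]
        sub = table.subset_sites(np.flatnonzero(keep)[:300])
        tree = sel.accession_tree(sub)
        # majority clade purity: deepest split separates the populations
        from util_trees import dendropy_splits
        names = sub.samples
        idx = {s: i for i, s in enumerate(names)}
        wild = {idx[s] for s in names if s.startswith("W")}
        best = 0.0
        for split in dendropy_splits(tree, names):
            side = set(split)
            for group in (side, set(range(len(names))) - side):
                purity = max(len(group & wild), len(group - wild)) \
                    / len(group)
                frac = len(group) / len(names)
                if purity >= 0.95 and frac >= 0.3:
                    best = max(best, frac)
        assert best > 0.0


class TestVariantTableInvariants:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            make_table([[[0, 1]], [[0, 1]]], positions=[100, 100])

    def test_pipeline_is_deterministic(self, small_config):
        def run():
            table, genes, _ = synthetic.gen_population(small_config, 9)
            table = sel.filter_variants(table)
            wins = {c: sel.make_windows(small_config.pop_chrom_length)
                    for c in np.unique(table.chrom)}
            scan = sel.ratio_scan(sel.window_pi(table, "wild", wins),
                                  sel.window_pi(table, "cultivated", wins))
            report, thr = sel.call_sweeps(scan, genes)
            return scan.to_csv(), report.to_csv(), thr
        assert run() == run()
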