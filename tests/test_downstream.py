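import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equiqtl.downstream import (
    esnp_distance_null,
    genic_proportion_ztest,
    is_genic,
    _genic_lookup,
    pvalue_matrix,
    shared_gene_esnp_distances,
    trans_hotspots,
    treatment_overlap,
    tss_enrichment,
    two_proportion_ztest,
)
from equiqtl.io_formats import GeneModel, SnpRecord


def _table(rows):
    return pd.DataFrame(
        rows, columns=["snp", "gene", "class", "beta", "tstat", "pvalue",
                       "fdr", "confidence"]
    )


def _row(snp, gene, p=1e-5, fdr=1e-3):
    return (snp, gene, "cis", 1.0, 5.0, p, fdr, "high")


class TestTreatmentOverlap:
    def test_identical_tables_all_shared(self):
        t = _table([_row("s1", "g1"), _row("s2", "g2")])
        counts, members = treatment_overlap({"A": t, "B": t, "C": t})
        assert counts == {1: 0, 2: 0, 3: 2}
        assert sorted(members["3"]) == ["g1", "g2"]

    def test_disjoint_tables_all_unique(self):
        a = _table([_row("s1", "g1")])
        b = _table([_row("s2", "g2")])
        counts, _ = treatment_overlap({"A": a, "B": b})
        assert counts == {1: 2, 2: 0}

    def test_counts_partition_union(self):
        rng = np.random.default_rng(0)
        sets = {}
        genes = [f"g{i}" for i in range(60)]
        for t in "ABCD":
            chosen = rng.choice(genes, size=30, replace=False)
            sets[t] = _table([_row(f"s_{g}", g) for g in chosen])
        counts, members = treatment_overlap(sets)
        union = set().union(*(set(t["gene"]) for t in sets.values()))
        assert sum(counts.values()) == len(union)
        assert sum(len(v) for v in members.values()) == len(union)


class TestPvalueMatrix:
    def _sets(self, p_by_treatment):
        return {
            t: _table([_row("s1", "g1", p=p, fdr=0.01)])
            for t, p in p_by_treatment.items()
        }

    def test_boundary_p_excluded_by_strict_less_than(self):
        sets = self._sets({"A": 0.01, "B": 1e-4})
        assert pvalue_matrix(sets, raw_p_max=1e-2).empty

    def test_log_transform_values(self):
        sets = self._sets({"A": 1e-4, "B": 1e-4, "C": 1e-4, "D": 1e-4})
        mat = pvalue_matrix(sets)
        assert mat.shape == (1, 4)
        np.testing.assert_allclose(mat.to_numpy(), 4.0)

    def test_row_count_matches_brute_force_filter(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        sets = {}
        for t in "AB":
            sets[t] = _table(
                [_row(f"s_{g}", g, p=rng.uniform(1e-6, 0.05),
                      fdr=rng.uniform(1e-4, 0.2)) for g in genes]
            )
        mat = pvalue_matrix(sets, raw_p_max=1e-2)
        pa = sets["A"].set_index("gene")
        pb = sets["B"].set_index("gene")
        expected = sum(
            1 for g in genes
            if (pa.loc[g, "fdr"] < 0.05 or pb.loc[g, "fdr"] < 0.05)
            and pa.loc[g, "pvalue"] < 1e-2 and pb.loc[g, "pvalue"] < 1e-2
        )
        assert len(mat) == expected


class TestEsnpDistanceNull:
    def test_single_snp_windows_contribute_nothing(self):
        pos = np.array([1, 5_000_000, 10_000_000])
        d = esnp_distance_null(pos, n_windows=50, window_bp=2_000_000, seed=0)
        assert (d <= 2_000_000).all() if d.size else True

    def test_distances_bounded_by_window(self):
        pos = np.arange(1, 30_000_001, 10_000)
        d = esnp_distance_null(pos, n_windows=20, window_bp=2_000_000, seed=1)
        assert d.size > 0
        assert d.max() <= 2_000_000

    def test_three_snp_window_exhaustive_pairs(self):
        pos = np.array([10_000, 30_000, 100_000, 50_000_000])
        d = esnp_distance_null(pos, n_windows=200, window_bp=2_000_000, seed=2)
        got = set(np.unique(d[d < 2_000_000]))
        assert got <= {20_000, 70_000, 90_000}

    def test_chromosome_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            esnp_distance_null(np.array([1, 100]), window_bp=2_000_000, seed=0)


class TestSharedGeneEsnpDistances:
    def _snps(self):
        return [
            SnpRecord("a", "1", 100_000, "A", "G", 0.3),
            SnpRecord("b", "1", 150_000, "A", "G", 0.3),
            SnpRecord("c", "2", 500_000, "A", "G", 0.3),
        ]

    def test_identical_best_esnps_give_empty_sample(self):
        t = _table([_row("a", "g1")])
        d, ks_d, ks_p = shared_gene_esnp_distances({"A": t, "B": t}, self._snps())
        assert d.size == 0 and ks_d is None

    def test_differing_esnps_on_shared_chromosome_counted(self):
        a = _table([_row("a", "g1")])
        b = _table([_row("b", "g1")])
        d, _, _ = shared_gene_esnp_distances({"A": a, "B": b}, self._snps())
        np.testing.assert_array_equal(d, [50_000])

    def test_cross_chromosome_pairs_skipped(self):
        a = _table([_row("a", "g1")])
        b = _table([_row("c", "g1")])
        d, _, _ = shared_gene_esnp_distances({"A": a, "B": b}, self._snps())
        assert d.size == 0

    def test_ks_of_identical_samples_is_zero(self):
        x = np.arange(100.0)
        ks = stats.ks_2samp(x, x)
        assert ks.statistic == 0.0

    def test_clustered_esnps_beat_windowed_null(self):
        rng = np.random.default_rng(3)
        hits = 0
        null_pos = np.sort(rng.integers(1, 50_000_000, size=2000))
        null = esnp_distance_null(null_pos, n_windows=100,
                                  window_bp=2_000_000, seed=4)
        for trial in range(20):
            snps, tables = [], {t: [] for t in "ABCD"}
            for gi in range(40):
                locus = rng.integers(1_000_000, 49_000_000)
                for t in "ABCD":
                    pos = locus + rng.integers(-50_000, 50_001)
                    sid = f"s_{gi}_{t}"
                    snps.append(SnpRecord(sid, "1", int(pos), "A", "G", 0.3))
                    tables[t].append(_row(sid, f"g{gi}"))
            sets = {t: _table(rows) for t, rows in tables.items()}
            d, ks_d, ks_p = shared_gene_esnp_distances(sets, snps, null)
            hits += ks_p is not None and ks_p < 0.01
        assert hits >= 19


class TestTssEnrichment:
    def _setup(self, offsets, cis_dist=1_000_000):
        genes, snps, rows = [], [], []
        for i, off in enumerate(offsets):
            tss = 2_000_000 + i * 3_000_000
            genes.append(GeneModel(f"g{i}", "1", "+", tss,
                                   [(tss, tss + 100, "exon")]))
            snps.append(SnpRecord(f"s{i}", "1", tss + int(off), "A", "G", 0.3))
            rows.append(_row(f"s{i}", f"g{i}"))
        return _table(rows), genes, snps

    def test_all_esnps_at_tss_reject_uniformity(self):
        table, genes, snps = self._setup([0] * 60)
        d, ks_d, p = tss_enrichment(table, genes, snps)
        assert ks_d == pytest.approx(0.5)
        assert p < 1e-10

    def test_uniform_esnps_accept_uniformity(self):
        rng = np.random.default_rng(5)
        table, genes, snps = self._setup(
            rng.uniform(-1_000_000, 1_000_000, size=200)
        )
        _, _, p = tss_enrichment(table, genes, snps)
        assert p > 0.05

    def test_record_outside_window_is_classification_bug(self):
        table, genes, snps = self._setup([1_500_000])
        with pytest.raises(ValueError, match="cis window"):
            tss_enrichment(table, genes, snps)

    def test_near_tss_concentration_detected(self):
        rng = np.random.default_rng(6)
        table, genes, snps = self._setup(rng.normal(0, 50_000, size=500))
        _, _, p = tss_enrichment(table, genes, snps)
        assert p < 1e-6


class TestTransHotspots:
    def _snps(self, n, chrom="1", spacing=1_000_000):
        return [
            SnpRecord(f"s{i}", chrom, 1 + i * spacing, "A", "G", 0.3)
            for i in range(n)
        ]

    def test_target_counts_partition_records(self):
        snps = self._snps(5)
        rows = [_row("s0", f"g{i}") for i in range(3)] + [_row("s1", "g9")]
        table = _table(rows)
        tag_pos = {"1": np.array([s.pos for s in snps])}
        recs = trans_hotspots(table, tag_pos, snps)
        assert sum(r.trans_gene_count for r in recs) == len(table)

    def test_singleton_snps_are_not_enriched(self):
        snps = self._snps(50)
        rows = [_row(f"s{i}", f"g{i}") for i in range(50)]
        tag_pos = {"1": np.array([s.pos for s in snps])}
        recs = trans_hotspots(_table(rows), tag_pos, snps)
        assert min(r.enrichment_p for r in recs) > 0.05 / len(recs)

    def test_planted_hotspot_ranks_first(self):
        rng = np.random.default_rng(7)
        snps = self._snps(200)
        rows = [_row("s0", f"hub{i}") for i in range(40)]
        for i in range(300):
            rows.append(_row(f"s{rng.integers(1, 200)}", f"bg{i}"))
        tag_pos = {"1": np.array([s.pos for s in snps])}
        recs = trans_hotspots(_table(rows), tag_pos, snps)
        assert recs[0].snp_id == "s0"
        assert recs[0].trans_gene_count == 40
        assert recs[0].enrichment_p < 1e-10


class TestGenicProportions:
    def test_equal_proportions_give_zero_z(self):
        z, p = two_proportion_ztest(30, 100, 30, 100)
        assert z == 0.0 and p == 1.0

    def test_worked_pooled_variance_example(self):
        z, p = two_proportion_ztest(40, 100, 60, 100)
        assert z == pytest.approx(-2.8284, abs=1e-4)
        assert p == pytest.approx(0.00468, abs=1e-5)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(0, 0, 1, 10)

    def test_genic_membership_matches_interval_oracle(self):
        rng = np.random.default_rng(8)
        genes = []
        for i in range(30):
            start = int(rng.integers(1, 9_000_000))
            end = start + int(rng.integers(100, 50_000))
            mid = (start + end) // 2
            genes.append(
                GeneModel(f"g{i}", "1", "+", start,
                          [(start, mid, "exon"), (mid + 1, end, "intron")])
            )
        lookup = _genic_lookup(genes)
        for _ in range(500):
            pos = int(rng.integers(1, 10_000_000))
            snp = SnpRecord("x", "1", pos, "A", "G", 0.3)
            oracle = any(
                s <= pos <= e for g in genes for s, e, _ in g.intervals
            )
            assert is_genic(snp, lookup) == oracle

    def test_proportions_and_z_from_tables(self):
        genes = [GeneModel("g", "1", "+", 1000, [(1000, 2000, "exon")])]
        cis = _table([_row("a", "g1"), _row("b", "g2")])
        trans = _table([_row("c", "g3"), _row("d", "g4")])
        snps = [
            SnpRecord("a", "1", 1500, "A", "G", 0.3),   # genic
            SnpRecord("b", "1", 5000, "A", "G", 0.3),   # intergenic
            SnpRecord("c", "1", 1200, "A", "G", 0.3),   # genic
            SnpRecord("d", "1", 1800, "A", "G", 0.3),   # genic
        ]
        prop_cis, prop_trans, z, p = genic_proportion_ztest(cis, trans, genes,
                                                            snps)
        assert prop_cis == 0.5 and prop_trans == 1.0
        zo, po = two_proportion_ztest(1, 2, 2, 2)
        assert z == pytest.approx(zo) and p == pytest.approx(po)
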