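import numpy as np
import pandas as pd
import pytest

from latentcorr.model import FeatureData
from latentcorr.preprocess_io import (
    GeneAnnotation,
    aggregate_windows,
    estimate_size_factors,
    qc_filter,
    read_dataset,
    read_epigenome,
    read_gene_annotation,
    write_dataset,
)
from latentcorr.synthetic import SimConfig, generate_dataset


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        dataset, _ = generate_dataset(SimConfig(n_cells=15, n_features=6, seed=1))
        expr = tmp_path / "expr.tsv"
        epi = tmp_path / "epi.tsv"
        fac = tmp_path / "factors.tsv"
        write_dataset(dataset, str(expr), str(epi), str(fac))
        back = read_dataset(str(expr), str(epi), str(fac))
        assert len(back) == len(dataset)
        for orig, rec in zip(dataset, back):
            assert orig.feature_id == rec.feature_id
            np.testing.assert_array_equal(orig.y1, rec.y1)
            np.testing.assert_array_equal(orig.y2, rec.y2)
            np.testing.assert_array_equal(orig.n, rec.n)
            np.testing.assert_allclose(orig.s, rec.s)

    def test_mtx_round_trip(self, tmp_path):
        dataset, _ = generate_dataset(SimConfig(n_cells=10, n_features=4, seed=2))
        expr = tmp_path / "expr.mtx"
        epi = tmp_path / "epi.tsv"
        fac = tmp_path / "factors.tsv"
        write_dataset(dataset, str(expr), str(epi), str(fac))
        back = read_dataset(str(expr), str(epi), str(fac))
        for orig, rec in zip(dataset, back):
            np.testing.assert_array_equal(orig.y1, rec.y1)

    def test_missing_methylation_cell_gets_zero_coverage(self, tmp_path):
        (tmp_path / "expr.tsv").write_text(
            "cell_id\tgeneA\ncell_1\t5\ncell_2\t7\ncell_3\t0\n"
        )
        (tmp_path / "epi.tsv").write_text(
            "feature_id\tcell_id\tmet_reads\ttotal_reads\n"
            "geneA\tcell_1\t3\t10\ngeneA\tcell_3\t1\t4\n"
        )
        dataset = read_dataset(str(tmp_path / "expr.tsv"), str(tmp_path / "epi.tsv"))
        feature = dataset[0]
        np.testing.assert_array_equal(feature.n, [10, 0, 4])
        np.testing.assert_array_equal(feature.y2, [3, 0, 1])

    def test_malformed_row_names_line(self, tmp_path):
        (tmp_path / "epi.tsv").write_text(
            "feature_id\tcell_id\tmet_reads\ttotal_reads\n"
            "geneA\tcell_1\t3\t10\ngeneA\tcell_2\t9\t4\n"
        )
        with pytest.raises(ValueError, match="line.*3"):
            read_epigenome(str(tmp_path / "epi.tsv"))

    def test_no_shared_cells_error(self, tmp_path):
        (tmp_path / "expr.tsv").write_text("cell_id\tgeneA\ncell_1\t5\n")
        (tmp_path / "epi.tsv").write_text(
            "feature_id\tcell_id\tmet_reads\ttotal_reads\ngeneA\tother\t1\t2\n"
        )
        with pytest.raises(ValueError, match="share no cells"):
            read_dataset(str(tmp_path / "expr.tsv"), str(tmp_path / "epi.tsv"))


class TestQcFilter:
    def _feature(self, fid, y1, y2, n):
        return FeatureData(fid, y1, y2, n, np.ones(len(y1)))

    def test_hand_picked_filters(self, rng):
        I = 20
        constant = self._feature(
            "const", np.full(I, 3), rng.integers(0, 5, I), np.full(I, 10)
        )
        y1_sparse = np.zeros(I, int)
        y1_sparse[:3] = [1, 2, 3]  # 85% zeros
        sparse = self._feature(
            "sparse", y1_sparse, rng.integers(0, 5, I), np.full(I, 10)
        )
        clean = self._feature(
            "clean", rng.poisson(5, I) + 1, rng.integers(0, 5, I), np.full(I, 10)
        )
        kept, log = qc_filter([constant, sparse, clean], max_zero_frac=0.80)
        assert [f.feature_id for f in kept] == ["clean"]
        assert set(log["feature_id"]) == {"const", "sparse"}

    def test_max_zero_frac_one_keeps_nonconstant(self, rng):
        I = 20
        features = [
            self._feature(
                f"f{j}",
                rng.poisson(2, I),
                rng.integers(0, 5, I),
                np.full(I, 10),
            )
            for j in range(4)
        ]
        kept, _ = qc_filter(features, max_zero_frac=1.0)
        assert len(kept) == len(
            [f for f in features if np.ptp(f.y1) > 0]
        )

    def test_idempotent(self, rng):
        dataset, _ = generate_dataset(SimConfig(n_cells=40, n_features=30, seed=3))
        once, _ = qc_filter(dataset)
        twice, log = qc_filter(once)
        assert [f.feature_id for f in twice] == [f.feature_id for f in once]
        assert log.empty

    def test_all_dropped_error(self):
        constant = self._feature("c", [1, 1, 1], [0, 1, 2], [3, 3, 3])
        with pytest.raises(ValueError, match="every feature"):
            qc_filter([constant])


class TestAggregateWindows:
    @pytest.fixture()
    def annotation(self):
        return [
            GeneAnnotation("geneA", "chr1", 10000, "+"),
            GeneAnnotation("geneB", "chr1", 50000, "-"),
        ]

    def _sites(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "cell_id", "met_reads", "total_reads"]
        )

    def test_site_at_tss_included(self, annotation):
        sites = self._sites([("chr1", 10000, "c1", 2, 5)])
        out = aggregate_windows(sites, annotation, window_bp=100)
        assert len(out) == 1
        assert out.iloc[0]["feature_id"] == "geneA"

    def test_boundary_arithmetic(self, annotation):
        sites = self._sites(
            [("chr1", 10000 - 3000, "c1", 1, 2), ("chr1", 10000 + 3000, "c1", 2, 3)]
        )
        narrow = aggregate_windows(sites, annotation, window_bp=2500)
        assert narrow.empty
        wide = aggregate_windows(sites, annotation, window_bp=12500)
        assert wide.iloc[0][["met_reads", "total_reads"]].tolist() == [3, 5]

    def test_hand_summed_counts(self, annotation):
        sites = self._sites(
            [
                ("chr1", 9000, "c1", 1, 4),
                ("chr1", 10500, "c1", 2, 2),
                ("chr1", 11000, "c2", 0, 3),
                ("chr1", 49000, "c1", 5, 9),
                ("chr2", 10000, "c1", 7, 7),  # wrong chromosome
            ]
        )
        out = aggregate_windows(sites, annotation, window_bp=2500)
        a_c1 = out.query("feature_id == 'geneA' and cell_id == 'c1'").iloc[0]
        assert (a_c1["met_reads"], a_c1["total_reads"]) == (3, 6)
        a_c2 = out.query("feature_id == 'geneA' and cell_id == 'c2'").iloc[0]
        assert (a_c2["met_reads"], a_c2["total_reads"]) == (0, 3)
        b_c1 = out.query("feature_id == 'geneB' and cell_id == 'c1'").iloc[0]
        assert (b_c1["met_reads"], b_c1["total_reads"]) == (5, 9)


class TestGtfReader:
    def test_tss_strand_conversion(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "plus_gene";\n'
            'chr1\tsrc\tgene\t3001\t4000\t.\t-\t.\tgene_id "minus_gene";\n'
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "plus_gene";\n'
        )
        genes = read_gene_annotation(str(gtf))
        assert len(genes) == 2
        assert genes[0].tss == 1000  # GTF start 1001 -> 0-based 1000
        assert genes[1].tss == 3999  # minus strand anchors at end
        assert genes[1].strand == "-"

    def test_missing_strand_error(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text('chr1\tsrc\tgene\t100\t200\t.\t.\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="strand"):
            read_gene_annotation(str(gtf))


class TestSizeFactors:
    def test_two_cell_libsize(self):
        counts = np.array([[50, 50], [100, 100]])
        np.testing.assert_allclose(
            estimate_size_factors(counts), [2 / 3, 4 / 3]
        )

    def test_identical_cells_give_ones(self):
        counts = np.tile([3, 4, 5], (6, 1))
        np.testing.assert_allclose(estimate_size_factors(counts), np.ones(6))

    def test_scale_invariance(self, rng):
        counts = rng.poisson(10, (8, 30))
        np.testing.assert_allclose(
            estimate_size_factors(counts), estimate_size_factors(5 * counts)
        )

    def test_zero_cell_floored_with_warning(self):
        counts = np.array([[0, 0], [10, 10]])
        with pytest.warns(UserWarning):
            factors = estimate_size_factors(counts)
        assert np.all(factors > 0)

    def test_median_ratio_zero_cell_error(self):
        counts = np.array([[0, 0], [10, 10]])
        with pytest.raises(ValueError):
            estimate_size_factors(counts, method="median_ratio")

    def test_median_ratio_recovers_depth(self, rng):
        base = rng.poisson(50, (1, 40))
        counts = np.vstack([base, 2 * base, 4 * base])
        factors = estimate_size_factors(counts, method="median_ratio")
        np.testing.assert_allclose(factors / factors[0], [1, 2, 4], rtol=1e-6)
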