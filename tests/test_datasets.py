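import numpy as np
import pytest

from fuseaft import (
    CancerDataset,
    align_genes,
    canonicalize,
    compute_km_weights,
    load_cancer_dataset,
    load_panel,
    weighted_standardize,
)
from fuseaft.exceptions import (
    DataFormatError,
    DegenerateWeightsError,
    EmptyIntersectionError,
    EmptyJoinError,
    NonPositiveTimeError,
)
from fuseaft.kmweights import KMWeights

from conftest import make_cohorts


class TestLoad:
    def test_identity_join(self, toy_tables):
        ds = load_cancer_dataset(*toy_tables, "TOY")
        assert ds.n == 4 and ds.p == 3
        assert sorted(ds.gene_ids) == ["EGFR", "KRAS", "TP53"]

    def test_status_mapping(self, tmp_path, toy_tables):
        expr, _ = toy_tables
        clin = tmp_path / "c5.tsv"
        clin.write_text(
            "SAMPLE_ID\tOS_MONTHS\tOS_STATUS\n"
            "S1\t1\tDECEASED\nS2\t2\tLIVING\nS3\t3\tLIVING\nS4\t4\tDECEASED\n"
        )
        ds = load_cancer_dataset(expr, clin, "TOY")
        # hand-checked mapping for the 4 matched samples (order of expr file)
        expected = {"S1": 1, "S2": 0, "S3": 0, "S4": 1}
        assert list(ds.delta) == [expected[s] for s in ("S1", "S2", "S3", "S4")]

    def test_cbioportal_composite_status(self, tmp_path, toy_tables):
        expr, _ = toy_tables
        clin = tmp_path / "c.tsv"
        clin.write_text(
            "SAMPLE_ID\tOS_MONTHS\tOS_STATUS\n"
            "S1\t1\t1:DECEASED\nS2\t2\t0:LIVING\nS3\t3\t0:LIVING\nS4\t4\t1:DECEASED\n"
        )
        ds = load_cancer_dataset(expr, clin, "TOY")
        assert list(ds.delta) == [1, 0, 0, 1]

    def test_extra_expression_sample_dropped(self, tmp_path, toy_tables):
        _, clin_path = toy_tables
        expr = tmp_path / "e.tsv"
        expr.write_text(
            "Hugo_Symbol\tS1\tS2\tS3\tS4\tS9\n"
            "TP53\t1\t2\t3\t4\t5\n"
            "EGFR\t1\t2\t3\t4\t5\n"
        )
        ds = load_cancer_dataset(expr, clin_path, "TOY")
        assert ds.n == 4

    def test_samples_by_genes_orientation(self, tmp_path, toy_tables):
        _, clin_path = toy_tables
        expr = tmp_path / "e2.tsv"
        expr.write_text(
            "sample\tTP53\tEGFR\n"
            "S1\t1\t5\nS2\t2\t6\nS3\t3\t7\nS4\t4\t8\n"
        )
        ds = load_cancer_dataset(expr, clin_path, "TOY")
        assert ds.p == 2 and ds.n == 4
        col = ds.gene_ids.index("TP53")
        assert list(ds.X[:, col]) == [1, 2, 3, 4]

    def test_missing_column_error(self, tmp_path, toy_tables):
        expr, _ = toy_tables
        clin = tmp_path / "bad.tsv"
        clin.write_text("SAMPLE_ID\tMONTHS\nS1\t3\n")
        with pytest.raises(DataFormatError):
            load_cancer_dataset(expr, clin, "TOY")

    def test_empty_join_error(self, tmp_path, toy_tables):
        expr, _ = toy_tables
        clin = tmp_path / "nojoin.tsv"
        clin.write_text("SAMPLE_ID\tOS_MONTHS\tOS_STATUS\nZZ\t3\tLIVING\n")
        with pytest.raises(EmptyJoinError):
            load_cancer_dataset(expr, clin, "TOY")

    def test_nonpositive_time_names_sample(self, tmp_path, toy_tables):
        expr, _ = toy_tables
        clin = tmp_path / "zero.tsv"
        clin.write_text(
            "SAMPLE_ID\tOS_MONTHS\tOS_STATUS\n"
            "S1\t1\tLIVING\nS2\t0\tDECEASED\nS3\t3\tLIVING\nS4\t4\tLIVING\n"
        )
        with pytest.raises(NonPositiveTimeError, match="S2"):
            load_cancer_dataset(expr, clin, "TOY")

    def test_load_panel(self, tmp_path):
        f = tmp_path / "panel.txt"
        f.write_text("TP53\n# comment\nEGFR\n\n")
        assert load_panel(f) == ["TP53", "EGFR"]


class TestCanonicalize:
    def _ds(self, times, delta):
        n = len(times)
        return CancerDataset(
            "T", ["g"], np.arange(n, dtype=float).reshape(n, 1),
            np.asarray(times, float), np.asarray(delta),
        )

    def test_sort_and_log(self):
        out = canonicalize(self._ds([2.0, 1.0, 3.0], [1, 1, 0]))
        assert np.allclose(out.y, np.log([1.0, 2.0, 3.0]))
        assert list(out.X[:, 0]) == [1, 0, 2]

    def test_tie_rule_events_first(self):
        out = canonicalize(self._ds([2.0, 2.0], [0, 1]))
        assert list(out.delta) == [1, 0]

    def test_idempotent(self):
        once = canonicalize(self._ds([2.0, 1.0, 3.0], [1, 0, 1]))
        twice = canonicalize(once)
        assert np.array_equal(once.y, twice.y)
        assert np.array_equal(once.delta, twice.delta)
        assert np.array_equal(once.X, twice.X)

    def test_nonpositive_time_error(self):
        with pytest.raises(NonPositiveTimeError):
            canonicalize(self._ds([1.0, -2.0], [1, 1]))


class TestAlignGenes:
    def _ds(self, label, genes, n=4, seed=0):
        rng = np.random.default_rng(seed)
        return CancerDataset(
            label, list(genes), rng.normal(size=(n, len(genes))),
            np.arange(1.0, n + 1), np.ones(n, dtype=int),
        )

    def test_intersection(self):
        data = align_genes([self._ds("A", "ABC"), self._ds("B", "BCD")])
        assert data.gene_ids == ["B", "C"]

    def test_panel_filter(self):
        data = align_genes([self._ds("A", "ABC"), self._ds("B", "BCD")], panel=["C"])
        assert data.gene_ids == ["C"]

    def test_identical_sorted(self):
        data = align_genes([self._ds("A", "CBA"), self._ds("B", "CBA"),
                            self._ds("C", "CBA")])
        assert data.gene_ids == ["A", "B", "C"]

    def test_order_commutative_up_to_labels(self):
        a, b = self._ds("A", "ABC", seed=1), self._ds("B", "BCD", seed=2)
        d1 = align_genes([a, b])
        d2 = align_genes([b, a])
        assert d1.gene_ids == d2.gene_ids
        assert np.array_equal(d1[0].X, d2[1].X)

    def test_empty_intersection(self):
        with pytest.raises(EmptyIntersectionError):
            align_genes([self._ds("A", "AB"), self._ds("B", "CD")])


class TestWeightedStandardize:
    def test_equal_unit_weights_symmetric_column(self):
        ds = CancerDataset.from_log_times(
            "T", ["g"], np.array([[1.0], [-1.0]]), np.array([0.0, 1.0]),
            np.array([1, 1]),
        )
        std, rec = weighted_standardize(ds, KMWeights(w=np.ones(2)))
        assert np.allclose(std.X[:, 0], [1.0, -1.0])
        assert rec.x_scale[0] == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        X = np.column_stack([np.full(4, 3.0), np.arange(4.0)])
        ds = CancerDataset.from_log_times(
            "T", ["c", "g"], X, np.arange(4.0), np.ones(4, dtype=int)
        )
        std, rec = weighted_standardize(ds, compute_km_weights(ds))
        assert not rec.retained[0] and rec.retained[1]
        assert np.all(std.X[:, 0] == 0.0)

    def test_unequal_weights_hand_computed(self):
        # 3 rows, weights (0.5, 0.3, 0.2); moments checked by direct arithmetic
        X = np.array([[1.0], [2.0], [4.0]])
        y = np.array([0.1, 0.2, 0.3])
        ds = CancerDataset.from_log_times("T", ["g"], X, y, np.ones(3, dtype=int))
        w = np.array([0.5, 0.3, 0.2])
        std, rec = weighted_standardize(ds, KMWeights(w=w))
        xbar = (0.5 * 1 + 0.3 * 2 + 0.2 * 4) / 1.0  # = 1.9
        msq = (0.5 * (1 - xbar) ** 2 + 0.3 * (2 - xbar) ** 2
               + 0.2 * (4 - xbar) ** 2) / 3.0
        assert rec.x_mean[0] == pytest.approx(xbar)
        assert rec.x_scale[0] == pytest.approx(np.sqrt(msq))
        assert rec.y_mean == pytest.approx(0.5 * 0.1 + 0.3 * 0.2 + 0.2 * 0.3)
        assert np.allclose(std.X[:, 0], (X[:, 0] - xbar) / np.sqrt(msq))

    def test_degenerate_weights_error(self):
        ds = CancerDataset.from_log_times(
            "T", ["g"], np.ones((3, 1)), np.arange(3.0), np.zeros(3, dtype=int)
        )
        with pytest.raises(DegenerateWeightsError):
            weighted_standardize(ds, compute_km_weights(ds))

    def test_round_trip_fitted_values(self):
        from fuseaft import PenaltySpec, fit_joint

        dsets, weights = make_cohorts(K=2, p=5, n=40, seed=3)
        fit = fit_joint(dsets, weights, PenaltySpec("magnitude", 0.05, 0.1))
        for k, ds in enumerate(dsets):
            std, rec = weighted_standardize(ds, weights[k])
            fitted_std = rec.y_mean + std.X @ (fit.beta_std[:, k])
            fitted_orig = fit.alpha[k] + ds.X @ fit.beta[:, k]
            assert np.max(np.abs(fitted_std - fitted_orig)) < 1e-10


def test_missing_values_rejected():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(DataFormatError):
        CancerDataset("T", ["g"], X, np.array([1.0, 2.0]), np.array([1, 1]))
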