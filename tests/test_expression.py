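import numpy as np
import pandas as pd
import pytest

from moanet.expression import (ExpressionError, ExpressionMatrix, SampleSheet,
                               binarize, collapse_probes,
                               differential_expression, filter_low_counts,
                               log2_normalize, pca_qc, read_expression)


def make_sheet(n_ctrl=2, n_trt=2):
    return SampleSheet(control=tuple(f"c{i}" for i in range(n_ctrl)),
                       treatment=tuple(f"t{i}" for i in range(n_trt)))


def make_matrix(values, sheet, scale="log2", index=None):
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      columns=list(sheet.samples),
                      index=index or [f"g{i}" for i in range(len(values))])
    return ExpressionMatrix(data=df, scale=scale)


class TestReadExpression:
    def test_parses_and_orders_columns(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts3\ts1\ts2\ts4\n"
                        "g1\t1.5\t2.5\t3.5\t4.5\n"
                        "g2\t5.5\t6.5\t7.5\t8.5\n"
                        "g3\t9.5\t1.5\t2.5\t3.5\n")
        sheet = SampleSheet(control=("s1", "s2"), treatment=("s3", "s4"))
        m = read_expression(path, sheet)
        assert list(m.data.columns) == ["s1", "s2", "s3", "s4"]
        assert m.data.shape == (3, 4)
        assert m.data.loc["g1", "s3"] == 1.5

    def test_missing_sample_named_in_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ts2\ts3\ns\t1\t2\t3\n")
        sheet = SampleSheet(control=("s1", "s2"), treatment=("s3", "s9"))
        with pytest.raises(ExpressionError, match="s9"):
            read_expression(path, sheet)

    def test_all_integer_matrix_inferred_as_counts(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tc0\tc1\tt0\tt1\ng1\t1\t2\t3\t4\ng2\t0\t0\t1\t9\n")
        m = read_expression(path, make_sheet())
        assert m.scale == "counts"

    def test_non_numeric_cell_reports_position(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tc0\tc1\tt0\tt1\ng1\t1\tx\t3\t4\n")
        with pytest.raises(ExpressionError, match="g1.*c1"):
            read_expression(path, make_sheet())


class TestCollapseProbes:
    def test_max_mean_probe_retained(self):
        sheet = make_sheet()
        m = make_matrix([[4, 6, 4, 6], [6, 8, 6, 8]], sheet, index=["p1", "p2"])
        m.rows = "probes"
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        assert list(out.data.index) == ["G"]
        assert out.data.loc["G"].tolist() == [6, 8, 6, 8]

    def test_tie_breaks_to_lexicographically_smallest_probe(self):
        sheet = make_sheet()
        m = make_matrix([[5, 5, 5, 5], [5, 5, 5, 5]], sheet, index=["p2", "p1"])
        m.rows = "probes"
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        # identical values; assert via the retained probe order (p1 first)
        assert list(out.data.index) == ["G"]

    def test_unmapped_probe_dropped_and_empty_map_errors(self):
        sheet = make_sheet()
        m = make_matrix([[1, 2, 3, 4], [5, 6, 7, 8]], sheet, index=["p1", "p3"])
        m.rows = "probes"
        out = collapse_probes(m, {"p1": "G1"})
        assert list(out.data.index) == ["G1"]
        with pytest.raises(ExpressionError):
            collapse_probes(m, {})


class TestFilterLowCounts:
    @pytest.mark.parametrize("ctrl,trt,kept", [
        ((0, 0, 0), (3, 5, 0), True),   # two nonzero in treatment
        ((0, 1, 0), (0, 0, 2), False),  # max one nonzero per group
        ((1, 1, 0), (0, 0, 0), True),   # two nonzero in control
    ])
    def test_rule(self, ctrl, trt, kept):
        sheet = make_sheet(3, 3)
        m = make_matrix([list(ctrl) + list(trt)], sheet, scale="counts")
        out = filter_low_counts(m, sheet)
        assert (len(out.data) == 1) is kept

    def test_requires_counts(self):
        sheet = make_sheet()
        m = make_matrix([[1, 2, 3, 4]], sheet, scale="log2")
        with pytest.raises(ExpressionError):
            filter_low_counts(m, sheet)


class TestLog2Normalize:
    def test_counts_use_pseudocount(self):
        sheet = make_sheet()
        m = make_matrix([[7, 0, 7, 0]], sheet, scale="counts")
        out = log2_normalize(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.data.iloc[0].tolist(), [3.0, 0.0, 3.0, 0.0])

    def test_intensity_floored_at_one(self):
        sheet = make_sheet()
        m = make_matrix([[0.25, 2.0, 4.0, 8.0]], sheet, scale="intensity")
        out = log2_normalize(m)
        np.testing.assert_allclose(out.data.iloc[0].tolist(), [0.0, 1.0, 2.0, 3.0])

    def test_log2_is_noop_with_warning(self):
        sheet = make_sheet()
        m = make_matrix([[1, 2, 3, 4]], sheet, scale="log2")
        with pytest.warns(UserWarning, match="already"):
            out = log2_normalize(m)
        assert out.data.equals(m.data)


class TestPcaQc:
    def _simulate(self, shift, seed=0, n_genes=400, n_shifted=200):
        rng = np.random.default_rng(seed)
        sheet = make_sheet(4, 4)
        X = rng.normal(7, 1, size=(n_genes, 8))
        X[:n_shifted, 4:] += shift
        return make_matrix(X, sheet), sheet

    def test_identical_distributions_not_separated(self):
        m, sheet = self._simulate(shift=0.0, seed=3)
        assert pca_qc(m, sheet).separated is False

    def test_strong_shift_separates_groups(self):
        m, sheet = self._simulate(shift=4.0, seed=3)
        report = pca_qc(m, sheet)
        assert report.separated is True
        assert set(report.coordinates.columns) == {"PC1", "PC2", "group"}

    def test_single_sample_group_rejected_by_sheet(self):
        with pytest.raises(ExpressionError, match="at least 2"):
            SampleSheet(control=("a",), treatment=("b",))


class TestDifferentialExpression:
    def test_equal_group_means_give_zero_fc_and_flat_p(self):
        sheet = make_sheet(3, 3)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, size=(50, 6))
        X = noise.copy()
        X[0] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]  # identical groups
        de = differential_expression(make_matrix(X, sheet), sheet)
        assert de.iloc[0]["log2fc"] == pytest.approx(0.0)
        assert de.iloc[0]["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_prior_df_zero_recovers_ordinary_pooled_t(self):
        from scipy import stats
        sheet = make_sheet(4, 4)
        rng = np.random.default_rng(7)
        X = rng.normal(5, 1, size=(30, 8))
        m = make_matrix(X, sheet)
        de = differential_expression(m, sheet, prior_df=0.0)
        t_ref, p_ref = stats.ttest_ind(X[:, 4:], X[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(de["t_stat"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(de["p_value"].to_numpy(), p_ref, rtol=1e-10)

    def test_permutation_invariance(self):
        sheet = make_sheet(3, 3)
        rng = np.random.default_rng(11)
        X = rng.normal(6, 1, size=(40, 6))
        m = make_matrix(X, sheet)
        de = differential_expression(m, sheet)
        # permute genes
        perm = rng.permutation(40)
        m2 = ExpressionMatrix(data=m.data.iloc[perm], scale="log2")
        de2 = differential_expression(m2, sheet)
        pd.testing.assert_frame_equal(de2.sort_index(), de.sort_index())
        # permute samples within groups
        cols = ["c1", "c0", "c2", "t2", "t0", "t1"]
        m3 = ExpressionMatrix(data=m.data[cols], scale="log2")
        sheet3 = SampleSheet(control=("c1", "c0", "c2"),
                             treatment=("t2", "t0", "t1"))
        de3 = differential_expression(m3, sheet3)
        np.testing.assert_allclose(de3["t_stat"], de["t_stat"], rtol=1e-12)

    def test_zero_variance_equal_means_not_an_error(self):
        sheet = make_sheet(3, 3)
        X = np.ones((1, 6)) * 4.0
        with pytest.warns(UserWarning, match="zero within-group variance"):
            de = differential_expression(make_matrix(X, sheet), sheet)
        assert de.iloc[0]["t_stat"] == 0.0
        assert de.iloc[0]["p_value"] == 1.0

    def test_fdr_respects_bh_monotonicity_and_dominates_p(self):
        sheet = make_sheet(4, 4)
        rng = np.random.default_rng(23)
        X = rng.normal(0, 1, size=(200, 8))
        X[:10, 4:] += 3.0
        de = differential_expression(make_matrix(X, sheet), sheet)
        assert (de["fdr"] >= de["p_value"] - 1e-15).all()
        ordered = de.sort_values("p_value")["fdr"].to_numpy()
        assert (np.diff(ordered) >= -1e-15).all()


class TestBinarize:
    def make_de(self, log2fc, fdr):
        n = len(log2fc)
        return pd.DataFrame({"log2fc": log2fc, "t_stat": np.zeros(n),
                             "p_value": fdr, "fdr": fdr},
                            index=[f"g{i}" for i in range(n)])

    @pytest.mark.parametrize("lfc,fdr,cutoff,expect", [
        (1.2, 0.004, 5e-3, (1, 1, 0)),   # passes both, up
        (0.9, 1e-6, 5e-3, (0, 0, 0)),    # fails FC despite tiny FDR
        (-2.0, 0.003, 1e-2, (1, 0, 1)),  # down-regulated
    ])
    def test_rules(self, lfc, fdr, cutoff, expect):
        de = self.make_de([lfc], [fdr])
        ind = binarize(de, fc_cutoff=2.0, fdr_cutoff=cutoff)
        assert (ind["all"].values["g0"], ind["up"].values["g0"],
                ind["down"].values["g0"]) == expect

    def test_up_plus_down_equals_all(self):
        rng = np.random.default_rng(5)
        de = self.make_de(rng.normal(0, 2, 300), rng.uniform(0, 0.05, 300))
        ind = binarize(de, fdr_cutoff=1e-2)
        n_up = sum(ind["up"].values.values())
        n_down = sum(ind["down"].values.values())
        n_all = sum(ind["all"].values.values())
        assert n_up + n_down == n_all
        for g in de.index:
            assert not (ind["up"].values[g] and ind["down"].values[g])
            if ind["up"].values[g] or ind["down"].values[g]:
                assert ind["all"].values[g] == 1

    def test_invalid_cutoffs(self):
        de = self.make_de([1.0], [0.01])
        with pytest.raises(ValueError):
            binarize(de, fc_cutoff=1.0)
        with pytest.raises(ValueError):
            binarize(de, fdr_cutoff=0.0)
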