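"""QC threshold rule, TMM against a brute-force oracle, unit conversions, gene filters."""

import numpy as np
import pandas as pd
import pytest

from glandscape import qc_normalize as qn
from glandscape.errors import (
    ConfigurationError,
    DegenerateCellError,
    EmptyResultError,
    QCConflictError,
    UnitError,
)
from glandscape.matrix_io import ExpressionMatrix

from conftest import make_matrix


def plate_with_controls(neg_totals, pos_totals, sample_totals):
    """One-gene-per-well-total matrix with labelled control wells."""
    totals = list(sample_totals) + list(neg_totals) + list(pos_totals)
    types = (
        ["sample"] * len(sample_totals)
        + ["neg_control"] * len(neg_totals)
        + ["pos_control"] * len(pos_totals)
    )
    counts = np.array([totals])
    return make_matrix(counts, gene_ids=["g0"], well_type=types)


class TestQCThreshold:
    def test_threshold_is_max_negative_plus_one(self):
        m = plate_with_controls([10, 40], [5000], [100, 60])
        assert qn.qc_threshold(m).threshold == 41

    def test_override_wins_regardless_of_controls(self):
        m = plate_with_controls([10, 40], [30], [100])  # pos 30 < would-be 41
        assert qn.qc_threshold(m, override=25119).threshold == 25119

    def test_positive_control_below_threshold_is_conflict(self):
        m = plate_with_controls([10, 40], [30], [100])
        with pytest.raises(QCConflictError):
            qn.qc_threshold(m)

    def test_no_controls_without_override_is_config_error(self):
        m = plate_with_controls([], [], [100, 200])
        with pytest.raises(ConfigurationError):
            qn.qc_threshold(m)

    def test_contract_on_synthetic_plates(self, plate):
        """Threshold excludes every negative and keeps every positive control."""
        qc = qn.qc_threshold(plate)
        totals = plate.nonspike_totals()
        wt = plate.well_type
        assert (totals[wt == "neg_control"] < qc.threshold).all()
        assert (totals[wt == "pos_control"] >= qc.threshold).all()


class TestFilterCells:
    def test_keeps_cells_at_or_above_threshold(self):
        m = plate_with_controls([40], [5000], [100, 41, 10])
        kept = qn.filter_cells(m, qn.qc_threshold(m))
        assert kept.n_cells == 2

    def test_zero_threshold_keeps_all_samples_but_no_controls(self):
        m = plate_with_controls([1], [5000], [100, 41, 10])
        qc = qn.qc_threshold(m, override=0)
        kept = qn.filter_cells(m, qc)
        assert kept.n_cells == 3
        assert set(kept.well_type) == {"sample"}

    def test_unreachable_threshold_is_empty_result(self):
        m = plate_with_controls([1], [5000], [100])
        with pytest.raises(EmptyResultError):
            qn.filter_cells(m, qn.qc_threshold(m, override=10**9))


def brute_force_tmm_log_factor(obs, ref, trim_m=0.30, trim_a=0.05):
    """Independent trim-then-weighted-mean oracle (sort/slice instead of ranks)."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    n_obs, n_ref = obs.sum(), ref.sum()
    shared = (obs > 0) & (ref > 0)
    o, r = obs[shared], ref[shared]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    drop_m = int(np.floor(n * trim_m))
    drop_a = int(np.floor(n * trim_a))
    keep_by_m = set(np.argsort(m, kind="stable")[drop_m : n - drop_m])
    keep_by_a = set(np.argsort(a, kind="stable")[drop_a : n - drop_a])
    keep = sorted(keep_by_m & keep_by_a)
    return np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])


class TestTMM:
    def test_identical_cells_give_unit_factors(self):
        col = np.array([5, 10, 20, 7, 3])
        m = make_matrix(np.column_stack([col, col, col]))
        factors = qn.tmm_factors(m).tmm_factor
        assert np.allclose(factors, 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        """Cell B = 3 × cell A entrywise: composition identical, factors 1."""
        a = np.array([5, 10, 20, 7, 3, 12, 9, 30, 2, 6])
        m = make_matrix(np.column_stack([a, 3 * a]))
        factors = qn.tmm_factors(m).tmm_factor
        assert np.allclose(factors, 1.0, atol=1e-9)

    def test_matches_brute_force_trim_and_weight_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.integers(1, 200, size=10)
        b = rng.integers(1, 200, size=10)
        m = make_matrix(np.column_stack([a, b]))
        factors = qn.tmm_factors(m).tmm_factor
        # oracle: reference is one of the two cells; factor of the other is
        # 2^(log factor), then both rescaled to geometric mean 1
        log_f = brute_force_tmm_log_factor(b, a)
        expected_other = 2 ** (log_f / 2)  # after gmean rescaling of (0, log_f)
        assert factors.iloc[1] / factors.iloc[0] == pytest.approx(2**log_f, rel=1e-9)
        assert factors.iloc[1] == pytest.approx(expected_other, rel=1e-9)

    def test_scaling_one_cell_leaves_factors_nearly_invariant(self, filtered_plate):
        """Count fractions (hence M, A and the trim) are unchanged by uniform
        scaling of one cell; only the delta-method precision weights shift
        with absolute depth, so factors move by at most a few percent."""
        sub = filtered_plate.subset_cells(filtered_plate.values.columns[:20])
        base = qn.tmm_factors(sub).tmm_factor
        scaled_values = sub.values.copy()
        scaled_values.iloc[:, 0] *= 4
        scaled = sub.with_counts(scaled_values.to_numpy())
        again = qn.tmm_factors(scaled).tmm_factor
        assert np.allclose(base, again, atol=0.05)

    def test_disjoint_support_is_degenerate(self):
        m = make_matrix(np.array([[5, 0], [7, 0], [0, 3], [0, 9]]))
        with pytest.raises(DegenerateCellError):
            qn.tmm_factors(m)


class TestFPKMAndTPM:
    def test_fpkm_closed_form(self):
        m = make_matrix(np.array([[10], [0]]), lengths=[1000, 500])
        norm = qn.NormFactors(
            tmm_factor=pd.Series([1.0], index=m.values.columns),
            library_size=pd.Series([10**6], index=m.values.columns),
        )
        expr = qn.fpkm(m, {"g0": 1000, "g1": 500}, norm)
        assert expr.values.iloc[0, 0] == pytest.approx(10.0)
        assert expr.values.iloc[1, 0] == 0.0

    def test_doubling_effective_size_halves_fpkm(self):
        m = make_matrix(np.array([[10]]), lengths=[1000])
        mk = lambda size: qn.NormFactors(
            tmm_factor=pd.Series([1.0], index=m.values.columns),
            library_size=pd.Series([size], index=m.values.columns),
        )
        one = qn.fpkm(m, {"g0": 1000}, mk(10**6)).values.iloc[0, 0]
        two = qn.fpkm(m, {"g0": 1000}, mk(2 * 10**6)).values.iloc[0, 0]
        assert two == pytest.approx(one / 2)

    def test_missing_length_lists_genes(self):
        m = make_matrix(np.array([[1], [2]]))
        norm = qn.NormFactors(
            tmm_factor=pd.Series([1.0], index=m.values.columns),
            library_size=pd.Series([100], index=m.values.columns),
        )
        with pytest.raises(ValueError, match="g1"):
            qn.fpkm(m, {"g0": 1000}, norm)

    def test_tpm_columns_sum_to_one_million(self, filtered_plate):
        lengths = filtered_plate.gene_table["length_bp"].to_dict()
        expr = qn.tpm(filtered_plate, lengths)
        assert np.allclose(expr.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_tpm_closed_form_two_genes(self):
        m = make_matrix(np.array([[10], [10]]), lengths=[1000, 2000])
        expr = qn.tpm(m, {"g0": 1000, "g1": 2000})
        assert expr.values.iloc[0, 0] == pytest.approx(666666.6667, abs=0.01)
        assert expr.values.iloc[1, 0] == pytest.approx(333333.3333, abs=0.01)

    def test_single_gene_tpm_is_one_million(self):
        m = make_matrix(np.array([[7]]))
        assert qn.tpm(m, {"g0": 1000}).values.iloc[0, 0] == pytest.approx(1e6)

    def test_zero_total_cell_is_error_naming_cell(self):
        m = make_matrix(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError, match="c1"):
            qn.tpm(m, {"g0": 1000, "g1": 1000})


class TestGeneFilters:
    def _expr(self, rows, unit="FPKM"):
        values = pd.DataFrame(
            np.array(rows, dtype=float),
            index=[f"g{i}" for i in range(len(rows))],
            columns=[f"c{j}" for j in range(len(rows[0]))],
        )
        return ExpressionMatrix(values, unit)

    def test_fpkm_filter_keep_and_drop_rules(self):
        expr = self._expr(
            [
                [5, 5, 5, 0, 0],  # 3 qualifying cells → kept
                [5, 5, 0, 0, 0],  # 2 qualifying → dropped
                [0, 0, 0, 0, 0],  # all zero → dropped
                [4, 4, 4, 4, 4],  # threshold inclusive → kept
            ]
        )
        mask = qn.filter_genes_fpkm(expr)
        assert mask.tolist() == [True, False, False, True]

    def test_fpkm_filter_is_idempotent(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng.exponential(5, size=(50, 10)))
        once = qn.filter_genes_fpkm(expr)
        kept = ExpressionMatrix(expr.values.loc[once[once].index], "FPKM")
        twice = qn.filter_genes_fpkm(kept)
        assert twice.all()

    def test_fpkm_filter_rejects_wrong_unit(self):
        with pytest.raises(UnitError):
            qn.filter_genes_fpkm(self._expr([[1, 2, 3]], unit="TPM"))

    def test_low_variability_filter_drops_high_mean_low_cv_gene(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(3, 1, size=(200, 30))
        values[0] = 1e4 + rng.normal(0, 1, 30)  # highest mean, tiniest CV
        expr = self._expr(values, unit="TPM")
        mask = qn.filter_low_variability(expr)
        assert not mask.iloc[0]

    def test_low_variability_filter_keeps_median_mean_gene(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(3, 1, size=(200, 30))
        means = values.mean(axis=1)
        median_gene = int(np.argsort(means)[100])
        values[median_gene] = means[median_gene]  # constant: CV 0, mean median
        expr = self._expr(values, unit="TPM")
        mask = qn.filter_low_variability(expr)
        assert mask.iloc[median_gene]  # AND rule: median mean is not top decile

    def test_low_variability_needs_twenty_genes(self):
        with pytest.raises(ValueError):
            qn.filter_low_variability(self._expr(np.ones((5, 4)), unit="TPM"))

    def test_constant_mean_panel_is_deterministic(self):
        values = np.ones((30, 10))
        expr = self._expr(values, unit="TPM")
        a = qn.filter_low_variability(expr)
        b = qn.filter_low_variability(expr)
        assert a.equals(b)
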