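"""Normalization chain: FPKM/RPM, zero filter, log2(+1), quantile, replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mirnet.containers import (
    CountMatrix,
    ExpressionMatrix,
    MirnetError,
    SampleDesign,
    TransformState,
)
from mirnet.normalize import (
    filter_all_zero,
    fpkm,
    log2_shift,
    normalize_chain,
    quantile_normalize,
    replicate_correlation,
    rpm,
)


def _design(n: int) -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "condition": ["sham" if i % 2 == 0 else "MI" for i in range(n)],
                "stage": ["1D"] * n,
                "replicate": [i // 2 + 1 for i in range(n)],
            }
        )
    )


def _counts(values: np.ndarray, lengths=None, layer="miRNA") -> CountMatrix:
    n_feat, n_samp = values.shape
    df = pd.DataFrame(
        values, index=[f"f{i}" for i in range(n_feat)], columns=[f"s{i}" for i in range(n_samp)]
    )
    ln = None if lengths is None else pd.Series(lengths, index=df.index)
    return CountMatrix(df, _design(n_samp), layer, ln)


class TestFPKM:
    @pytest.mark.parametrize(
        "count,length,col_total,expected",
        [
            (100, 1000, 1_000_000, 100.0),
            (0, 1000, 1_000_000, 0.0),
            (50, 2000, 2_000_000, 12.5),
        ],
    )
    def test_formula(self, count, length, col_total, expected):
        filler = col_total - count
        cm = _counts(
            np.array([[count, count], [filler, filler]]),
            lengths=[length, 1000],
            layer="mRNA",
        )
        expr = fpkm(cm)
        assert expr.values.iloc[0, 0] == pytest.approx(expected)
        assert expr.transform_state is TransformState.LINEAR

    def test_requires_lengths(self):
        cm = _counts(np.ones((2, 2), dtype=int))
        with pytest.raises(MirnetError, match="lengths"):
            fpkm(cm)

    def test_zero_column_total_rejected(self):
        cm = _counts(np.zeros((2, 2), dtype=int), lengths=[1000, 1000], layer="mRNA")
        with pytest.raises(MirnetError, match="zero total"):
            fpkm(cm)

    def test_homogeneous_in_counts_at_fixed_totals(self):
        # scaling one row's count scales its FPKM at fixed column totals
        a = _counts(np.array([[10, 10], [990, 990]]), lengths=[500, 500], layer="mRNA")
        b = _counts(np.array([[30, 30], [970, 970]]), lengths=[500, 500], layer="mRNA")
        ratio = fpkm(b).values.iloc[0, 0] / fpkm(a).values.iloc[0, 0]
        assert ratio == pytest.approx(3.0)


class TestRPM:
    def test_unit_case(self):
        cm = _counts(np.array([[5, 5], [5, 5]]))
        assert rpm(cm).values.iloc[0, 0] == pytest.approx(500_000)

    def test_all_equal_column(self):
        cm = _counts(np.full((4, 2), 7))
        assert np.allclose(rpm(cm).values, 1e6 / 4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(
            np.int64,
            (5, 3),
            elements=st.integers(min_value=0, max_value=10_000),
        ).filter(lambda a: (a.sum(axis=0) > 0).all())
    )
    def test_columns_sum_to_one_million(self, values):
        sums = rpm(_counts(values)).values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(MirnetError, match="zero total"):
            rpm(_counts(np.zeros((3, 2), dtype=int)))


class TestZeroFilter:
    def test_all_zero_row_removed_others_kept(self):
        values = pd.DataFrame(
            {"s0": [0.0, 0.0], "s1": [0.0, 0.1], "s2": [0.0, 0.0], "s3": [0.0, 0.0]},
            index=["dead", "alive"],
        )
        expr = ExpressionMatrix(values, _design(4), "miRNA")
        out = filter_all_zero(expr)
        assert list(out.values.index) == ["alive"]

    def test_surviving_count(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(50, 4)).astype(float)
        vals[rng.choice(50, 10, replace=False)] = 0.0
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(50)], columns=[f"s{i}" for i in range(4)]),
            _design(4),
            "miRNA",
        )
        n_all_zero = int(((vals == 0).all(axis=1)).sum())
        assert filter_all_zero(expr).values.shape[0] == 50 - n_all_zero


class TestLog2Shift:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_values(self, x, expected):
        expr = ExpressionMatrix(
            pd.DataFrame({"s0": [x], "s1": [x]}, index=["f"]), _design(2), "miRNA"
        )
        out = log2_shift(expr)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.transform_state is TransformState.LOG2P1

    def test_negative_rejected(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s0": [-1.0], "s1": [0.0]}, index=["f"]), _design(2), "miRNA"
        )
        with pytest.raises(MirnetError, match="negative"):
            log2_shift(expr)

    def test_strictly_increasing_preserves_column_order_stats(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, size=(20, 2))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(20)], columns=["s0", "s1"]),
            _design(2),
            "miRNA",
        )
        out = log2_shift(expr)
        for col in ("s0", "s1"):
            assert (
                np.argsort(expr.values[col].to_numpy()).tolist()
                == np.argsort(out.values[col].to_numpy()).tolist()
            )

    def test_state_precondition(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s0": [1.0], "s1": [1.0]}, index=["f"]),
            _design(2),
            "miRNA",
            TransformState.LOG2P1,
        )
        with pytest.raises(MirnetError, match="transform state"):
            log2_shift(expr)


def _log2_expr(values: np.ndarray) -> ExpressionMatrix:
    n_feat, n_samp = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values, index=[f"f{i}" for i in range(n_feat)], columns=[f"s{i}" for i in range(n_samp)]
        ),
        _design(n_samp),
        "miRNA",
        TransformState.LOG2P1,
    )


class TestQuantileNormalize:
    def test_worked_two_by_two(self):
        out = quantile_normalize(_log2_expr(np.array([[1.0, 4.0], [2.0, 3.0]])))
        assert out.values.values.tolist() == [[2.0, 3.0], [3.0, 2.0]]

    def test_identical_columns_fixed_point(self):
        vals = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        out = quantile_normalize(_log2_expr(vals))
        assert np.allclose(out.values.to_numpy(), vals)

    def test_single_column_identity(self):
        vals = np.array([[5.0], [1.0]])
        design = SampleDesign(
            pd.DataFrame(
                {"sample_id": ["s0"], "condition": ["sham"], "stage": ["1D"], "replicate": [1]}
            )
        )
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=["a", "b"], columns=["s0"]),
            design,
            "miRNA",
            TransformState.LOG2P1,
        )
        out = quantile_normalize(expr)
        assert np.allclose(out.values.to_numpy(), vals)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(
            np.float64,
            (6, 4),
            elements=st.floats(0, 20, allow_nan=False, width=32),
            unique=True,  # tie-free columns: the exact-multiset contract
        )
    )
    def test_idempotent_and_identical_multisets(self, vals):
        once = quantile_normalize(_log2_expr(vals))
        cols = [np.sort(once.values[c].to_numpy()) for c in once.values.columns]
        for c in cols[1:]:
            assert np.allclose(cols[0], c)
        again = quantile_normalize(
            ExpressionMatrix(once.values, once.design, once.layer, TransformState.LOG2P1)
        )
        assert np.allclose(once.values.to_numpy(), again.values.to_numpy())

    def test_within_column_ties_share_span_mean(self):
        # two tied entries at the bottom of column 0 share the mean of the
        # substituted reference values for ranks 1-2
        vals = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(_log2_expr(vals)).values.to_numpy()
        ref = np.sort(vals, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[2, 0] == pytest.approx(ref[2])
        assert np.allclose(out[:, 1], ref)

    def test_total_sum_preserved(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 10, size=(8, 3))
        out = quantile_normalize(_log2_expr(vals))
        assert out.values.to_numpy().sum() == pytest.approx(vals.sum())


class TestReplicateCorrelation:
    def test_duplicated_column_r2_one(self):
        col = np.array([1.0, 5.0, 3.0, 8.0])
        vals = np.stack([col, col, col + np.array([0.1, -0.2, 0.3, 0.0]), col], axis=1)
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(4)], columns=[f"s{i}" for i in range(4)]),
            _design(4),
            "miRNA",
        )
        qc = replicate_correlation(expr)
        assert (qc["mean_r2"] <= 1.0 + 1e-12).all()
        mi = qc[qc["condition"] == "MI"].iloc[0]  # columns s1, s3 are identical
        assert mi["mean_r2"] == pytest.approx(1.0)

    def test_constant_column_flagged_not_averaged(self):
        vals = np.array([[1.0, 2.0, 1.0, 2.0]] * 3)  # every column constant
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(3)], columns=[f"s{i}" for i in range(4)]),
            _design(4),
            "miRNA",
        )
        qc = replicate_correlation(expr)
        assert (qc["n_undefined"] == 1).all()
        assert qc["mean_r2"].isna().all()

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(500, 4))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(500)], columns=[f"s{i}" for i in range(4)]),
            _design(4),
            "miRNA",
        )
        qc = replicate_correlation(expr)
        assert (qc["mean_r2"] < 0.05).all()

    def test_synthetic_replicates_highly_correlated(self, bundle):
        from mirnet import io
        from mirnet.normalize import normalize_chain
        design = io.read_design(bundle.design)
        counts = io.read_counts(bundle.mrna_counts, design, "mRNA")
        qc = replicate_correlation(normalize_chain(counts))
        assert qc["mean_r2"].mean() > 0.99


def test_normalize_chain_end_state(bundle):
    from mirnet import io
    design = io.read_design(bundle.design)
    counts = io.read_counts(bundle.mirna_counts, design, "miRNA")
    expr = normalize_chain(counts)
    assert expr.transform_state is TransformState.LOG2P1_QUANTILE
    expr_nq = normalize_chain(counts, quantile=False)
    assert expr_nq.transform_state is TransformState.LOG2P1
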