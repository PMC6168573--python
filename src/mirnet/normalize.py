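"""Quantification and normalization chain for both expression layers.

The chain is fixed, in this order:

1. unit normalization — FPKM for mRNA (length- and depth-normalized) or RPM
   for miRNA (depth-normalized);
2. removal of features that are zero in every sample;
3. +1 pseudocount followed by log2;
4. quantile normalization across samples.

Each step enforces its precondition through the matrix's transform state, so
a downstream stage cannot silently consume half-normalized values.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    ExpressionMatrix,
    MirnetError,
    SampleDesign,
    TransformState,
)


def fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of feature per million mapped fragments.

    value = count / ((length / 1e3) * (column_total / 1e6)).
    """
    if counts.layer != "mRNA" or counts.lengths is None:
        raise MirnetError("FPKM requires an mRNA count matrix with feature lengths")
    totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise MirnetError(f"zero total mapped reads in samples: {bad}")
    kb = counts.lengths.astype(float) / 1e3
    per_million = totals.astype(float) / 1e6
    values = counts.counts.astype(float).div(per_million, axis=1).div(kb, axis=0)
    return ExpressionMatrix(values, counts.design, "mRNA", TransformState.LINEAR)


def rpm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per million: count / column_total * 1e6.

    Before any row filtering every output column sums to exactly 1e6 (up to
    float round-off).
    """
    totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise MirnetError(f"zero total reads in samples: {bad}")
    values = counts.counts.astype(float).div(totals.astype(float), axis=1) * 1e6
    return ExpressionMatrix(values, counts.design, counts.layer, TransformState.LINEAR)


def filter_all_zero(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features whose value is exactly 0 in every sample; keep row order."""
    expr.require_state(TransformState.LINEAR)
    keep = (expr.values != 0).any(axis=1)
    return ExpressionMatrix(expr.values.loc[keep], expr.design, expr.layer, TransformState.LINEAR)


def log2_shift(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(value + 1); maps 0 -> 0 and is strictly increasing."""
    expr.require_state(TransformState.LINEAR)
    if (expr.values.values < 0).any():
        raise MirnetError("negative expression values; log2(+1) undefined for the chain")
    values = np.log2(expr.values + 1.0)
    return expr.advanced(values, TransformState.LOG2P1)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples.

    Each column's rank-r value is replaced by the mean of the r-th order
    statistics over all columns; within-column ties receive the mean of the
    substituted values over the tied span. A single-column matrix is returned
    unchanged. The operation is idempotent.
    """
    expr.require_state(TransformState.LOG2P1)
    df = expr.values
    if df.shape[1] <= 1:
        return expr.advanced(df.copy(), TransformState.LOG2P1_QUANTILE)
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.sort(arr, axis=0).mean(axis=1)  # mean of order statistics per rank
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = ref.copy()
        # average the reference values over each tied run of the sorted column
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = ref[start:end].mean()
                start = end
        out[idx, j] = assigned
    values = pd.DataFrame(out, index=df.index, columns=df.columns)
    return expr.advanced(values, TransformState.LOG2P1_QUANTILE)


def normalize_chain(counts: CountMatrix, quantile: bool = True) -> ExpressionMatrix:
    """Run the full chain for a layer: FPKM/RPM -> zero-filter -> log2(+1) [-> quantile]."""
    unit = fpkm(counts) if counts.layer == "mRNA" else rpm(counts)
    logged = log2_shift(filter_all_zero(unit))
    return quantile_normalize(logged) if quantile else logged


def replicate_correlation(expr: ExpressionMatrix, design: SampleDesign | None = None) -> pd.DataFrame:
    """Mean pairwise squared Pearson correlation of replicates per (condition, stage).

    Pairs in which either column is constant have an undefined correlation;
    they are flagged (n_undefined) and excluded from the group mean.
    """
    design = design or expr.design
    rows = []
    groups = design.table.groupby(["condition", "stage"], sort=False)
    for (condition, stage), sub in groups:
        cols = list(sub["sample_id"])
        if len(cols) < 2:
            raise MirnetError(
                f"group ({condition}, {stage}) has <2 replicates; cannot compute correlation"
            )
        r2s = []
        undefined = 0
        for a, b in itertools.combinations(cols, 2):
            x = expr.values[a].to_numpy(dtype=float)
            y = expr.values[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                undefined += 1
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2s.append(r * r)
        rows.append(
            {
                "condition": condition,
                "stage": stage,
                "mean_r2": float(np.mean(r2s)) if r2s else np.nan,
                "n_pairs": len(r2s),
                "n_undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
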