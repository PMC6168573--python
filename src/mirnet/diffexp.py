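"""Stage-wise differential expression: independent t-test + fold change.

A feature is called "up" at a stage when its BH-adjusted p-value is below
``alpha`` (default 0.05) AND its MI-vs-sham fold change exceeds
``fc_threshold`` (default 2, i.e. |log2FC| > 1); "down" symmetrically; "ns"
otherwise. The t-test runs on the log2 normalized values; fold change is
computed on the linear (2^x) group means, i.e. on the pseudocounted linear
scale. Adjustment is BH across all features within each stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DETable, ExpressionMatrix, MirnetError, SampleDesign, TransformState


def two_group_ttest(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided independent two-sample t-test (Welch by default).

    Degenerate contract when both samples have zero variance: p = 1 if the
    means are equal, p = 0 if they differ (the data leave no doubt either way).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MirnetError("t-test requires at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf if np.mean(b) > np.mean(a) else -np.inf, 0.0
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    return float(t), float(p)


def fold_change(mean_sham: float, mean_mi: float) -> tuple[float, float]:
    """Return (signed fold change, log2fc) for MI vs sham linear means.

    The signed reporting convention: FC = 2^log2fc when log2fc >= 0, else
    -2^(-log2fc), so a 4-fold drop prints as -4.
    """
    if mean_sham <= 0 or mean_mi <= 0:
        raise MirnetError("fold change requires positive group means")
    log2fc = float(np.log2(mean_mi / mean_sham))
    fc = float(2.0**log2fc) if log2fc >= 0 else float(-(2.0 ** (-log2fc)))
    return fc, log2fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise MirnetError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    expr: ExpressionMatrix,
    stage: str,
    design: SampleDesign | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    equal_var: bool = False,
) -> DETable:
    """Call DE features for one stage (MI vs sham).

    ``expr`` must be fully normalized (log2p1_quantile). Vectorized over
    features; zero-variance features fall back to the degenerate t contract.
    """
    expr.require_state(TransformState.LOG2P1_QUANTILE)
    design = design or expr.design
    design.require_stage(stage)
    sham_cols = design.samples("sham", stage)
    mi_cols = design.samples("MI", stage)
    if len(sham_cols) < 2 or len(mi_cols) < 2:
        raise MirnetError(f"stage {stage!r} needs >=2 replicates per condition")

    sham = expr.values[sham_cols].to_numpy(dtype=float)
    mi = expr.values[mi_cols].to_numpy(dtype=float)

    # t-test on log2 values; near-constant rows trigger harmless precision
    # warnings inside scipy and are overridden by the degenerate contract below
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_raw = stats.ttest_ind(mi, sham, axis=1, equal_var=equal_var)
    var0 = (sham.var(axis=1) == 0) & (mi.var(axis=1) == 0)
    if var0.any():
        equal_means = np.isclose(sham[var0].mean(axis=1), mi[var0].mean(axis=1))
        p_raw = np.asarray(p_raw)
        p_raw[np.where(var0)[0][equal_means]] = 1.0
        p_raw[np.where(var0)[0][~equal_means]] = 0.0
    p_raw = np.nan_to_num(np.asarray(p_raw, dtype=float), nan=1.0)

    # fold change on linear means of back-transformed values
    lin_sham = np.power(2.0, sham).mean(axis=1)
    lin_mi = np.power(2.0, mi).mean(axis=1)
    log2fc = np.log2(lin_mi / lin_sham)
    fc = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))

    p_adj = bh_adjust(p_raw)
    log2_thr = np.log2(fc_threshold)
    direction = np.where(
        (p_adj < alpha) & (log2fc > log2_thr),
        "up",
        np.where((p_adj < alpha) & (log2fc < -log2_thr), "down", "ns"),
    )

    records = pd.DataFrame(
        {
            "feature_id": expr.values.index,
            "stage": stage,
            "mean_sham": lin_sham,
            "mean_mi": lin_mi,
            "log2fc": log2fc,
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    return DETable(records, alpha=alpha, fc_threshold=fc_threshold)


def call_differential_all_stages(
    expr: ExpressionMatrix,
    design: SampleDesign | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    equal_var: bool = False,
) -> DETable:
    """Run :func:`call_differential` for every stage in the design."""
    design = design or expr.design
    tables = [
        call_differential(expr, stage, design, alpha, fc_threshold, equal_var)
        for stage in design.stages
    ]
    return DETable.concat(tables)
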