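"""Condition-wise statistical comparisons for activity/abundance matrices.

Comparisons follow the study design of a two-condition ("wet"/"dry")
incubation with a few replicates per condition: Welch t-tests on normalized
counts, per-entity log2 fold changes with significance flags, and squared
Pearson correlations.  The differential comparison is a documented
simplification of count-model (DESeq2-style) differential expression — it
keeps the same report structure (log2FC wet/dry, p, significance at
p < 0.05, BH-adjusted p) without the negative-binomial shrinkage model, and
says so in its output metadata.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05

DIFFERENTIAL_METHOD_NOTE = (
    "welch-t on normalized values with epsilon-offset log2FC; "
    "not a negative-binomial (DESeq2-style) model"
)


def t_test(group_a: Sequence[float],
           group_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test, two-sided.

    Returns (t, p) with Welch–Satterthwaite degrees of freedom.  When both
    groups have zero variance and equal means the result is (0, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t_test requires n >= 2 per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def differential(matrix: pd.DataFrame, conditions: Mapping[str, str],
                 alpha: float = DEFAULT_ALPHA,
                 condition_a: str = "wet",
                 condition_b: str = "dry") -> pd.DataFrame:
    """Per-entity log2 fold change (wet relative to dry) with significance.

    ``matrix`` is entities x samples (non-negative normalized values);
    ``conditions`` maps each sample (column) to its condition label.
    log2FC = log2((mean_wet + eps) / (mean_dry + eps)) with eps the smallest
    positive matrix value divided by 10.  p-values come from the Welch
    t-test on the normalized values; ``significant`` flags raw p < alpha and
    ``significant_adj`` flags Benjamini–Hochberg adjusted p < alpha.
    Entities absent (all-zero) in every sample are excluded.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("matrix must be non-negative")
    unmapped = [s for s in matrix.columns if s not in conditions]
    if unmapped:
        raise ValueError(f"samples without a condition label: {unmapped}")
    cols_a = [s for s in matrix.columns if conditions[s] == condition_a]
    cols_b = [s for s in matrix.columns if conditions[s] == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("differential requires >= 2 samples per condition")
    present = matrix.loc[(matrix != 0).any(axis=1)]
    positive = present.to_numpy()
    positive = positive[positive > 0]
    eps = positive.min() / 10.0 if positive.size else 1e-9
    rows = []
    for entity, row in present.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        t, p = t_test(a, b)
        log2fc = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
        rows.append({"entity": entity, "log2fc": log2fc, "t": t, "p": p})
    result = pd.DataFrame(rows, columns=["entity", "log2fc", "t", "p"])
    if not result.empty:
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["p"] < alpha
        result["significant_adj"] = result["p_adj"] < alpha
    else:
        result["p_adj"] = []
        result["significant"] = []
        result["significant_adj"] = []
    result.attrs["method"] = DIFFERENTIAL_METHOD_NOTE
    result.attrs["epsilon"] = float(eps)
    return result


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Squared Pearson correlation; None when either variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3 or len(x) != len(y):
        raise ValueError("correlation_r2 requires n >= 3 paired values")
    if x.std() == 0.0 or y.std() == 0.0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
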