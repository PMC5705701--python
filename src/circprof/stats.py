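"""Class-wise differential expression and correlation statistics.

Differential expression between tumor risk classes uses the two-sided
Wilcoxon rank-sum test on CPM (exact enumeration when the smaller group
has <= 8 samples and there are no ties, otherwise the normal
approximation with tie and continuity correction), with
Benjamini-Hochberg control at FDR < 0.1 within each analysis family.
The sign convention is log2FC > 0 for higher expression in class 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_GROUP = 8


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaNs are preserved and excluded from the family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def ranksum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value with the documented branching.

    Exact when min(n, m) <= 8 and the pooled data has no ties; normal
    approximation with tie and continuity correction otherwise.  A
    constant pooled sample returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if min(len(x), len(y)) <= EXACT_MAX_GROUP and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _group_arrays(matrix: pd.DataFrame, labels: pd.Series, a, b):
    labels = labels.reindex(matrix.columns)
    cols_a = labels.index[labels == a]
    cols_b = labels.index[labels == b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {len(cols_a)} vs {len(cols_b)}"
        )
    return matrix[cols_a].to_numpy(float), matrix[cols_b].to_numpy(float)


def wilcoxon_de(
    matrix: pd.DataFrame,
    labels: pd.Series,
    class_a=1,
    class_b=2,
    fdr_level: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Row-wise rank-sum differential expression between two classes.

    ``matrix`` is feature x sample (CPM or circular-to-linear ratios);
    ``labels`` maps sample id to class.  Returns one row per feature:
    log2_fold_change (class_a over class_b, pseudocount added to both
    means), p_value, q_value (BH across tested features), significant,
    and a ``constant`` flag for rows with no variation (p set to 1).
    """
    xa, xb = _group_arrays(matrix, labels, class_a, class_b)
    n_a, n_b = xa.shape[1], xb.shape[1]
    pooled = np.concatenate([xa, xb], axis=1)
    constant = np.all(pooled == pooled[:, :1], axis=1)

    p = np.ones(len(matrix))
    todo = ~constant
    if todo.any():
        if min(n_a, n_b) <= EXACT_MAX_GROUP:
            p[todo] = [ranksum_test(x, y) for x, y in zip(xa[todo], xb[todo])]
        else:
            res = stats.mannwhitneyu(
                xa[todo], xb[todo], axis=1, alternative="two-sided",
                method="asymptotic",
            )
            p[todo] = res.pvalue
    log2fc = np.log2(
        (xa.mean(axis=1) + pseudocount) / (xb.mean(axis=1) + pseudocount)
    )
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "significant": q < fdr_level,
            "constant": constant,
        },
        index=matrix.index,
    )


def ratio_de(
    ratios: pd.DataFrame,
    labels: pd.Series,
    class_a=1,
    class_b=2,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Differential expression of circular-to-linear ratios.

    Ratios are strictly positive so no pseudocount is added to the fold
    change.
    """
    return wilcoxon_de(
        ratios, labels, class_a=class_a, class_b=class_b,
        fdr_level=fdr_level, pseudocount=0.0,
    )


def total_expression_comparison(
    cpm: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample total circRNA CPM by class with pairwise rank-sum tests."""
    labels = labels.reindex(cpm.columns)
    totals = cpm.sum(axis=0)
    classes = sorted(labels.dropna().unique())
    summary = pd.DataFrame(
        {
            "risk_class": classes,
            "n_samples": [int((labels == c).sum()) for c in classes],
            "median_total_cpm": [
                float(totals[labels == c].median()) for c in classes
            ],
            "mean_total_cpm": [float(totals[labels == c].mean()) for c in classes],
        }
    )
    rows = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            ta, tb = totals[labels == a], totals[labels == b]
            if len(ta) < 2 or len(tb) < 2:
                rows.append(
                    {"class_a": a, "class_b": b, "p_value": float("nan"),
                     "insufficient_n": True}
                )
                continue
            rows.append(
                {"class_a": a, "class_b": b,
                 "p_value": ranksum_test(ta, tb), "insufficient_n": False}
            )
    return summary, pd.DataFrame(rows)


def _spearman_by_row(
    matrix: pd.DataFrame, partner: pd.Series, partner_name: str, fdr_level: float
) -> pd.DataFrame:
    rows = []
    partner = partner.reindex(matrix.columns)
    degenerate_partner = partner.nunique() <= 1
    for cid, values in matrix.iterrows():
        if degenerate_partner or values.nunique() <= 1:
            rows.append((cid, partner_name, np.nan, np.nan, True))
            continue
        rho, p = stats.spearmanr(values.to_numpy(), partner.to_numpy())
        rows.append((cid, partner_name, float(rho), float(p), False))
    out = pd.DataFrame(
        rows, columns=["circ_id", "partner", "spearman_rho", "p_value", "degenerate"]
    )
    out["q_value"] = bh_adjust(out["p_value"])
    out["significant"] = out["q_value"] < fdr_level
    return out


def regulator_correlation(
    cpm: pd.DataFrame,
    gene_expression: pd.DataFrame,
    regulators: tuple[str, ...] = ("ADAR1", "QKI"),
    fdr_level: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-circRNA Spearman correlation with biogenesis regulators.

    BH correction is applied within each regulator family.  Also returns
    the global Spearman correlation of total circRNA expression with each
    regulator (ADAR1 edits and melts the paired intronic stems that drive
    circularization; Quaking promotes circle formation).
    """
    shared = [s for s in cpm.columns if s in gene_expression.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched samples, got {len(shared)}")
    cpm = cpm[shared]
    per_circ = []
    global_rows = []
    totals = cpm.sum(axis=0)
    for gene in regulators:
        if gene not in gene_expression.index:
            raise KeyError(f"regulator {gene!r} absent from expression matrix")
        expr = gene_expression.loc[gene, shared]
        per_circ.append(_spearman_by_row(cpm, expr, gene, fdr_level))
        rho, p = stats.spearmanr(totals.to_numpy(), expr.to_numpy())
        global_rows.append(
            {"partner": gene, "total_expression_rho": float(rho), "p_value": float(p)}
        )
    return pd.concat(per_circ, ignore_index=True), pd.DataFrame(global_rows)


def eortc_correlation(
    cpm: pd.DataFrame, eortc: pd.Series, fdr_level: float = 0.1
) -> pd.DataFrame:
    """Per-circRNA Spearman correlation with the EORTC progression score."""
    shared = [s for s in cpm.columns if s in eortc.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched samples, got {len(shared)}")
    return _spearman_by_row(cpm[shared], eortc[shared], "EORTC", fdr_level)
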