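"""Ortholog-pair expression agreement between the human and mouse arms.

Three complementary views of cross-species concordance:

* per condition: correlate the per-gene group summary (median log expression
  per medium x timepoint cell) of human vs mouse across all ortholog pairs —
  one correlation per condition, 16 in total;
* per gene: correlate a pair's 16 human group medians against its 16 mouse
  group medians — one correlation per ortholog pair, used to rank the most
  concordant genes;
* conservation: rank-correlate the per-pair expression correlation against
  % global sequence identity, testing whether conserved sequence predicts
  conserved regulation.

Because donor effects dominate the human arm, expression is donor-centred
(an additive subject + condition-group model, group means preserved) before
any between-species comparison; the mouse arm passes through the same
operator with small effect.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import ExpressionMatrix
from .design import MEDIUM_ORDER, TIMEPOINTS

__all__ = [
    "donor_center",
    "group_medians",
    "resolve_orthologs",
    "pair_correlations",
    "condition_correlations",
    "correlation_vs_identity",
    "top_pairs",
    "GROUP_ORDER",
]

#: the 16 condition groups in canonical order
GROUP_ORDER = tuple(f"{m}_{t}h" for m in MEDIUM_ORDER for t in TIMEPOINTS)


def _included(metadata: pd.DataFrame) -> pd.DataFrame:
    return metadata[metadata["status"] == "included"]


def donor_center(expr: ExpressionMatrix, metadata: pd.DataFrame) -> ExpressionMatrix:
    """Remove subject (donor batch) effects, preserving condition-group means.

    Per gene, an additive least-squares model ``subject + group`` is fitted
    with sum-to-zero subject contrasts and the fitted subject component is
    subtracted.  On a balanced design the group means are unchanged.
    """
    dead = set(metadata["subject_id"]) - set(_included(metadata)["subject_id"])
    if dead:
        raise ValueError(f"subject(s) with all samples excluded: {sorted(dead)}")
    meta = _included(metadata).set_index("sample_id")
    cols = [c for c in expr.sample_ids if c in meta.index]
    meta = meta.loc[cols]
    if meta["subject_id"].nunique() < 2:
        return ExpressionMatrix(expr.values[cols].copy(), expr.pseudocount,
                                expr.library_sizes[cols])

    group = meta["medium"].astype(str) + "_" + meta["timepoint_h"].astype(str) + "h"
    G = pd.get_dummies(group, dtype=float).to_numpy()
    subj = pd.get_dummies(meta["subject_id"], dtype=float)
    # sum-to-zero coding: last subject = -(sum of others)
    S = subj.iloc[:, :-1].to_numpy() - subj.iloc[:, [-1]].to_numpy()
    X = np.hstack([G, S])
    pinv = np.linalg.pinv(X)
    Y = expr.values[cols].to_numpy().T  # samples x genes
    beta = pinv @ Y
    subj_part = S @ beta[G.shape[1]:, :]
    corrected = (Y - subj_part).T
    vals = pd.DataFrame(corrected, index=expr.gene_ids, columns=cols)
    return ExpressionMatrix(vals, expr.pseudocount, expr.library_sizes[cols])


def group_medians(expr: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Median expression per gene per (medium, timepoint) group.

    Returns a genes x 16 frame in canonical group order; groups with no
    included sample appear as all-NaN columns (flagged, never imputed).
    """
    meta = _included(metadata)
    group = meta["medium"].astype(str) + "_" + meta["timepoint_h"].astype(str) + "h"
    out = pd.DataFrame(index=expr.gene_ids, columns=list(GROUP_ORDER), dtype=float)
    for g, sub in meta.groupby(group.to_numpy()):
        cols = [s for s in sub["sample_id"] if s in expr.values.columns]
        if cols:
            out[g] = expr.values[cols].median(axis=1)
    empty = [g for g in GROUP_ORDER if out[g].isna().all()]
    if empty:
        warnings.warn(f"empty condition group(s): {empty}", stacklevel=2)
    return out


def resolve_orthologs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Reduce a possibly many-to-many ortholog map to one-to-one.

    Keeps, per gene on either side, the partner with highest % identity;
    ties break by gene id.  Input needs columns ``gene_h``, ``gene_m``,
    ``pct_identity``.
    """
    p = pairs.sort_values(
        ["pct_identity", "gene_h", "gene_m"], ascending=[False, True, True],
        kind="mergesort",
    )
    p = p.drop_duplicates("gene_h", keep="first").drop_duplicates("gene_m", keep="first")
    if ((p["pct_identity"] < 0) | (p["pct_identity"] > 100)).any():
        raise ValueError("pct_identity must lie in [0, 100]")
    return p.reset_index(drop=True)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pair_correlations(
    gm_h: pd.DataFrame,
    gm_m: pd.DataFrame,
    pairs: pd.DataFrame,
    min_groups: int = 3,
) -> pd.DataFrame:
    """Per ortholog pair: correlation of its condition-group medians.

    Pearson on the log-scale medians and Spearman on their ranks across the
    (up to 16) groups non-missing in both species.  Pairs with fewer than
    ``min_groups`` shared groups or zero variance in either vector get NaN
    correlations with a reason code.
    """
    shared = [g for g in GROUP_ORDER if g in gm_h.columns and g in gm_m.columns]
    H = gm_h.loc[pairs["gene_h"], shared].to_numpy()
    M = gm_m.loc[pairs["gene_m"], shared].to_numpy()
    n = len(pairs)
    pearson = np.full(n, np.nan)
    spearman = np.full(n, np.nan)
    n_groups = np.zeros(n, dtype=int)
    reasons = np.array([""] * n, dtype=object)
    for i in range(n):
        ok = ~(np.isnan(H[i]) | np.isnan(M[i]))
        n_groups[i] = ok.sum()
        if n_groups[i] < min_groups:
            reasons[i] = "too_few_groups"
            continue
        x, y = H[i, ok], M[i, ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            reasons[i] = "zero_variance"
            continue
        pearson[i] = np.corrcoef(x, y)[0, 1]
        spearman[i] = _spearman(x, y)
    out = pairs[["gene_h", "gene_m"]].copy().reset_index(drop=True)
    if "pct_identity" in pairs.columns:
        out["pct_identity"] = pairs["pct_identity"].to_numpy()
    out["pearson_r"] = pearson
    out["spearman_rho"] = spearman
    out["n_groups"] = n_groups
    out["reason"] = reasons
    return out


def condition_correlations(
    expr_h: ExpressionMatrix,
    expr_m: ExpressionMatrix,
    metadata_h: pd.DataFrame,
    metadata_m: pd.DataFrame,
    pairs: pd.DataFrame,
    summary: str = "median",
) -> pd.DataFrame:
    """Per condition: cross-gene correlation of human vs mouse expression.

    For each of the 16 (medium, timepoint) groups, the per-gene group summary
    (median by default, mean optionally) of each species is correlated across
    all ortholog pairs.  Returns 16 rows of (condition, pearson_r,
    spearman_rho, n_pairs).
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")

    def _summaries(expr, metadata):
        meta = _included(metadata)
        group = meta["medium"].astype(str) + "_" + meta["timepoint_h"].astype(str) + "h"
        out = pd.DataFrame(index=expr.gene_ids, columns=list(GROUP_ORDER), dtype=float)
        for g, sub in meta.groupby(group.to_numpy()):
            cols = [s for s in sub["sample_id"] if s in expr.values.columns]
            if cols:
                block = expr.values[cols]
                out[g] = block.median(axis=1) if summary == "median" else block.mean(axis=1)
        return out

    sh = _summaries(expr_h, metadata_h).loc[pairs["gene_h"]].to_numpy()
    sm = _summaries(expr_m, metadata_m).loc[pairs["gene_m"]].to_numpy()
    rows = []
    for j, g in enumerate(GROUP_ORDER):
        x, y = sh[:, j], sm[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rho = _spearman(x[ok], y[ok])
        else:
            r = rho = np.nan
        rows.append({"condition": g, "pearson_r": r, "spearman_rho": rho,
                     "n_pairs": int(ok.sum())})
    return pd.DataFrame(rows)


def correlation_vs_identity(
    pair_corr: pd.DataFrame, min_pairs: int = 10
) -> tuple[pd.DataFrame, float, float]:
    """Rank correlation between expression correlation and sequence identity.

    Returns the scatter table (pairs with defined Pearson r) and the
    Spearman (rho, p) between ``pearson_r`` and ``pct_identity`` — the test
    of whether highly conserved genes show higher expression correlation.
    Constant identity gives NaN rho.
    """
    if "pct_identity" not in pair_corr.columns:
        raise ValueError("pair correlations carry no pct_identity column")
    tab = pair_corr.dropna(subset=["pearson_r", "pct_identity"]).reset_index(drop=True)
    if len(tab) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs with defined correlations, "
                         f"got {len(tab)}")
    if np.ptp(tab["pct_identity"].to_numpy()) == 0:
        warnings.warn("constant sequence identity; rank correlation undefined",
                      stacklevel=2)
        return tab, float("nan"), float("nan")
    rho, p = stats.spearmanr(tab["pearson_r"], tab["pct_identity"])
    return tab, float(rho), float(p)


def top_pairs(pair_corr: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Top-k ortholog pairs by Pearson correlation of group-median expression.

    Ties break by % identity (descending, when present) then human gene id.
    Asking for more pairs than have defined correlations returns all with a
    warning.
    """
    defined = pair_corr.dropna(subset=["pearson_r"])
    if k > len(defined):
        warnings.warn(f"k={k} exceeds {len(defined)} defined pairs; returning all",
                      stacklevel=2)
        k = len(defined)
    by = ["pearson_r"] + (["pct_identity"] if "pct_identity" in defined.columns else [])
    asc = [False] * len(by) + [True]
    ranked = defined.sort_values(by + ["gene_h"], ascending=asc, kind="mergesort")
    return ranked.head(k).reset_index(drop=True)
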