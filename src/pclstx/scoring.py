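"""Sign scoring of contrasts and cross-species gene ranking.

Each of a species' 14 nutrient-vs-control contrasts is collapsed to a sign
in {-1, 0, +1}: the sign of the log2 fold change when the contrast passes
both the significance gate (BH-adjusted p <= alpha) and the fold-change gate
(|log2FC| >= threshold), else 0.  Three per-gene statistics summarise the
sign table across contrasts:

* ``sum of signs`` per species (range [-14, 14]) and combined over both
  species (range [-28, 28]) — consistent regulation across nutrient
  conditions;
* ``divergence`` = sum over matched contrasts of |sign_h - sign_m|
  (range [0, 28]) — opposite regulation between species;
* ``sum_score`` = |sum over contrasts of log2FC * (-log10 p_adj)| — a
  magnitude- and significance-weighted ranking score.

Genes whose absolute combined sum reaches a selection threshold (default 8)
are retained and ranked by the weighted score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import DEResults, PADJ_FLOOR

__all__ = [
    "sign_of_contrast",
    "sign_table",
    "sum_of_signs",
    "combined_sum",
    "divergence_score",
    "weighted_sum_score",
    "build_gene_scores",
    "select_and_rank",
    "score_histogram",
    "N_CONTRASTS",
]

#: contrasts per species: 7 non-control media x 2 timepoints
N_CONTRASTS = 14


def sign_of_contrast(
    log2fc: float | np.ndarray,
    p_adj: float | np.ndarray,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> int | np.ndarray:
    """Sign in {-1, 0, +1} of one contrast under both gates.

    Returns sign(log2fc) iff ``p_adj <= alpha`` and ``|log2fc| >=
    lfc_threshold``; otherwise 0.  Missing statistics give 0.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    sig = (p_adj <= alpha) & (np.abs(log2fc) >= lfc_threshold)
    out = np.where(sig & ~np.isnan(log2fc), np.sign(log2fc), 0.0).astype(int)
    return out if out.ndim else int(out)


def sign_table(
    results: DEResults | pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene x contrast table of signs from long-form contrast results."""
    table = results.table if isinstance(results, DEResults) else results
    signs = sign_of_contrast(
        table["log2fc"].to_numpy(), table["p_adj"].to_numpy(), lfc_threshold, alpha
    )
    long = table[["gene_id", "contrast_id"]].copy()
    long["sign"] = signs
    wide = long.pivot(index="gene_id", columns="contrast_id", values="sign")
    # preserve the contrast order of the input
    return wide[list(dict.fromkeys(table["contrast_id"]))]


def _check_vector(signs, expected_length: int | None) -> np.ndarray:
    v = np.asarray(signs)
    if expected_length is not None and v.shape[-1] != expected_length:
        raise ValueError(f"expected {expected_length} contrasts, got {v.shape[-1]}")
    if not np.isin(v, (-1, 0, 1)).all():
        raise ValueError("signs must be in {-1, 0, +1}")
    return v.astype(int)


def sum_of_signs(signs, expected_length: int | None = N_CONTRASTS) -> int | np.ndarray:
    """Sum of one species' contrast signs, bounded in [-14, 14]."""
    v = _check_vector(signs, expected_length)
    s = v.sum(axis=-1)
    return s if np.ndim(s) else int(s)


def combined_sum(signs_h, signs_m, expected_length: int | None = N_CONTRASTS):
    """Sum of signs over the combined human + mouse contrasts, in [-28, 28]."""
    h = _check_vector(signs_h, expected_length)
    m = _check_vector(signs_m, expected_length)
    if h.shape != m.shape:
        raise ValueError("species sign vectors differ in shape")
    s = h.sum(axis=-1) + m.sum(axis=-1)
    return s if np.ndim(s) else int(s)


def divergence_score(signs_h, signs_m, expected_length: int | None = N_CONTRASTS):
    """Sum over matched contrasts of |sign_h - sign_m|, in [0, 28]."""
    h = _check_vector(signs_h, expected_length)
    m = _check_vector(signs_m, expected_length)
    if h.shape != m.shape:
        raise ValueError("species sign vectors differ in shape")
    s = np.abs(h - m).sum(axis=-1)
    return s if np.ndim(s) else int(s)


def weighted_sum_score(
    log2fc,
    p_adj,
    significant_only: bool = False,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> float | np.ndarray:
    """|sum over contrasts of log2FC * (-log10 p_adj)|.

    Adjusted p-values are floored at 1e-300 so the score stays finite.  With
    ``significant_only`` the sum runs only over contrasts passing both gates;
    by default every contrast contributes (non-significant ones with small
    weight).
    """
    lfc = np.asarray(log2fc, dtype=float)
    padj = np.clip(np.asarray(p_adj, dtype=float), PADJ_FLOOR, 1.0)
    terms = np.where(np.isnan(lfc), 0.0, lfc) * (-np.log10(padj))
    if significant_only:
        mask = sign_of_contrast(lfc, padj, lfc_threshold, alpha) != 0
        terms = np.where(mask, terms, 0.0)
    s = np.abs(terms.sum(axis=-1))
    return s if np.ndim(s) else float(s)


def build_gene_scores(
    results_h: DEResults,
    results_m: DEResults,
    pairs: pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
    significant_only: bool = False,
) -> pd.DataFrame:
    """Per-ortholog-pair score record from two species' contrast results.

    ``pairs`` needs columns ``gene_h`` and ``gene_m``; contrasts are matched
    across species by contrast id.  Pairs missing from either results table
    are dropped.
    """

    def _wide(res: DEResults, col: str) -> pd.DataFrame:
        return res.table.pivot(index="gene_id", columns="contrast_id", values=col)

    lfc_h, padj_h = _wide(results_h, "log2fc"), _wide(results_h, "p_adj")
    lfc_m, padj_m = _wide(results_m, "log2fc"), _wide(results_m, "p_adj")
    cids = [c.contrast_id for c in results_h.contrasts]
    if [c.contrast_id for c in results_m.contrasts] != cids:
        raise ValueError("contrast sets differ between species")

    keep = pairs["gene_h"].isin(lfc_h.index) & pairs["gene_m"].isin(lfc_m.index)
    pairs = pairs.loc[keep].reset_index(drop=True)
    gh, gm = pairs["gene_h"], pairs["gene_m"]

    lh = lfc_h.loc[gh, cids].to_numpy()
    ph = padj_h.loc[gh, cids].to_numpy()
    lm = lfc_m.loc[gm, cids].to_numpy()
    pm = padj_m.loc[gm, cids].to_numpy()

    sh = sign_of_contrast(lh, ph, lfc_threshold, alpha)
    sm = sign_of_contrast(lm, pm, lfc_threshold, alpha)
    n = len(cids)
    out = pd.DataFrame(
        {
            "gene_h": gh,
            "gene_m": gm,
            "sum_signs_h": sum_of_signs(sh, n),
            "sum_signs_m": sum_of_signs(sm, n),
            "sum_signs_combined": combined_sum(sh, sm, n),
            "divergence": divergence_score(sh, sm, n),
            "sum_score_h": weighted_sum_score(lh, ph, significant_only, lfc_threshold, alpha),
            "sum_score_m": weighted_sum_score(lm, pm, significant_only, lfc_threshold, alpha),
        }
    )
    if "pct_identity" in pairs.columns:
        out["pct_identity"] = pairs["pct_identity"].to_numpy()
    return out


def select_and_rank(
    records: pd.DataFrame,
    min_abs_sum: int = 8,
    rank_by: str = "sum_score_h",
    select_on: str = "sum_signs_combined",
) -> pd.DataFrame:
    """Apply the |combined sum| >= threshold gate and rank by a weighted score.

    Adds ``selected`` (0/1) and ``rank`` (1-based within the selection, NA
    elsewhere); ranking is descending by ``rank_by``, ties broken by human
    gene id.  By default selection uses the combined human+mouse sum; pass
    ``select_on='sum_signs_h'`` for a per-species gate.
    """
    if rank_by not in ("sum_score_h", "sum_score_m"):
        raise ValueError("rank_by must be sum_score_h or sum_score_m")
    out = records.copy()
    out["selected"] = (out[select_on].abs() >= min_abs_sum).astype(int)
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    sel = out[out["selected"] == 1].sort_values(
        [rank_by, "gene_h"], ascending=[False, True], kind="mergesort"
    )
    out.loc[sel.index, "rank"] = np.arange(1, len(sel) + 1)
    return out.sort_values(
        ["selected", rank_by, "gene_h"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


_SUPPORT = {
    "per_species_h": ("sum_signs_h", range(-14, 15)),
    "per_species_m": ("sum_signs_m", range(-14, 15)),
    "combined": ("sum_signs_combined", range(-28, 29)),
    "divergence": ("divergence", range(0, 29)),
}


def score_histogram(records: pd.DataFrame, which: str = "combined") -> pd.Series:
    """Gene counts per integer score over the statistic's full support."""
    if which not in _SUPPORT:
        raise ValueError(f"which must be one of {sorted(_SUPPORT)}")
    col, support = _SUPPORT[which]
    counts = records[col].value_counts()
    idx = pd.Index(list(support), name=col)
    return counts.reindex(idx, fill_value=0).astype(int).rename("n_genes")
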