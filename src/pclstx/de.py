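"""Paired differential expression with empirical-Bayes variance moderation.

The study's contrasts compare each nutrient medium against the time-matched
control medium within subject (liver donor or animal), which removes the
dominant between-donor component of the human data.  Per gene and contrast
the pipeline computes the mean within-subject log2-CPM difference, shrinks
the per-gene variances toward a common prior estimated by method of moments
on the log variances (the scaled-F model behind moderated t-statistics),
tests the moderated statistic against a t distribution with augmented
degrees of freedom, and controls FDR per contrast with Benjamini-Hochberg.

The model surface follows the estimator/results convention:
``PairedContrastModel.from_counts(...).fit()`` returns :class:`DEResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import ContrastSpec, contrast_set

__all__ = [
    "ExpressionMatrix",
    "log_cpm",
    "filter_low_counts",
    "moderate_variances",
    "bh_adjust",
    "fit_paired_contrasts",
    "PairedContrastModel",
    "DEResults",
    "PADJ_FLOOR",
]

#: Floor applied to adjusted p-values before -log10 weighting downstream.
PADJ_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """log2 counts-per-million values (genes x samples) plus its provenance."""

    values: pd.DataFrame
    pseudocount: float
    library_sizes: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a pseudocount.

    ``value = log2((count + pc) / (library_size + 2*pc) * 1e6)`` with the
    library size taken as the column sum.  The pseudocount keeps zero counts
    finite; the ``2*pc`` library correction is the usual log-CPM convention.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero count column(s): {bad}")
    vals = np.log2(
        (counts + pseudocount).div(lib + 2.0 * pseudocount, axis=1) * 1e6
    )
    return ExpressionMatrix(values=vals, pseudocount=pseudocount, library_sizes=lib)


def filter_low_counts(counts: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Keep genes detected in at least one sample (max count over samples > threshold)."""
    return counts.loc[counts.max(axis=1) > threshold]


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, which is ~linear)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting value for all y > 0
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def moderate_variances(
    s2: np.ndarray | pd.Series, d: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Under the hierarchical model ``s2_g ~ s02 * F(d, d0)``, the prior degrees
    of freedom ``d0`` and prior variance ``s02`` are estimated by matching the
    mean and variance of ``log s2_g`` to the log scaled-F distribution
    (digamma/trigamma moments).  Returns the posterior variances

        ``s2_tilde = (d0*s02 + d*s2) / (d0 + d)``

    together with ``(d0, s02)``; ``d0 = inf`` means complete shrinkage to
    ``s02``.  With fewer than 10 genes no moderation is attempted (``d0=0``).
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if (s2 < 0).any():
        raise ValueError("variances must be non-negative")
    ok = s2 > 0
    if ok.sum() < 10:
        warnings.warn(
            "fewer than 10 positive variances; skipping moderation (d0=0)",
            stacklevel=2,
        )
        return s2.copy(), 0.0, float(np.median(s2)) if s2.size else 0.0

    z = np.log(s2[ok])
    # e_g = log s2_g corrected for the sampling distribution of log chi2_d/d
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, d / 2.0)
    if excess > 0:
        half_d0 = float(_trigamma_inverse(np.array([excess]))[0])
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
    else:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
    return s2_tilde, d0, s0_2


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


def fit_paired_contrasts(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
) -> pd.DataFrame:
    """Per-gene paired contrast statistics (log2fc, moderated p) without FDR.

    For each contrast, subjects with both the test-medium and the
    time-matched control sample included contribute one within-subject
    difference; subjects missing either member are dropped for that contrast.
    Contrasts with fewer than 2 complete pairs are emitted with missing
    statistics rather than silently omitted.
    """
    if contrasts is None:
        contrasts = contrast_set()
    meta = metadata[metadata["status"] == "included"]
    idx = meta.set_index(["medium", "timepoint_h"])
    vals = expr.values
    rows: list[pd.DataFrame] = []
    for c in contrasts:
        try:
            test = idx.loc[[(c.test_medium, c.timepoint_h)]]
            ctr = idx.loc[[("CTR", c.timepoint_h)]]
        except KeyError:
            test = ctr = pd.DataFrame(columns=meta.columns)
        test_by = dict(zip(test["subject_id"], test["sample_id"]))
        ctr_by = dict(zip(ctr["subject_id"], ctr["sample_id"]))
        subjects = sorted(set(test_by) & set(ctr_by))
        n_pairs = len(subjects)
        block = pd.DataFrame(
            {
                "gene_id": vals.index,
                "contrast_id": c.contrast_id,
                "log2fc": np.nan,
                "p": np.nan,
                "n_pairs": n_pairs,
            }
        )
        if n_pairs >= 2:
            diffs = (
                vals[[test_by[s] for s in subjects]].to_numpy()
                - vals[[ctr_by[s] for s in subjects]].to_numpy()
            )
            lfc = diffs.mean(axis=1)
            s2 = diffs.var(axis=1, ddof=1)
            d = n_pairs - 1
            s2_tilde, d0, _ = moderate_variances(s2, d)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = lfc / np.sqrt(s2_tilde / n_pairs)
            df_total = d0 + d
            if np.isinf(df_total):
                p = 2.0 * stats.norm.sf(np.abs(t))
            else:
                p = 2.0 * stats.t.sf(np.abs(t), df_total)
            p = np.where(np.isfinite(t), p, np.where(np.isnan(t), 1.0, 0.0))
            block["log2fc"] = lfc
            block["p"] = p
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


@dataclass
class DEResults:
    """Fitted paired-contrast results.

    ``table`` is long-form with one row per gene x contrast: ``gene_id``,
    ``contrast_id``, ``log2fc``, ``p``, ``p_adj`` (BH within contrast),
    ``n_pairs``.
    """

    table: pd.DataFrame
    alpha: float
    lfc_threshold: float
    contrasts: list[ContrastSpec]
    model: "PairedContrastModel | None" = field(default=None, repr=False)

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[(t["p_adj"] <= self.alpha) & (t["log2fc"].abs() >= self.lfc_threshold)]

    def pivot(self, column: str = "log2fc") -> pd.DataFrame:
        return self.table.pivot(index="gene_id", columns="contrast_id", values=column)

    def summary(self) -> str:
        lines = [
            "Paired contrast differential expression",
            f"  genes: {self.table['gene_id'].nunique()}   contrasts: {len(self.contrasts)}",
            f"  cutoffs: |log2FC| >= {self.lfc_threshold}, BH p_adj <= {self.alpha}",
            "",
            f"  {'contrast':<12}{'n_pairs':>8}{'n_up':>8}{'n_down':>8}",
        ]
        sig = self.significant()
        for c in self.contrasts:
            sub = self.table[self.table["contrast_id"] == c.contrast_id]
            s = sig[sig["contrast_id"] == c.contrast_id]
            n_pairs = int(sub["n_pairs"].iloc[0]) if len(sub) else 0
            lines.append(
                f"  {c.contrast_id:<12}{n_pairs:>8}"
                f"{int((s['log2fc'] > 0).sum()):>8}{int((s['log2fc'] < 0).sum()):>8}"
            )
        return "\n".join(lines)


class PairedContrastModel:
    """Donor-blocked paired contrast model over a log-CPM expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        log2-CPM values; columns must match included samples in ``metadata``.
    metadata : DataFrame
        Columns ``sample_id``, ``subject_id``, ``medium``, ``timepoint_h``,
        ``status``.
    contrasts : list of ContrastSpec, optional
        Defaults to the full 14-contrast set.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        metadata: pd.DataFrame,
        contrasts: list[ContrastSpec] | None = None,
    ):
        required = {"sample_id", "subject_id", "medium", "timepoint_h", "status"}
        missing = required - set(metadata.columns)
        if missing:
            raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
        unknown = set(metadata.loc[metadata["status"] == "included", "sample_id"]) - set(
            expr.sample_ids
        )
        if unknown:
            raise ValueError(
                f"metadata references samples absent from the expression matrix: "
                f"{sorted(unknown)[:5]}"
            )
        self.expr = expr
        self.metadata = metadata
        self.contrasts = contrasts if contrasts is not None else contrast_set()

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        contrasts: list[ContrastSpec] | None = None,
        pseudocount: float = 0.5,
        count_filter: int | None = 10,
    ) -> "PairedContrastModel":
        """Build the model from raw counts: low-count filter then log-CPM."""
        included = metadata.loc[metadata["status"] == "included", "sample_id"]
        counts = counts[[s for s in counts.columns if s in set(included)]]
        if count_filter is not None:
            counts = filter_low_counts(counts, count_filter)
        return cls(log_cpm(counts, pseudocount), metadata, contrasts)

    def fit(self, alpha: float = 0.05, lfc_threshold: float = 0.5) -> DEResults:
        """Fit all contrasts, BH-adjust within each contrast, return results."""
        table = fit_paired_contrasts(self.expr, self.metadata, self.contrasts)
        table["p_adj"] = np.nan
        for cid, grp in table.groupby("contrast_id"):
            if grp["p"].notna().all():
                table.loc[grp.index, "p_adj"] = bh_adjust(grp["p"].to_numpy())
        table = table[["gene_id", "contrast_id", "log2fc", "p", "p_adj", "n_pairs"]]
        return DEResults(
            table=table,
            alpha=alpha,
            lfc_threshold=lfc_threshold,
            contrasts=self.contrasts,
            model=self,
        )
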