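"""Gene-weighted linear model of motif activity.

For one genotype contrast, the per-gene expression log2 ratio y_i is
regressed on the promoter's counts of each oriented motif (intercept,
forward STRE, reverse STRE, forward PDS, reverse PDS by default).  Genes
are weighted by |y_i| so that strongly responding genes dominate the fit
(zero-response genes drop out); each coefficient is the inferred activity
of one oriented motif in that contrast, in log2-ratio units per motif copy,
with a partial-F "ANOVA" p-value (equal to the squared-t test of the
coefficient within the joint model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from regulon_shift.motifs import MotifCountTable


def build_design(
    table: MotifCountTable,
    motifs: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    encoding: str = "counts",
) -> pd.DataFrame:
    """Design matrix: intercept plus one column per (motif, orientation).

    Column order is (intercept, fwd motif1, rev motif1, fwd motif2, ...).
    ``encoding='counts'`` uses occurrence counts (default); ``'indicator'``
    uses presence/absence 0-1.  Rows follow ``genes`` order (default: table
    order); a requested gene missing from the table is an error.
    """
    if encoding not in ("counts", "indicator"):
        raise ValueError(f"unknown encoding {encoding!r}")
    motif_names = list(motifs) if motifs is not None else table.motifs
    gene_order = list(genes) if genes is not None else table.genes
    columns: dict[str, pd.Series] = {}
    for motif in motif_names:
        for orientation in ("fwd", "rev"):
            columns[f"{orientation}_{motif}"] = table.counts(motif, orientation)
    design = pd.DataFrame(columns)
    missing = [g for g in gene_order if g not in design.index]
    if missing:
        raise KeyError(f"genes missing from count table: {missing[:5]}")
    design = design.loc[gene_order]
    if encoding == "indicator":
        design = (design > 0).astype(int)
    design.insert(0, "intercept", 1)
    design.index.name = "gene_id"
    return design


@dataclass
class ActivityFit:
    """Fitted motif activities for one contrast."""

    coefficients: pd.Series  # per design column
    standard_errors: pd.Series
    p_values: pd.Series  # partial-F (squared-t) per column
    weighting: str
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "stderr": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def fit_motif_activity(
    design: pd.DataFrame,
    response: pd.Series,
    weighting: str = "abs_response",
) -> ActivityFit:
    """Weighted least squares of contrast log2 ratios on oriented motif counts.

    ``weighting='abs_response'`` uses w_i = |y_i| (zero-response genes drop
    out); ``'none'`` is ordinary least squares.  The reported p-value per
    coefficient is the partial F-test of that column against the full
    model's residual, which equals the squared-t test; weights are scale
    free (doubling all weights changes nothing).
    """
    if weighting not in ("abs_response", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    y = response.reindex(design.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:5]
        raise ValueError(f"response missing for genes: {missing}")
    if not np.isfinite(y.to_numpy()).all():
        raise ValueError("response contains non-finite values")

    X = design.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if weighting == "abs_response":
        w = np.abs(yv)
        keep = w > 0
        if not keep.any():
            raise ValueError("all responses are zero: every gene has zero weight")
        X, yv, w = X[keep], yv[keep], w[keep]
    else:
        keep = np.ones(yv.shape[0], dtype=bool)
        w = np.ones_like(yv)

    n_used = int(keep.sum())
    if n_used <= X.shape[1]:
        raise ValueError(
            f"need more genes ({n_used}) than design columns ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X * np.sqrt(w)[:, None])
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        cols = design.columns[1:]
        raise ValueError(
            f"design is rank deficient after weighting; most collinear columns: "
            f"{cols[i]!r}, {cols[j]!r}"
        )

    model = sm.WLS(yv, X, weights=w)
    fit = model.fit()
    names = list(design.columns)
    return ActivityFit(
        coefficients=pd.Series(fit.params, index=names),
        standard_errors=pd.Series(fit.bse, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        weighting=weighting,
        n_genes=n_used,
    )


def activity_table(fits: dict[tuple[str, str], ActivityFit]) -> pd.DataFrame:
    """Long-format activity report: one row per (phase, contrast, term)."""
    rows = []
    for (phase, contrast), fit in fits.items():
        for term in fit.coefficients.index:
            if term == "intercept":
                continue
            rows.append(
                {
                    "phase": phase,
                    "contrast": contrast,
                    "term": term,
                    "coefficient": fit.coefficients[term],
                    "stderr": fit.standard_errors[term],
                    "p_value": fit.p_values[term],
                    "n_genes": fit.n_genes,
                }
            )
    return pd.DataFrame(rows)
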