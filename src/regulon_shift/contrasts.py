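"""Per-gene genotype contrasts across a strains-by-phases design.

The design is four genotypes (wild type, two single deletions, the double
deletion) sampled at three growth phases (logarithmic, post-diauxic shift,
early stationary).  Each phase is analysed separately: per gene, a one-way
layout across the strains at that phase yields strain means and a pooled
residual variance; a contrast is a difference of two strain means.  The
test is an empirical-Bayes moderated t: per-gene variances are shrunk
toward a prior (d0, s0^2) estimated from the ensemble of all gene variances
by moment matching on log s^2, which adds d0 degrees of freedom to every
gene's test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

PHASES = ("log", "PDS", "stat")
STRAINS = ("wt", "gis1", "rph1", "gis1rph1")

#: The five genotype contrasts examined at every phase, as (A, B) for A - B.
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("gis1", "wt"),
    ("rph1", "wt"),
    ("gis1rph1", "gis1"),
    ("gis1rph1", "rph1"),
    ("gis1rph1", "wt"),
)


def contrast_name(strain_a: str, strain_b: str) -> str:
    return f"{strain_a}-{strain_b}"


class ExpressionMatrix:
    """log2 expression values, genes x samples.

    Columns are labelled ``strain.phase.replicate`` (e.g. ``wt.log.1``).
    Values must be finite and sample labels unique.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))[:5]}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        for col in values.columns:
            if len(str(col).split(".")) != 3:
                raise ValueError(
                    f"sample label {col!r} is not 'strain.phase.replicate'"
                )
        self.values = values.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def sample_info(self) -> pd.DataFrame:
        """Sample metadata parsed from column labels."""
        rows = []
        for col in self.values.columns:
            strain, phase, rep = str(col).split(".")
            rows.append({"sample": col, "strain": strain, "phase": phase,
                         "replicate": rep})
        return pd.DataFrame(rows)

    def phase_groups(self, phase: str) -> dict[str, pd.DataFrame]:
        """Per-strain replicate sub-matrices at one phase."""
        info = self.sample_info()
        at_phase = info[info["phase"] == phase]
        if at_phase.empty:
            raise KeyError(f"no samples at phase {phase!r}")
        return {
            strain: self.values[list(sub["sample"])]
            for strain, sub in at_phase.groupby("strain", sort=False)
        }

    def to_tsv(self, path) -> None:
        # %.17g round-trips float64 exactly through text
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        frame = pd.read_csv(
            path, sep="\t", index_col="gene_id", float_precision="round_trip"
        )
        non_numeric = frame.columns[
            [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
        ]
        if len(non_numeric):
            col = non_numeric[0]
            row = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric cell at gene {row!r}, sample {col!r}")
        return cls(frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass
class EBPrior:
    """Empirical-Bayes variance prior: d0 prior df (inf allowed), s0^2 scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the no-moderation limit (ordinary t); inf is full shrinkage
        if not (self.d0 >= 0):
            raise ValueError("prior df must be >= 0 (use math.inf for no spread)")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0)


@dataclass
class ContrastResult:
    """Per-gene statistics for one genotype contrast at one phase."""

    phase: str
    strain_a: str
    strain_b: str
    table: pd.DataFrame  # gene-indexed: log2_ratio, s2, df, scale
    prior: EBPrior | None = field(default=None)

    @property
    def name(self) -> str:
        return contrast_name(self.strain_a, self.strain_b)

    @property
    def log2_ratio(self) -> pd.Series:
        return self.table["log2_ratio"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def compute_contrast(
    matrix: ExpressionMatrix, phase: str, strain_a: str, strain_b: str
) -> ContrastResult:
    """Per-gene mean difference A - B with variance pooled across all strains.

    The residual variance comes from the one-way per-gene model over every
    strain sampled at the phase (not just the contrasted pair), with
    df = (samples at phase) - (strains at phase).  The contrast scale factor
    sqrt(1/nA + 1/nB) is stored for the t statistic.
    """
    groups = matrix.phase_groups(phase)
    for strain in (strain_a, strain_b):
        if strain not in groups:
            raise KeyError(f"strain {strain!r} has no samples at phase {phase!r}")
    for strain, block in groups.items():
        if block.shape[1] < 2:
            raise ValueError(
                f"strain {strain!r} at phase {phase!r} has "
                f"{block.shape[1]} replicate(s); need at least 2"
            )
    n_samples = sum(block.shape[1] for block in groups.values())
    df = n_samples - len(groups)
    rss = sum(
        ((block.to_numpy() - block.to_numpy().mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for block in groups.values()
    )
    s2 = rss / df
    mean_a = groups[strain_a].mean(axis=1)
    mean_b = groups[strain_b].mean(axis=1)
    scale = math.sqrt(1.0 / groups[strain_a].shape[1] + 1.0 / groups[strain_b].shape[1])
    table = pd.DataFrame(
        {
            "log2_ratio": mean_a - mean_b,
            "s2": s2,
            "df": float(df),
            "scale": scale,
        },
        index=matrix.genes,
    )
    return ContrastResult(phase, strain_a, strain_b, table)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_eb_prior(s2: Sequence[float], df: float) -> EBPrior:
    """Estimate (d0, s0^2) by moment matching on log s^2.

    With s^2 ~ s0^2 * chi^2_df / df given true variance drawn from a scaled
    inverse chi-square prior, z = log s^2 has var(z) = trigamma(df/2) +
    trigamma(d0/2); d0 follows by trigamma inversion and s0^2 from the mean
    of z.  If the observed spread of log s^2 does not exceed the sampling
    component trigamma(df/2), d0 is flagged infinite (complete shrinkage).
    Zero variances are excluded from estimation (log undefined); all-zero
    input is degenerate data.
    """
    s2_arr = np.asarray(s2, dtype=float)
    if df < 1:
        raise ValueError("residual df must be >= 1")
    positive = s2_arr[s2_arr > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero: degenerate data")
    if positive.size < 50:
        warnings.warn(
            f"estimating the variance prior from only {positive.size} genes",
            stacklevel=2,
        )
    z = np.log(positive)
    # e is an unbiased estimate of log(sigma_g^2) per gene under the model
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var * (n - 1) / n - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return EBPrior(math.inf, math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBPrior(d0, s0_sq)


def moderated_t_test(
    contrast: ContrastResult, prior: EBPrior | None = None
) -> ContrastResult:
    """Moderated t and two-sided p for every gene of a contrast.

    Posterior variance (d0*s0^2 + df*s^2)/(d0 + df); t = ratio / (posterior
    sd * scale); p from t with d0 + df degrees of freedom.  ``prior=None``
    fits the prior from this contrast's own variance ensemble.  A prior with
    d0 -> 0 reproduces the ordinary pooled t exactly; an infinite prior
    gives a z-like statistic with fixed s0.
    """
    table = contrast.table
    if prior is None:
        prior = fit_eb_prior(table["s2"].to_numpy(), float(table["df"].iloc[0]))
    df = table["df"].to_numpy()
    s2 = table["s2"].to_numpy()
    if prior.is_infinite:
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(df, np.inf)
    elif prior.d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = table["log2_ratio"].to_numpy() / (np.sqrt(s2_post) * table["scale"].to_numpy())
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    out = table.copy()
    out["moderated_t"] = t
    out["p_raw"] = p
    out["p_fdr"] = bh_adjust(p)
    return ContrastResult(contrast.phase, contrast.strain_a, contrast.strain_b, out, prior)


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    result: ContrastResult, fold_threshold: float = 2.0, alpha: float = 0.01
) -> pd.DataFrame:
    """Differentially expressed genes: |log2 ratio| >= log2(fold) and FDR p < alpha.

    Returns a gene-indexed frame with the ratio, adjusted p and direction
    ('up'/'down'), restricted to the called genes.  The fold threshold is
    inclusive, the alpha threshold strict.
    """
    if fold_threshold <= 0:
        raise ValueError("fold threshold must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if "p_fdr" not in result.table:
        raise ValueError("run moderated_t_test before calling differential genes")
    table = result.table
    mask = (table["log2_ratio"].abs() >= math.log2(fold_threshold)) & (
        table["p_fdr"] < alpha
    )
    out = table.loc[mask, ["log2_ratio", "p_fdr"]].copy()
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    return out


def qpcr_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Delta-delta Ct fold change: 2 ** -((tgt-ref)_case - (tgt-ref)_control)."""
    for value in (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control):
        if not math.isfinite(value):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
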