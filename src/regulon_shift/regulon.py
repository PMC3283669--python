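"""Regulon statistics for a pair of paralogous transcription factors.

Given per-gene log2 ratios g (single mutant 1 vs wild type), r (single
mutant 2 vs wild type) and d (double mutant vs wild type):

* influence ratio |g| - |r| says which paralog dominates a gene;
* redundancy coefficient (d - (g + r)) / d is 1 when only the double
  deletion has an effect (complete redundancy), 0 when single-mutant
  effects add up, and negative when singles exceed the double;
* a gene's mode of regulation is classified from the sign pattern of its
  significant contrasts plus a redundancy cutoff (default 0.5).

Also here: average-linkage Pearson clustering of contrast profiles,
hypergeometric set-overlap tests, Wilcoxon group-response tests, Welch-t
motif enrichment, and the occurrence-level one-sided hypergeometric
orientation-bias test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from regulon_shift.contrasts import ContrastResult
from regulon_shift.motifs import MotifCountTable


class GeneSet:
    """A named set of unique gene identifiers."""

    def __init__(self, name: str, members: Iterable[str]):
        members = list(members)
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {name!r} contains duplicates")
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"


def influence_ratio(g: float, r: float) -> float:
    """|g| - |r|: positive means paralog 1 dominates, negative paralog 2."""
    if not (math.isfinite(g) and math.isfinite(r)):
        raise ValueError("log ratios must be finite")
    return abs(g) - abs(r)


def redundancy_coefficient(g: float, r: float, d: float) -> float:
    """(d - (g + r)) / d, or NaN when d == 0 (undefined, never an error).

    1 = effect only in the double mutant; 0 = additive single effects;
    negative = singles exceed the double.
    """
    if not all(math.isfinite(x) for x in (g, r, d)):
        raise ValueError("log ratios must be finite")
    if d == 0:
        return float("nan")
    return (d - (g + r)) / d


@dataclass
class RegulationProfile:
    """Per-gene summary of the three informative contrasts at one phase."""

    gene_id: str
    g: float
    r: float
    d: float

    @property
    def influence(self) -> float:
        return influence_ratio(self.g, self.r)

    @property
    def redundancy(self) -> float:
        return redundancy_coefficient(self.g, self.r, self.d)


MODE_LABELS = (
    "activated-by-1", "repressed-by-1", "activated-by-2", "repressed-by-2",
    "redundant-activation", "redundant-repression",
    "synergistic-activation", "synergistic-repression",
    "opposite", "unclear",
)


def classify_mode(
    profile: RegulationProfile,
    g_significant: bool,
    r_significant: bool,
    d_significant: bool,
    redundancy_cutoff: float = 0.5,
) -> str:
    """Label a gene's mode of regulation from its significant contrasts.

    Sign convention: ratios are mutant minus wild type, so a POSITIVE
    significant ratio means the deletion derepresses the gene, i.e. the
    factor represses it.  Significant g and r of opposite sign give
    'opposite'; no significant contrast gives 'unclear'.  When both factors
    act in the same direction (or only the double mutant responds), the
    redundancy coefficient splits redundant (>= cutoff) from synergistic.
    """
    sig_dir = {
        "g": np.sign(profile.g) if g_significant else 0,
        "r": np.sign(profile.r) if r_significant else 0,
        "d": np.sign(profile.d) if d_significant else 0,
    }
    if not any(sig_dir.values()):
        return "unclear"
    if sig_dir["g"] and sig_dir["r"] and sig_dir["g"] != sig_dir["r"]:
        return "opposite"
    if sig_dir["g"] and not sig_dir["r"] and not sig_dir["d"]:
        return "repressed-by-1" if sig_dir["g"] > 0 else "activated-by-1"
    if sig_dir["r"] and not sig_dir["g"] and not sig_dir["d"]:
        return "repressed-by-2" if sig_dir["r"] > 0 else "activated-by-2"
    # both factors implicated (directly or through the double mutant)
    direction = sig_dir["d"] or sig_dir["g"] or sig_dir["r"]
    redundancy = profile.redundancy
    joint = "redundant" if (not math.isnan(redundancy) and redundancy >= redundancy_cutoff) else "synergistic"
    sense = "repression" if direction > 0 else "activation"
    return f"{joint}-{sense}"


def profile_table(
    g: ContrastResult, r: ContrastResult, d: ContrastResult
) -> pd.DataFrame:
    """Gene-indexed table of g, r, d ratios with influence and redundancy."""
    frame = pd.DataFrame(
        {"g": g.log2_ratio, "r": r.log2_ratio, "d": d.log2_ratio}
    )
    frame["influence"] = frame["g"].abs() - frame["r"].abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        redundancy = (frame["d"] - (frame["g"] + frame["r"])) / frame["d"]
    frame["redundancy"] = redundancy.where(frame["d"] != 0, np.nan)
    return frame


@dataclass
class ClusterAssignment:
    """Flat cut of an average-linkage tree: labels in 1..k plus merge heights."""

    labels: pd.Series  # gene-indexed, values 1..k
    k: int
    merge_heights: np.ndarray

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def cluster_profiles(profiles: pd.DataFrame, k: int = 6) -> ClusterAssignment:
    """Average-linkage clustering on 1 - Pearson distance, cut to k clusters.

    ``profiles`` is gene-indexed with one column per contrast (>= 2 columns).
    A zero-variance profile has no defined correlation and is an error.
    """
    if profiles.shape[0] < k:
        raise ValueError(f"need at least k={k} genes, got {profiles.shape[0]}")
    if profiles.shape[1] < 2:
        raise ValueError("profiles need at least 2 contrast dimensions")
    values = profiles.to_numpy(dtype=float)
    variances = values.var(axis=1)
    if np.any(variances == 0):
        gene = profiles.index[int(np.argmax(variances == 0))]
        raise ValueError(f"gene {gene!r} has a zero-variance profile")
    tree = linkage(values, method="average", metric="correlation")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterAssignment(
        pd.Series(labels, index=profiles.index, name="cluster"),
        k=int(labels.max()),
        merge_heights=tree[:, 2].copy(),
    )


@dataclass
class OverlapResult:
    set_a: str
    set_b: str
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


def set_overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    p = P(X >= observed overlap) with X ~ Hypergeom(N=|universe|, K=|a|,
    n=|b|); exchange-symmetric in a and b.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not a.members <= universe.members:
        raise ValueError(f"set {a.name!r} not contained in the universe")
    if not b.members <= universe.members:
        raise ValueError(f"set {b.name!r} not contained in the universe")
    overlap = len(a.members & b.members)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(a), len(b)))
    return OverlapResult(a.name, b.name, len(universe), len(a), len(b), overlap, p)


@dataclass
class GroupResponse:
    group: str
    contrast: str
    n_group: int
    direction: str  # 'up' or 'down'
    p_value: float


def group_response_test(group: GeneSet, contrast: ContrastResult) -> GroupResponse:
    """Two-sample Wilcoxon rank-sum of a group's log2 ratios vs all other genes.

    Two-sided; exact when the smaller side has <= 10 values and no ties,
    otherwise the normal approximation with tie correction.  Direction is
    the sign of (group median - complement median).
    """
    ratios = contrast.log2_ratio
    in_group = ratios.index.isin(group.members)
    x = ratios[in_group].to_numpy()
    y = ratios[~in_group].to_numpy()
    if x.size == 0:
        raise ValueError(f"group {group.name!r} has no genes in the contrast")
    if y.size == 0:
        raise ValueError(f"group {group.name!r} covers every gene; no complement")
    method = "exact" if min(x.size, y.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = "up" if np.median(x) >= np.median(y) else "down"
    return GroupResponse(group.name, contrast.name, x.size, direction, float(res.pvalue))


@dataclass
class EnrichmentResult:
    gene_set: str
    motif: str
    set_mean: float
    background_mean: float
    t_statistic: float
    p_enrichment: float
    p_depletion: float


def motif_enrichment_test(
    gene_set: GeneSet, table: MotifCountTable, motif: str
) -> EnrichmentResult:
    """Welch two-sample t on per-promoter total motif counts, set vs rest.

    One-sided p toward enrichment (set mean above background) is primary;
    the depletion-side p is also reported since depletion is informative in
    its own right.
    """
    counts = table.counts(motif, "total")
    in_set = counts.index.isin(gene_set.members)
    x = counts[in_set].to_numpy(dtype=float)
    y = counts[~in_set].to_numpy(dtype=float)
    if y.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} equals the whole table")
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 promoters in the set and its complement")
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p_greater = stats.ttest_ind(
                x, y, equal_var=False, alternative="greater"
            )
    return EnrichmentResult(
        gene_set.name,
        motif,
        float(x.mean()),
        float(y.mean()),
        float(t_stat),
        float(p_greater),
        float(1.0 - p_greater),
    )


@dataclass
class OrientationBias:
    gene_set: str
    motif: str
    set_fwd: int
    set_total: int
    population_fwd: int
    population_total: int
    fwd_rev_ratio: float
    p_value: float
    direction: str  # 'forward' or 'reverse'


def orientation_bias_test(
    gene_set: GeneSet, table: MotifCountTable, motif: str
) -> OrientationBias:
    """One-sided hypergeometric test for orientation bias of motif occurrences.

    The sampled units are motif OCCURRENCES, not promoters: the population
    is every occurrence in all promoters labelled forward (K of M); the
    sample is the n occurrences in the set's promoters; observed is the
    set's forward count.  The tail is chosen by the observed direction:
    upper P(X >= obs) if the set's forward fraction exceeds the
    population's, else lower P(X <= obs).
    """
    fwd = table.counts(motif, "fwd")
    rev = table.counts(motif, "rev")
    pop_fwd = int(fwd.sum())
    pop_total = int(fwd.sum() + rev.sum())
    if pop_total == 0:
        raise ValueError(f"motif {motif!r} never occurs in the table")
    in_set = fwd.index.isin(gene_set.members)
    set_fwd = int(fwd[in_set].sum())
    set_total = int(fwd[in_set].sum() + rev[in_set].sum())
    if set_total == 0:
        raise ValueError(
            f"motif {motif!r} has no occurrences in gene set {gene_set.name!r}"
        )
    set_rev = set_total - set_fwd
    ratio = set_fwd / set_rev if set_rev > 0 else float("nan")
    if set_fwd / set_total >= pop_fwd / pop_total:
        p = float(stats.hypergeom.sf(set_fwd - 1, pop_total, pop_fwd, set_total))
        direction = "forward"
    else:
        p = float(stats.hypergeom.cdf(set_fwd, pop_total, pop_fwd, set_total))
        direction = "reverse"
    return OrientationBias(
        gene_set.name, motif, set_fwd, set_total, pop_fwd, pop_total,
        ratio, p, direction,
    )


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from GMT (name<TAB>desc<TAB>genes...) or one-id-per-line.

    A one-per-line file yields a single set named after the file stem.
    """
    from pathlib import Path

    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no gene identifiers found")
    if any("\t" in ln for ln in lines):
        sets = []
        for i, ln in enumerate(lines, 1):
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, description, genes")
            sets.append(GeneSet(fields[0], fields[2:]))
        return sets
    return [GeneSet(path.stem, lines)]


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for gene in gene_set:
            fh.write(gene + "\n")
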