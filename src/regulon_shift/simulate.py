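"""Synthetic promoters and expression with a known motif-activity ground truth.

The generator inverts the analysis chain: promoters are i.i.d. background
DNA (per-base GC model) with Poisson-distributed insertions of each oriented
motif; per-phase genotype effects are then constructed from the promoters'
oriented motif counts through a linear activity model, so each configured
contrast's expected log2 ratio is X @ beta for that contrast; Gaussian
replicate noise is added on top of a per-gene baseline.

Ground-truth motif counts are defined by RE-SCANNING the emitted sequences,
not by insertion bookkeeping: background DNA can contain incidental motif
words and insertions may abut, so the scan is the only verifiable truth.

The default activity coefficients encode the growth-phase switch the model
is meant to exhibit: both factors repress through forward-biased STRE/PDS
sites in log phase (deletion raises expression, positive coefficients), and
activate through them after the diauxic shift (negative coefficients), with
the PDS element strictly tied to factor 1 (Gis1) and the reverse STRE to
factor 2 (Rph1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regulon_shift.contrasts import (
    CONTRASTS,
    PHASES,
    STRAINS,
    ExpressionMatrix,
    contrast_name,
)
from regulon_shift.motifs import (
    DEFAULT_MOTIFS,
    MotifCountTable,
    MotifSpec,
    scan_promoters,
)
from regulon_shift.promoters import PromoterRegion, write_promoters_fasta

#: beta-vector term order used throughout: intercept then fwd/rev per motif.
def design_terms(motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS) -> list[str]:
    terms = ["intercept"]
    for motif in motifs:
        terms += [f"fwd_{motif.name}", f"rev_{motif.name}"]
    return terms


#: How each named contrast combines the strain effects (gis1, rph1, gis1rph1)
#: relative to wild type (whose effect is 0 by construction).
_CONTRAST_BASIS: dict[str, tuple[float, float, float]] = {
    "gis1-wt": (1, 0, 0),
    "rph1-wt": (0, 1, 0),
    "gis1rph1-wt": (0, 0, 1),
    "gis1rph1-gis1": (-1, 0, 1),
    "gis1rph1-rph1": (0, -1, 1),
}

_MUTANTS = ("gis1", "rph1", "gis1rph1")

#: Default planted activities (log2-ratio units per motif copy) for the three
#: basis contrasts at each phase; terms (intercept, fwdSTRE, revSTRE, fwdPDS,
#: revPDS).  Positive in log phase (repression by the factors), negative
#: after the shift (activation), mirroring the qualitative regulatory switch.
DEFAULT_ACTIVITY: dict[tuple[str, str], tuple[float, ...]] = {
    ("log", "gis1-wt"): (0.0, 0.16, 0.13, 0.15, 0.092),
    ("log", "rph1-wt"): (0.0, 0.31, 0.20, 0.13, 0.064),
    ("log", "gis1rph1-wt"): (0.0, 0.70, 0.37, 0.25, 0.036),
    ("PDS", "gis1-wt"): (0.0, 0.047, -0.0018, -0.54, -0.19),
    ("PDS", "rph1-wt"): (0.0, -0.10, -0.23, -0.076, -0.067),
    ("PDS", "gis1rph1-wt"): (0.0, -0.22, -0.32, -0.74, -0.44),
    ("stat", "gis1-wt"): (0.0, -0.048, 0.0021, -0.88, -0.11),
    ("stat", "rph1-wt"): (0.0, -0.021, -0.0016, 0.14, 0.068),
    ("stat", "gis1rph1-wt"): (0.0, -0.31, -0.17, -0.75, -0.091),
}

DEFAULT_INSERTION_RATE: dict[tuple[str, str], float] = {
    ("STRE", "fwd"): 0.2,
    ("STRE", "rev"): 0.2,
    ("PDS", "fwd"): 0.1,
    ("PDS", "rev"): 0.1,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the real study's design: 2000 genes with 800-bp
    promoters at yeast-like 38% GC, four genotypes x three phases x three
    replicates, planted activities following the fitted growth-phase switch,
    and 0.2 log2 units of replicate noise.
    """

    n_genes: int = 2000
    promoter_length: int = 800
    gc_content: float = 0.38
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
    insertion_rate: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_RATE)
    )
    activity: Mapping[tuple[str, str], Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY)
    )
    noise_sd: float = 0.2
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    clean_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        longest = max(len(m) for m in self.motifs)
        if self.promoter_length < longest:
            raise ValueError(
                f"promoter_length {self.promoter_length} shorter than the "
                f"longest motif ({longest} bp)"
            )
        if any(rate < 0 for rate in self.insertion_rate.values()):
            raise ValueError("insertion rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        motif_names = {m.name for m in self.motifs}
        for motif_name, orientation in self.insertion_rate:
            if motif_name not in motif_names or orientation not in ("fwd", "rev"):
                raise ValueError(
                    f"insertion_rate key ({motif_name!r}, {orientation!r}) does "
                    f"not name a configured motif orientation"
                )
        n_terms = len(design_terms(self.motifs))
        for (phase, contrast), beta in self.activity.items():
            if contrast not in _CONTRAST_BASIS:
                raise ValueError(
                    f"contrast {contrast!r} is not expressible from the strains "
                    f"{STRAINS}; known contrasts: {sorted(_CONTRAST_BASIS)}"
                )
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}; phases are {PHASES}")
            if len(beta) != n_terms:
                raise ValueError(
                    f"activity for ({phase}, {contrast}) has {len(beta)} terms, "
                    f"expected {n_terms} ({design_terms(self.motifs)})"
                )


@dataclass
class SyntheticStudy:
    """Bundle of synthetic promoters, expression, and the planted truth."""

    promoters: list[PromoterRegion]
    expression: ExpressionMatrix
    true_counts: MotifCountTable
    true_activity: dict[tuple[str, str], np.ndarray]
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA + TSVs + JSON ground truth; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "promoters": outdir / "promoters.fa",
            "expression": outdir / "expression.tsv",
            "counts": outdir / "true_counts.tsv",
            "activity": outdir / "true_activity.json",
        }
        write_promoters_fasta(self.promoters, paths["promoters"])
        self.expression.to_tsv(paths["expression"])
        self.true_counts.to_tsv(paths["counts"])
        payload = {
            f"{phase}:{contrast}": dict(
                zip(design_terms(self.config.motifs), map(float, beta))
            )
            for (phase, contrast), beta in sorted(self.true_activity.items())
        }
        paths["activity"].write_text(json.dumps(payload, indent=2, sort_keys=True))
        return paths


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_probabilities(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_sequences(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    cum = np.cumsum(_base_probabilities(gc))
    draws = np.searchsorted(cum, rng.random((n, length)), side="right")
    block = _BASES[draws]
    return [block[i].tobytes().decode("ascii") for i in range(n)]


def _contains_any(seq: str, words: Sequence[str]) -> bool:
    return any(w in seq for w in words)


def simulate_promoters(
    config: SimulationConfig,
) -> tuple[list[PromoterRegion], MotifCountTable]:
    """Generate background promoters with Poisson motif insertions.

    Insertion counts per (motif, orientation) are Poisson with the configured
    mean; insertions are placed at uniform positions without overlapping each
    other (overlap with incidental background matches is allowed).  With
    ``clean_background`` the background is rejection-sampled until it
    contains no configured motif word, giving an exact null when all
    insertion rates are zero.  Counts are obtained by re-scanning the final
    sequences.  Deterministic for a given config (single generator stream).
    """
    rng = np.random.default_rng(config.seed)
    length = config.promoter_length
    all_words = [w for m in config.motifs for o in ("fwd", "rev") for w in m.expand(o)]
    insertion_words = {
        (m.name, o): m.expand(o) for m in config.motifs for o in ("fwd", "rev")
    }
    rate_items = sorted(config.insertion_rate.items())

    backgrounds = _random_sequences(rng, config.n_genes, length, config.gc_content)
    if config.clean_background:
        for i in range(config.n_genes):
            attempts = 0
            while _contains_any(backgrounds[i], all_words):
                attempts += 1
                if attempts > 10_000:
                    raise RuntimeError(
                        "clean background rejection sampling did not converge; "
                        "promoter too short or GC too extreme"
                    )
                backgrounds[i] = _random_sequences(rng, 1, length, config.gc_content)[0]

    promoters: list[PromoterRegion] = []
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:05d}"
        seq = list(backgrounds[i])
        occupied: list[tuple[int, int]] = []
        for (motif_name, orientation), rate in rate_items:
            if rate == 0:
                continue
            n_insert = int(rng.poisson(rate))
            words = insertion_words[(motif_name, orientation)]
            for _ in range(n_insert):
                word = words[0] if len(words) == 1 else words[int(rng.integers(len(words)))]
                if sum(b - a for a, b in occupied) + len(word) > length:
                    raise ValueError(
                        f"promoter of {gene_id} too short to hold all requested "
                        f"insertions"
                    )
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - len(word) + 1))
                    span = (start, start + len(word))
                    if all(span[1] <= a or span[0] >= b for a, b in occupied):
                        occupied.append(span)
                        seq[span[0]:span[1]] = word
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"promoter of {gene_id} too crowded to place a "
                        f"{motif_name} insertion without overlap"
                    )
        promoters.append(
            PromoterRegion(gene_id, "".join(seq), ("synthetic", 0, length, "+"))
        )

    counts = scan_promoters(promoters, config.motifs)
    return promoters, counts


def _solve_strain_effects(
    config: SimulationConfig, phase: str
) -> dict[str, np.ndarray] | None:
    """Per-mutant beta vectors consistent with the configured contrasts.

    Solves C @ E = B for the three mutant effect vectors (wild type is 0),
    where C maps strain effects to the configured contrasts.  Inconsistent
    over-determination is an error; under-determination takes the minimum
    norm solution (unconstrained contrasts are then implied).  Returns None
    when the phase has no configured activity (all effects zero).
    """
    entries = [
        (contrast, np.asarray(beta, dtype=float))
        for (p, contrast), beta in config.activity.items()
        if p == phase
    ]
    if not entries:
        return None
    C = np.array([_CONTRAST_BASIS[name] for name, _ in entries], dtype=float)
    B = np.vstack([beta for _, beta in entries])
    E, *_ = np.linalg.lstsq(C, B, rcond=None)
    residual = C @ E - B
    if not np.allclose(residual, 0.0, atol=1e-10):
        bad = [entries[i][0] for i in np.argwhere(
            np.abs(residual).max(axis=1) > 1e-10).ravel()]
        raise ValueError(
            f"activity for phase {phase!r} is inconsistent across contrasts "
            f"{bad}: the five contrasts are linear in three strain effects"
        )
    return {mutant: E[i] for i, mutant in enumerate(_MUTANTS)}


def true_activity_map(config: SimulationConfig) -> dict[tuple[str, str], np.ndarray]:
    """Planted beta for every expressible contrast at every phase."""
    n_terms = len(design_terms(config.motifs))
    out: dict[tuple[str, str], np.ndarray] = {}
    for phase in PHASES:
        effects = _solve_strain_effects(config, phase)
        if effects is None:
            effects = {m: np.zeros(n_terms) for m in _MUTANTS}
        full = {"wt": np.zeros(n_terms), **effects}
        for a, b in CONTRASTS:
            out[(phase, contrast_name(a, b))] = full[a] - full[b]
    return out


def simulate_expression(
    counts: MotifCountTable, config: SimulationConfig
) -> ExpressionMatrix:
    """Replicate-level log2 expression whose genotype effects follow X @ beta.

    Per phase, per-gene strain means are baseline + X_gene @ beta(strain)
    with wild type at baseline; replicates add N(0, noise_sd^2).  The noise
    stream is independent of the promoter stream (seed offset by a fixed
    constant) so the same promoters can carry different noise realisations.
    """
    genes = counts.genes
    missing = [g for g in genes if g not in set(counts.frame["gene_id"])]
    if missing:
        raise ValueError(f"counts missing for genes: {missing[:5]}")
    rng = np.random.default_rng((config.seed + 104729) % 2**31)

    from regulon_shift.activity import build_design

    design = build_design(counts, motifs=[m.name for m in config.motifs], genes=genes)
    X = design.to_numpy(dtype=float)
    n = len(genes)
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)

    columns: dict[str, np.ndarray] = {}
    for phase in PHASES:
        effects = _solve_strain_effects(config, phase)
        for strain in STRAINS:
            if strain == "wt" or effects is None:
                mean = baseline
            else:
                mean = baseline + X @ effects[strain]
            for rep in range(1, config.n_replicates + 1):
                noise = (
                    config.noise_sd * rng.standard_normal(n)
                    if config.noise_sd > 0
                    else 0.0
                )
                columns[f"{strain}.{phase}.{rep}"] = mean + noise
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(frame)


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Full synthetic study: promoters, counts, expression and planted truth."""
    if config is None:
        config = SimulationConfig()
    promoters, counts = simulate_promoters(config)
    expression = simulate_expression(counts, config)
    return SyntheticStudy(
        promoters=promoters,
        expression=expression,
        true_counts=counts,
        true_activity=true_activity_map(config),
        config=config,
    )
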