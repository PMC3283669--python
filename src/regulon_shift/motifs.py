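"""Orientation-resolved exact-word motif scanning of promoter sequences.

The two motifs of interest are the stress response element (STRE, 5-mer
AGGGG, bound by Msn2/4 and Rph1) and the post-diauxic shift element (PDS,
6-mer AGGGAT, bound by Gis1).  A "forward" occurrence is the motif word as
written on the promoter's coding strand (the strand read 5'->3' toward the
start codon); a "reverse" occurrence is its reverse complement on the same
strand.  Overlapping occurrences are all counted: AGGGG self-overlaps in
G-runs, so greedy non-overlapping counting would undercount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC one-letter degenerate codes accepted in motif words (one per word).
_IUPAC = {
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_IUPAC_COMP = {"W": "W", "S": "S", "R": "Y", "Y": "R", "K": "M", "M": "K",
               "B": "V", "D": "H", "H": "D", "V": "B"}


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _rc_word(word: str) -> str:
    out = []
    for base in reversed(word):
        out.append(_IUPAC_COMP.get(base, base.translate(_COMPLEMENT)))
    return "".join(out)


@dataclass(frozen=True)
class MotifSpec:
    """A named DNA word; the reverse pattern is derived by reverse complement.

    At most one degenerate IUPAC position is allowed, enough to express the
    long PDS consensus T(A/T)AGGGAT as TWAGGGAT for sensitivity analyses.
    """

    name: str
    forward: str
    reverse: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        word = self.forward.upper()
        if len(word) < 4:
            raise ValueError(f"motif {self.name!r}: word {word!r} shorter than 4 bp")
        degenerate = [b for b in word if b in _IUPAC]
        bad = [b for b in word if b not in "ACGT" and b not in _IUPAC]
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid bases {bad!r}")
        if len(degenerate) > 1:
            raise ValueError(
                f"motif {self.name!r}: at most one degenerate position supported"
            )
        object.__setattr__(self, "forward", word)
        object.__setattr__(self, "reverse", _rc_word(word))

    def __len__(self) -> int:
        return len(self.forward)

    def expand(self, orientation: str = "fwd") -> tuple[str, ...]:
        """Concrete ACGT words matched in the given orientation."""
        word = self.forward if orientation == "fwd" else self.reverse
        for i, base in enumerate(word):
            if base in _IUPAC:
                return tuple(word[:i] + b + word[i + 1:] for b in _IUPAC[base])
        return (word,)


#: Stress response element, AGGGG / CCCCT.
STRE = MotifSpec("STRE", "AGGGG")
#: Post-diauxic shift element as used in the quantitative analyses, AGGGAT / ATCCCT.
PDS = MotifSpec("PDS", "AGGGAT")

DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (STRE, PDS)


def _find_all(sequence: str, word: str) -> list[int]:
    """Start offsets of every (possibly overlapping) occurrence of word."""
    positions: list[int] = []
    start = sequence.find(word)
    while start != -1:
        positions.append(start)
        start = sequence.find(word, start + 1)
    return positions


def count_motif_occurrences(
    sequence: str, motif: MotifSpec
) -> tuple[int, int, list[int], list[int]]:
    """Count forward and reverse occurrences of a motif in one sequence.

    Returns ``(fwd_count, rev_count, fwd_positions, rev_positions)`` with
    positions as 0-based start offsets.  The sequence is uppercased; N never
    matches (exact string matching over ACGT).  An empty sequence yields
    zeros.
    """
    seq = sequence.upper()
    fwd_positions: list[int] = []
    rev_positions: list[int] = []
    for word in motif.expand("fwd"):
        fwd_positions.extend(_find_all(seq, word))
    for word in motif.expand("rev"):
        rev_positions.extend(_find_all(seq, word))
    fwd_positions.sort()
    rev_positions.sort()
    return len(fwd_positions), len(rev_positions), fwd_positions, rev_positions


class MotifCountTable:
    """Per (gene, motif) forward/reverse occurrence counts and positions.

    Backed by a tidy DataFrame with columns ``gene_id, motif, fwd_count,
    rev_count, fwd_positions, rev_positions`` (positions ';'-joined in the
    TSV representation, lists in memory).
    """

    COLUMNS = ["gene_id", "motif", "fwd_count", "rev_count",
               "fwd_positions", "rev_positions"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if frame.duplicated(["gene_id", "motif"]).any():
            dupes = frame.loc[frame.duplicated(["gene_id", "motif"]), "gene_id"]
            raise ValueError(f"duplicate (gene, motif) rows: {sorted(set(dupes))[:5]}")
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["gene_id"]))

    @property
    def motifs(self) -> list[str]:
        return list(dict.fromkeys(self.frame["motif"]))

    def counts(self, motif: str, orientation: str = "total") -> pd.Series:
        """Per-gene counts for one motif: 'fwd', 'rev' or 'total'."""
        sub = self.frame[self.frame["motif"] == motif].set_index("gene_id")
        if sub.empty:
            raise KeyError(f"motif {motif!r} not in table")
        if orientation == "total":
            return sub["fwd_count"] + sub["rev_count"]
        return sub[f"{orientation}_count"]

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        for col in ("fwd_positions", "rev_positions"):
            out[col] = out[col].map(lambda ps: ";".join(map(str, ps)))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MotifCountTable":
        frame = pd.read_csv(
            path, sep="\t",
            dtype={"gene_id": str, "motif": str,
                   "fwd_positions": str, "rev_positions": str},
        )
        for col in ("fwd_positions", "rev_positions"):
            frame[col] = (
                frame[col]
                .fillna("")
                .map(lambda s: [int(x) for x in s.split(";") if x])
            )
        return cls(frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MotifCountTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


def scan_promoters(
    promoters: Mapping[str, str] | Iterable,
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
) -> MotifCountTable:
    """Scan every promoter for every motif (full cross product).

    ``promoters`` is either a mapping of gene id to sequence or an iterable
    of objects with ``gene_id`` and ``sequence`` attributes.  Duplicate gene
    ids are an error.
    """
    if isinstance(promoters, Mapping):
        items = list(promoters.items())
    else:
        items = [(p.gene_id, p.sequence) for p in promoters]
    if not items:
        raise ValueError("no promoters to scan")
    if not motifs:
        raise ValueError("no motifs to scan for")
    seen: set[str] = set()
    for gene_id, _ in items:
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
    rows = []
    for gene_id, seq in items:
        for motif in motifs:
            fwd, rev, fpos, rpos = count_motif_occurrences(seq, motif)
            rows.append((gene_id, motif.name, fwd, rev, fpos, rpos))
    return MotifCountTable(pd.DataFrame(rows, columns=MotifCountTable.COLUMNS))


def summarize_density(
    table: MotifCountTable, gene_set: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-motif mean forward/reverse/total occurrences per promoter.

    Rows are motifs, columns ``fwd_per_promoter, rev_per_promoter,
    total_per_promoter, fwd_rev_ratio, n_promoters``.  The forward/reverse
    ratio is NaN when the reverse mean is zero.  ``gene_set=None`` uses all
    genes in the table; genes in the set but not the table are an error.
    """
    frame = table.frame
    if gene_set is not None:
        wanted = set(gene_set)
        if not wanted:
            raise ValueError("empty gene set")
        known = set(frame["gene_id"])
        missing = wanted - known
        if missing:
            raise KeyError(f"genes not in count table: {sorted(missing)[:5]}")
        frame = frame[frame["gene_id"].isin(wanted)]
    rows = {}
    for motif, sub in frame.groupby("motif", sort=False):
        fwd = sub["fwd_count"].mean()
        rev = sub["rev_count"].mean()
        rows[motif] = {
            "fwd_per_promoter": fwd,
            "rev_per_promoter": rev,
            "total_per_promoter": fwd + rev,
            "fwd_rev_ratio": fwd / rev if rev > 0 else float("nan"),
            "n_promoters": len(sub),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "motif"
    return out.loc[table.motifs if gene_set is None else [m for m in table.motifs if m in out.index]]
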