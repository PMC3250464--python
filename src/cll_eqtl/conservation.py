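"""Evolutionarily-conserved-region (ECR) filter for eQTL SNPs.

A SNP passes the filter when its ±100 bp neighbourhood overlaps a
conserved stretch of a human–mouse or human–rat pairwise alignment.  A
conserved stretch is a maximal run of alignment columns in which *every*
100-column sliding subwindow reaches at least 70% identity; gap and N
columns count as mismatches and the identity denominator is the full
column count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

GAPLIKE = {"-", "N"}


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped pairwise alignment anchored on the human sequence.

    ``start`` is the 1-based human coordinate of the first non-gap human
    column; ``human``/``other`` are equal-length strings over
    {A,C,G,T,-,N}.
    """

    species: str
    chromosome: str
    start: int
    human: str
    other: str

    def __post_init__(self) -> None:
        if len(self.human) != len(self.other):
            raise ValueError("aligned sequences must have equal length")
        alphabet = set("ACGTN-")
        if set(self.human.upper()) - alphabet or set(self.other.upper()) - alphabet:
            raise ValueError("alignment contains symbols outside {A,C,G,T,N,-}")
        object.__setattr__(self, "human", self.human.upper())
        object.__setattr__(self, "other", self.other.upper())

    @property
    def n_columns(self) -> int:
        return len(self.human)

    def match_columns(self) -> np.ndarray:
        """Boolean per column: identical, non-gap, non-N."""
        h = np.frombuffer(self.human.encode(), dtype="S1")
        o = np.frombuffer(self.other.encode(), dtype="S1")
        bad = np.isin(h, [b"-", b"N"]) | np.isin(o, [b"-", b"N"])
        return (h == o) & ~bad

    def human_positions(self) -> np.ndarray:
        """1-based human coordinate per column (gap columns inherit the
        coordinate of the previous non-gap column)."""
        nongap = np.array([c != "-" for c in self.human])
        return self.start - 1 + np.maximum(1, np.cumsum(nongap))

    def human_span(self) -> tuple[int, int]:
        pos = self.human_positions()
        return int(pos[0]), int(pos[-1])


def window_identity(alignment: PairwiseAlignment, col_start: int, col_end: int) -> float:
    """Identity fraction over columns [col_start, col_end) (0-based)."""
    if not (0 <= col_start < col_end <= alignment.n_columns):
        raise ValueError("invalid column range")
    m = alignment.match_columns()[col_start:col_end]
    return float(m.sum()) / (col_end - col_start)


def find_ecrs(
    alignment: PairwiseAlignment,
    min_len: int = 100,
    min_identity: float = 0.70,
) -> list[tuple[int, int]]:
    """Maximal conserved column intervals, 0-based half-open.

    An interval qualifies when every ``min_len``-column subwindow within
    it has identity ≥ ``min_identity`` (boundary inclusive: exactly
    70/100 passes).  Intervals are maximal runs of qualifying window
    starts and therefore have length ≥ ``min_len``.
    """
    n = alignment.n_columns
    if n < min_len:
        return []
    m = alignment.match_columns().astype(int)
    csum = np.concatenate([[0], np.cumsum(m)])
    window_matches = csum[min_len:] - csum[:-min_len]  # per start offset
    # threshold with integer arithmetic to keep 70/100 exact
    ok = window_matches >= int(np.ceil(min_identity * min_len - 1e-9))
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            intervals.append((i, j + min_len))
            i = j + 1
        i += 1
    return intervals


@dataclass(frozen=True)
class ConservationCall:
    snp_id: str
    status: str  # "conserved" | "not_conserved" | "unevaluable"
    species: tuple[str, ...] = ()
    best_identity: float = float("nan")
    best_interval: tuple[int, int] | None = None  # human bp, inclusive

    @property
    def conserved(self) -> bool:
        return self.status == "conserved"


def snp_in_conserved_region(
    snp_id: str,
    chromosome: str,
    position: int,
    alignments: Iterable[PairwiseAlignment],
    flank: int = 100,
    min_len: int = 100,
    min_identity: float = 0.70,
    species_accepted: Sequence[str] = ("mouse", "rat"),
) -> ConservationCall:
    """Does any accepted species' ECR overlap [position−flank, position+flank]?

    A SNP covered by no alignment is 'unevaluable', distinct from a
    covered-but-unconserved 'not_conserved'.
    """
    lo, hi = position - flank, position + flank
    covered = False
    supporting: list[str] = []
    best_identity = float("nan")
    best_interval: tuple[int, int] | None = None
    for aln in alignments:
        if aln.chromosome != chromosome or aln.species not in species_accepted:
            continue
        span_lo, span_hi = aln.human_span()
        if not (span_lo <= position <= span_hi):
            continue
        covered = True
        pos_per_col = aln.human_positions()
        for c0, c1 in find_ecrs(aln, min_len, min_identity):
            h0, h1 = int(pos_per_col[c0]), int(pos_per_col[c1 - 1])
            if h0 <= hi and h1 >= lo:
                if aln.species not in supporting:
                    supporting.append(aln.species)
                ident = window_identity(aln, c0, c1)
                if not (ident <= best_identity):  # NaN-safe max
                    best_identity = ident
                    best_interval = (h0, h1)
    if not covered:
        return ConservationCall(snp_id, "unevaluable")
    if supporting:
        return ConservationCall(
            snp_id, "conserved", tuple(supporting), best_identity, best_interval
        )
    return ConservationCall(snp_id, "not_conserved")


def conserved_fraction(calls: Sequence[ConservationCall]) -> float:
    """Percentage of evaluated SNPs called conserved (1 decimal)."""
    evaluated = [c for c in calls if c.status != "unevaluable"]
    if not evaluated:
        return float("nan")
    frac = sum(c.conserved for c in evaluated) / len(evaluated)
    return round(100.0 * frac, 1)
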