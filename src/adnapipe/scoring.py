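"""Alignment scoring scheme and Karlin-Altschul statistics.

The default scheme mirrors a Mega-BLAST-like nucleotide search: match +1,
mismatch -3, affine gaps costing ``gap_open + k * gap_extend`` for a gap of
length k.  Bitscores and e-values use the Karlin-Altschul transformation

    bits = (lambda * S - ln K) / ln 2
    E    = m * n * 2 ** (-bits)

with the effective search space taken as query length times total database
length (no edge correction).  lambda and K for the +1/-3 scheme are the
standard ungapped values, which are a good approximation for these
stringent gap costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 1.374
    karlin_k: float = 0.711

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be non-positive (extend strictly)")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: float, query_length: int, db_length: int) -> float:
        return query_length * db_length * 2.0 ** (-self.bitscore(raw_score))

    def gap_cost(self, length: int) -> int:
        """Total (negative) score of a gap of ``length`` columns."""
        if length <= 0:
            return 0
        return self.gap_open + length * self.gap_extend


DEFAULT_SCHEME = ScoringScheme()


def score_pair(a: int, b: int, scheme: ScoringScheme) -> int:
    """Score one alignment column of two code characters (gap code 4).

    Gap-vs-gap columns score 0; gap-vs-base columns are charged the extend
    penalty only (the caller accounts for gap opening).
    """
    from .seq import GAP_CODE

    if a == GAP_CODE and b == GAP_CODE:
        return 0
    if a == GAP_CODE or b == GAP_CODE:
        return scheme.gap_extend
    return scheme.match if a == b else scheme.mismatch


def rescore_alignment(row_a: str, row_b: str, scheme: ScoringScheme) -> int:
    """Recompute the affine-gap score of a pair of gapped rows.

    Used to verify the LocalHit invariant that the reported aligned strings
    reproduce the reported raw score.
    """
    from .seq import GAP_CODE, encode

    a = encode(row_a)
    b = encode(row_b)
    if a.size != b.size:
        raise ValueError("gapped rows differ in length")
    score = 0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == GAP_CODE and y == GAP_CODE:
            continue
        if x == GAP_CODE:
            score += scheme.gap_extend + (0 if in_gap_a else scheme.gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == GAP_CODE:
            score += scheme.gap_extend + (0 if in_gap_b else scheme.gap_open)
            in_gap_a, in_gap_b = False, True
        else:
            score += scheme.match if x == y else scheme.mismatch
            in_gap_a = in_gap_b = False
    return score
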