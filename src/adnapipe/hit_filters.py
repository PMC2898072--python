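"""The filter stack applied between read classification and divergence
estimation.

Four filters protect the triangulation from non-orthologous and
uninformative alignments:

* unique-best  -- the read has exactly one best local hit to each genome;
* orthology    -- the two hit locations map onto each other through the
  whole-genome alignment with >= 90% reciprocal overlap;
* bitscore gap -- the best hit to the primary genome beats the second
  best by at least 6 bits (reads from duplicated loci produce near-tied
  hits and are removed here);
* length       -- the read is strictly longer than 35 bp;
* positive semi-global score (computed upstream, enforced here).

Boundary semantics: overlap >= 0.90 passes, gap >= 6 bits passes, length
must strictly exceed 35 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError
from .local_search import LocalHit
from .synth_genomes import GenomePairAlignment

FILTER_ORDER = ("unique", "orthology", "bitscore_gap", "length", "positive_score")


@dataclass(frozen=True)
class FilterConfig:
    min_length: int = 35  # strict: length must exceed this
    min_bitscore_gap: float = 6.0
    min_reciprocal_overlap: float = 0.90
    require_unique_best: bool = True
    require_positive_semiglobal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_reciprocal_overlap <= 1.0:
            raise ParameterError("overlap must lie in (0, 1]")
        if self.min_bitscore_gap < 0:
            raise ParameterError("bitscore gap must be >= 0")


@dataclass
class ReadContext:
    """Everything the filter stack needs to know about one read."""

    read_id: str
    length: int
    hits_a: list[LocalHit] = field(default_factory=list)
    hits_b: list[LocalHit] = field(default_factory=list)
    unique_a: bool = False
    unique_b: bool = False
    semiglobal_score: int | None = None


@dataclass
class FilterReport:
    """Per-read filter outcomes; a read survives iff every enabled
    filter passes (the conjunction is order-independent; the stated
    order is only how counts are reported)."""

    per_read: dict[str, dict[str, bool]] = field(default_factory=dict)
    pass_counts: dict[str, int] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\t" + "\t".join(FILTER_ORDER) + "\tsurvives\n")
            for rid, flags in sorted(self.per_read.items()):
                vals = "\t".join(str(int(flags[f])) for f in FILTER_ORDER)
                fh.write(f"{rid}\t{vals}\t{int(rid in set(self.survivors))}\n")


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def orthology_filter(
    hit_a: LocalHit,
    hit_b: LocalHit,
    alignment: GenomePairAlignment,
    min_overlap: float = 0.90,
) -> bool:
    """Reciprocal liftover verification of two hit locations.

    Lifting the genome-A hit interval must overlap the genome-B hit by
    at least ``min_overlap`` of the genome-B interval, and vice versa.
    A liftover that maps nowhere fails the filter.
    """
    a_iv = (hit_a.target_start, hit_a.target_end)
    b_iv = (hit_b.target_start, hit_b.target_end)
    lifted_a = alignment.liftover(a_iv[0], a_iv[1], "A->B")
    if lifted_a is None:
        return False
    if _interval_overlap(lifted_a, b_iv) < min_overlap * (b_iv[1] - b_iv[0]):
        return False
    lifted_b = alignment.liftover(b_iv[0], b_iv[1], "B->A")
    if lifted_b is None:
        return False
    if _interval_overlap(lifted_b, a_iv) < min_overlap * (a_iv[1] - a_iv[0]):
        return False
    return True


def bitscore_gap_filter(hits: list[LocalHit], min_gap: float = 6.0) -> bool:
    """True iff the best hit beats the second best by >= ``min_gap`` bits
    (single-hit reads pass trivially)."""
    if len(hits) < 2:
        return True
    scores = sorted((h.bitscore for h in hits), reverse=True)
    return scores[0] - scores[1] >= min_gap


def length_filter(read_length: int, min_length: int = 35) -> bool:
    """True iff the read is strictly longer than ``min_length`` bp."""
    return read_length > min_length


def apply_filters(
    reads: list[ReadContext],
    alignment: GenomePairAlignment,
    config: FilterConfig = FilterConfig(),
    enabled: tuple[str, ...] = FILTER_ORDER,
) -> FilterReport:
    """Evaluate the filter stack on every read.

    ``enabled`` selects which filters participate in the survival
    conjunction; all filters are still evaluated and reported.
    """
    report = FilterReport(pass_counts={f: 0 for f in FILTER_ORDER})
    for ctx in reads:
        flags: dict[str, bool] = {}
        flags["unique"] = ctx.unique_a and ctx.unique_b
        if ctx.hits_a and ctx.hits_b:
            flags["orthology"] = orthology_filter(
                ctx.hits_a[0], ctx.hits_b[0], alignment, config.min_reciprocal_overlap
            )
        else:
            flags["orthology"] = False
        flags["bitscore_gap"] = bitscore_gap_filter(ctx.hits_a, config.min_bitscore_gap)
        flags["length"] = length_filter(ctx.length, config.min_length)
        flags["positive_score"] = (
            ctx.semiglobal_score is not None and ctx.semiglobal_score > 0
        )
        for f in FILTER_ORDER:
            if flags[f]:
                report.pass_counts[f] += 1
        report.per_read[ctx.read_id] = flags
        if all(flags[f] for f in enabled):
            report.survivors.append(ctx.read_id)
    return report
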