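"""Synthetic diverged genome pairs with a known whole-genome alignment.

This module stands in for the real reference genomes and their UCSC
whole-genome alignment / liftover chains.  Two genomes descend from a
common ancestor by a time-symmetric two-lineage simulation: each lineage
independently receives half the requested pairwise substitution and indel
rates, so an outgroup attaching anywhere along the path between the two
genomes sees a roughly central ancestor -- the geometry the divergence
triangulation assumes.

Coordinates are 0-based half-open throughout.  The alignment is the exact
record of the mutations applied, so it serves as ground truth for
orthology (liftover) and for the fragment simulator's step-1/step-3
variant lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import CoordinateError, DegenerateInputError, ParameterError
from .seq import GAP_CODE, decode, encode

DEFAULT_PAIR_DIVERGENCE = 0.012
DEFAULT_INDEL_RATE = 5e-4
DEFAULT_INDEL_GEOM_P = 0.5


@dataclass
class SyntheticGenome:
    """A labelled chromosome-like sequence over the strict ACGT alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ParameterError("genome length must be >= 1")
        self._codes = encode(self.sequence)
        if self._codes.max(initial=0) >= GAP_CODE:
            raise ParameterError("genome alphabet must be strictly ACGT")

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentBlock:
    """One colinear gapped block of a genome-pair alignment."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ParameterError("gapped rows must have equal length")
        self.col_a = encode(self.gapped_a)
        self.col_b = encode(self.gapped_b)
        if np.any((self.col_a == GAP_CODE) & (self.col_b == GAP_CODE)):
            raise ParameterError("no alignment column may be gap in both rows")
        # per-column source coordinates (-1 where the row has a gap)
        a_mask = self.col_a != GAP_CODE
        b_mask = self.col_b != GAP_CODE
        self.a_pos = np.where(a_mask, self.a_start + np.cumsum(a_mask) - 1, -1)
        self.b_pos = np.where(b_mask, self.b_start + np.cumsum(b_mask) - 1, -1)
        if a_mask.sum() != self.a_end - self.a_start:
            raise ParameterError("ungapped row A does not span [a_start, a_end)")
        if b_mask.sum() != self.b_end - self.b_start:
            raise ParameterError("ungapped row B does not span [b_start, b_end)")
        # column index of each A (resp. B) position inside this block
        self.a_col = np.flatnonzero(a_mask)
        self.b_col = np.flatnonzero(b_mask)


@dataclass
class SubstitutionMatrix:
    """4x4 conditional substitution probabilities (from-base x to-base).

    Rows hold the distribution of the replacement base given that the
    original base mutates; diagonals are zero and each row sums to one.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, 4):
            raise ParameterError("substitution matrix must be 4x4")
        if np.any(p < 0) or np.any(np.diag(p) != 0):
            raise ParameterError("entries must be >= 0 with zero diagonal")
        if not np.allclose(p.sum(axis=1), 1.0):
            raise ParameterError("off-diagonal rows must sum to 1")
        self.probs = p

    @classmethod
    def uniform(cls) -> "SubstitutionMatrix":
        p = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(p, 0.0)
        return cls(p)


@dataclass
class GenomePairStats:
    """Summary statistics of a genome-pair alignment.

    ``r`` is the average per-aligned-site nucleotide substitution rate
    (mismatching ungapped columns / ungapped columns); ``indel_rate``
    counts indel events per aligned site.
    """

    r: float
    indel_rate: float
    matrix: SubstitutionMatrix

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError("r must lie in [0, 1]")


@dataclass
class GenomePairAlignment:
    """Colinear block map between two genomes; ground truth for liftover."""

    name_a: str
    name_b: str
    length_a: int
    length_b: int
    blocks: list[AlignmentBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks.sort(key=lambda b: b.a_start)
        prev_end = 0
        for blk in self.blocks:
            if blk.a_start < prev_end:
                raise ParameterError("blocks overlap on genome A")
            prev_end = blk.a_end

    # -- internal lookups ------------------------------------------------
    def _block_for(self, genome: Literal["A", "B"], pos: int) -> AlignmentBlock | None:
        for blk in self.blocks:
            lo, hi = (blk.a_start, blk.a_end) if genome == "A" else (blk.b_start, blk.b_end)
            if lo <= pos < hi:
                return blk
        return None

    def column_images(
        self, genome: Literal["A", "B"], start: int, end: int
    ) -> np.ndarray:
        """Positions in the other genome aligned to [start, end), per column."""
        images: list[np.ndarray] = []
        for blk in self.blocks:
            lo, src_col, dst_pos = (
                (blk.a_start, blk.a_col, blk.b_pos)
                if genome == "A"
                else (blk.b_start, blk.b_col, blk.a_pos)
            )
            hi = blk.a_end if genome == "A" else blk.b_end
            s, e = max(start, lo), min(end, hi)
            if s >= e:
                continue
            cols = src_col[s - lo : e - lo]
            img = dst_pos[cols]
            images.append(img[img >= 0])
        if not images:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(images)

    # -- operations ------------------------------------------------------
    def liftover(
        self, start: int, end: int, direction: Literal["A->B", "B->A"] = "A->B"
    ) -> tuple[int, int] | None:
        """Map a half-open interval through the alignment.

        Returns the interval spanned by the images of the interval's
        aligned positions in the other genome, or ``None`` if no position
        is aligned (e.g. the interval falls entirely inside a deletion).
        """
        genome: Literal["A", "B"] = "A" if direction == "A->B" else "B"
        length = self.length_a if genome == "A" else self.length_b
        if not (0 <= start < end <= length):
            raise CoordinateError(
                f"interval [{start}, {end}) outside genome of length {length}"
            )
        img = self.column_images(genome, start, end)
        if img.size == 0:
            return None
        return int(img.min()), int(img.max()) + 1

    def ungapped_column_count(self) -> int:
        return sum(
            int(np.sum((b.col_a != GAP_CODE) & (b.col_b != GAP_CODE)))
            for b in self.blocks
        )

    def mismatch_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """A-coordinates of mismatching ungapped columns and the B variant."""
        cached = getattr(self, "_mismatch_cache", None)
        if cached is not None:
            return cached
        pos, var = [], []
        for blk in self.blocks:
            mask = (
                (blk.col_a != GAP_CODE)
                & (blk.col_b != GAP_CODE)
                & (blk.col_a != blk.col_b)
            )
            pos.append(blk.a_pos[mask])
            var.append(blk.col_b[mask])
        if not pos:
            result = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8))
        else:
            result = (np.concatenate(pos), np.concatenate(var))
        self._mismatch_cache = result
        return result

    def indel_events(self) -> list[tuple[str, int, int, str]]:
        """Indel events as ``(kind, a_start, a_end, b_bases)`` tuples.

        ``("del_in_b", a0, a1, "")`` -- genome-A bases [a0, a1) absent in B;
        ``("ins_in_b", a0, a0, bases)`` -- B bases inserted between A
        positions a0-1 and a0.
        """
        cached = getattr(self, "_indel_cache", None)
        if cached is not None:
            return cached
        events: list[tuple[str, int, int, str]] = []
        for blk in self.blocks:
            gap_b = blk.col_b == GAP_CODE
            gap_a = blk.col_a == GAP_CODE
            # deletions in B: runs of gap in row B
            for s, e in _runs(gap_b):
                events.append(("del_in_b", int(blk.a_pos[s]), int(blk.a_pos[e - 1]) + 1, ""))
            # insertions in B: runs of gap in row A, anchored after the
            # previous A position
            if gap_a.any():
                last_a = np.maximum.accumulate(blk.a_pos)
                for s, e in _runs(gap_a):
                    anchor = int(last_a[s - 1]) + 1 if s > 0 and last_a[s - 1] >= 0 else blk.a_start
                    events.append(("ins_in_b", anchor, anchor, decode(blk.col_b[s:e])))
        events.sort(key=lambda ev: (ev[1], ev[0]))
        self._indel_cache = events
        return events

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#pair\t{self.name_a}\t{self.length_a}\t{self.name_b}\t{self.length_b}\n")
            for b in self.blocks:
                fh.write(
                    f"{b.a_start}\t{b.a_end}\t{b.b_start}\t{b.b_end}\t"
                    f"{b.strand}\t{b.gapped_a}\t{b.gapped_b}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomePairAlignment":
        blocks = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#pair":
                raise ParameterError("not a genome-pair alignment TSV")
            name_a, length_a, name_b, length_b = (
                header[1],
                int(header[2]),
                header[3],
                int(header[4]),
            )
            for line in fh:
                a0, a1, b0, b1, strand, ga, gb = line.rstrip("\n").split("\t")
                blocks.append(
                    AlignmentBlock(int(a0), int(a1), int(b0), int(b1), strand, ga, gb)
                )
        return cls(name_a, name_b, length_a, length_b, blocks)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _apply_lineage_mutations(
    ancestor: np.ndarray,
    sub_rate: float,
    indel_rate: float,
    indel_geom_p: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Substituted copy, deletion mask (ancestor coords) and insertions.

    Insertions are keyed by the ancestor position *after* which the bases
    go (-1 inserts before the first base).
    """
    length = ancestor.size
    seq = ancestor.copy()
    mask = rng.random(length) < sub_rate
    shift = rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)
    seq[mask] = (seq[mask] + shift) % 4

    deleted = np.zeros(length, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    sites = np.flatnonzero(rng.random(length) < indel_rate)
    for pos in sites:
        ln = int(rng.geometric(indel_geom_p))
        if rng.random() < 0.5:
            deleted[pos : pos + ln] = True
        else:
            ins = rng.integers(0, 4, ln, dtype=np.uint8)
            insertions[int(pos)] = np.concatenate([insertions.get(int(pos), np.empty(0, np.uint8)), ins])
    return seq, deleted, insertions


def simulate_genome_pair(
    length: int,
    pair_divergence: float = DEFAULT_PAIR_DIVERGENCE,
    indel_rate: float = DEFAULT_INDEL_RATE,
    indel_geom_p: float = DEFAULT_INDEL_GEOM_P,
    seed: int = 0,
    name_a: str = "gA",
    name_b: str = "gB",
) -> tuple[SyntheticGenome, SyntheticGenome, GenomePairAlignment]:
    """Simulate a diverged genome pair with its exact alignment.

    A common ancestor of ``length`` bp receives substitutions at rate
    ``pair_divergence / 2`` and indel events at ``indel_rate / 2`` per
    site on each of two independent lineages.  Indel lengths are
    geometric with parameter ``indel_geom_p``; inserted bases are uniform
    over ACGT.  The default calibration (1.2% substitutions, 5e-4 indels
    per site) emulates a human/chimpanzee-like pair at a 6.5-Myr split.
    """
    if length < 1000:
        raise ParameterError("length must be >= 1000")
    if not 0.0 <= pair_divergence < 0.75:
        raise ParameterError("pair_divergence must lie in [0, 0.75)")
    if indel_rate < 0 or not 0 < indel_geom_p <= 1:
        raise ParameterError("invalid indel parameters")

    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, length, dtype=np.uint8)
    seq_a, del_a, ins_a = _apply_lineage_mutations(
        ancestor, pair_divergence / 2.0, indel_rate / 2.0, indel_geom_p, rng
    )
    seq_b, del_b, ins_b = _apply_lineage_mutations(
        ancestor, pair_divergence / 2.0, indel_rate / 2.0, indel_geom_p, rng
    )

    # columns for ancestor positions; sites deleted on both lineages leave
    # no column at all (no gap-gap columns)
    keep = ~(del_a & del_b)
    row_a = np.where(del_a, GAP_CODE, seq_a).astype(np.uint8)[keep]
    row_b = np.where(del_b, GAP_CODE, seq_b).astype(np.uint8)[keep]

    # splice insertions (each becomes a run of base/gap columns); an
    # insertion after ancestor position p lands after p's column
    col_of = np.cumsum(keep) - 1  # ancestor pos -> column index (if kept)
    splice: list[tuple[int, np.ndarray, np.ndarray]] = []
    for pos, bases in ins_a.items():
        at = col_of[pos] + 1 if pos >= 0 else 0
        splice.append((int(at), bases, np.full(bases.size, GAP_CODE, np.uint8)))
    for pos, bases in ins_b.items():
        at = col_of[pos] + 1 if pos >= 0 else 0
        splice.append((int(at), np.full(bases.size, GAP_CODE, np.uint8), bases))
    if splice:
        splice.sort(key=lambda t: t[0])
        parts_a, parts_b, prev = [], [], 0
        for at, pa, pb in splice:
            parts_a.extend([row_a[prev:at], pa])
            parts_b.extend([row_b[prev:at], pb])
            prev = at
        parts_a.append(row_a[prev:])
        parts_b.append(row_b[prev:])
        row_a = np.concatenate(parts_a)
        row_b = np.concatenate(parts_b)

    genome_a = SyntheticGenome(name_a, decode(row_a[row_a != GAP_CODE]))
    genome_b = SyntheticGenome(name_b, decode(row_b[row_b != GAP_CODE]))
    block = AlignmentBlock(
        0, len(genome_a), 0, len(genome_b), "+", decode(row_a), decode(row_b)
    )
    alignment = GenomePairAlignment(
        name_a, name_b, len(genome_a), len(genome_b), [block]
    )
    return genome_a, genome_b, alignment


def estimate_substitution_stats(alignment: GenomePairAlignment) -> GenomePairStats:
    """Estimate r, the indel rate and the substitution matrix.

    ``r`` is the mismatch fraction over ungapped columns.  The matrix is
    tallied from mismatching columns in both directions (A->B and B->A,
    making it symmetric) with a +1 pseudocount per off-diagonal cell so
    small alignments never produce zero rows.
    """
    ungapped = alignment.ungapped_column_count()
    if ungapped == 0:
        raise DegenerateInputError("alignment has no ungapped columns")
    counts = np.ones((4, 4), dtype=float)
    np.fill_diagonal(counts, 0.0)
    mismatches = 0
    n_events = 0
    for blk in alignment.blocks:
        mask = (
            (blk.col_a != GAP_CODE)
            & (blk.col_b != GAP_CODE)
            & (blk.col_a != blk.col_b)
        )
        mismatches += int(mask.sum())
        np.add.at(counts, (blk.col_a[mask], blk.col_b[mask]), 1.0)
        np.add.at(counts, (blk.col_b[mask], blk.col_a[mask]), 1.0)
    n_events = len(alignment.indel_events())
    matrix = SubstitutionMatrix(counts / counts.sum(axis=1, keepdims=True))
    return GenomePairStats(
        r=mismatches / ungapped, indel_rate=n_events / ungapped, matrix=matrix
    )


def liftover(
    interval: tuple[str, int, int],
    alignment: GenomePairAlignment,
    direction: Literal["A->B", "B->A"] = "A->B",
) -> tuple[int, int] | None:
    """Functional wrapper around :meth:`GenomePairAlignment.liftover`."""
    _genome, start, end = interval
    return alignment.liftover(start, end, direction)


def simulate_contaminant_db(
    n_sequences: int,
    length: int,
    gc_content: float = 0.5,
    seed: int = 0,
    prefix: str = "decoy",
) -> list[SyntheticGenome]:
    """Random decoy sequences statistically independent of the genome pair.

    Stands in for the microbial/environmental databases a real analysis
    would search against.
    """
    if n_sequences < 0:
        raise ParameterError("n_sequences must be >= 0")
    if not 0.0 <= gc_content <= 1.0:
        raise ParameterError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    return [
        SyntheticGenome(
            f"{prefix}_{i:04d}",
            decode(rng.choice(4, size=length, p=p).astype(np.uint8)),
        )
        for i in range(n_sequences)
    ]
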