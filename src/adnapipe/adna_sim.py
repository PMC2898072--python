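"""Four-step ancient-DNA fragment simulator with full truth tracking.

Fragments are sampled from genome A of a synthetic genome pair (step 0),
then transformed in four steps:

1. lineage divergence -- at every aligned position where the two genomes
   differ, the genome-A base is replaced by the genome-B variant with
   probability ``X / D`` (X = simulated divergence in Myr, D = total
   tree length, 13 Myr for a 6.5-Myr genome-pair split);
2. random substitutions -- every site mutates with probability
   ``X / D * r`` (r = average substitution rate of the pair), the new
   base drawn from the pair's substitution matrix;
3. indels -- every indel event of the pair alignment overlapping the
   fragment is applied as a unit with probability ``X / D``;
4. damage -- single-stranded overhangs at both ends (geometric lengths)
   deaminate C->T at the single-stranded rate; with the nick probability
   the 3' overhang is read as the complementary strand's filled-in copy,
   turning its deamination into G->A; the double-stranded interior
   deaminates at the (much lower) double-stranded rate on both strands.

Every change is logged so that replaying the truth record over the
source substring reproduces each read byte-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CoordinateError, ParameterError, SamplingExhaustedError
from .io import write_fasta
from .seq import decode, encode, revcomp_codes
from .synth_genomes import GenomePairAlignment, GenomePairStats, SyntheticGenome

D_TOTAL_MYR = 13.0  # human/chimp tree length: 2 x 6.5 Myr
MEAN_FRAGMENT_LENGTH = 63.0


@dataclass(frozen=True)
class DamageParams:
    """Parameters of the terminal-deamination damage model."""

    overhang_p: float = 0.3  # geometric parameter; P(overhang >= 1) = p
    nick_prob: float = 0.8
    delta_ss: float = 0.845  # single-stranded C deamination probability
    delta_ds: float = 0.015  # double-stranded C deamination probability

    def __post_init__(self) -> None:
        for name in ("overhang_p", "nick_prob", "delta_ss", "delta_ds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @property
    def p_overhang_nonzero(self) -> float:
        """P(overhang length >= 1) under P(L=k) = (1-p) p^k, k >= 0."""
        return self.overhang_p


@dataclass
class LengthDistribution:
    """Fragment length distribution: empirical histogram or lognormal."""

    lengths: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.lengths.size == 0 or np.any(self.lengths < 1):
            raise ParameterError("length support must be >= 1 bp")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ParameterError("probabilities must sum to 1")

    @classmethod
    def from_histogram(cls, histogram: dict[int, float]) -> "LengthDistribution":
        items = sorted(histogram.items())
        lengths = np.array([l for l, _p in items])
        probs = np.array([p for _l, p in items])
        return cls(lengths, probs / probs.sum())

    @classmethod
    def lognormal(
        cls,
        mean: float = MEAN_FRAGMENT_LENGTH,
        sigma: float = 0.35,
        min_length: int = 20,
        max_length: int = 200,
    ) -> "LengthDistribution":
        """Discretized lognormal with the requested mean (default 63 bp).

        Emulates the right-skewed size distribution of heavily
        fragmented ancient molecules.
        """
        mu = np.log(mean) - sigma**2 / 2.0
        lengths = np.arange(min_length, max_length + 1)
        x = lengths.astype(float)
        dens = np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / x
        probs = dens / dens.sum()
        # nudge the discretized mean back onto the target by re-centering
        obs = float((x * probs).sum())
        mu += np.log(mean / obs)
        dens = np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / x
        probs = dens / dens.sum()
        return cls(lengths, probs)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.lengths, size=n, p=self.probs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LengthDistribution":
        data = np.loadtxt(path, dtype=float, ndmin=2)
        return cls.from_histogram({int(l): p for l, p in data})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for l, p in zip(self.lengths, self.probs):
                fh.write(f"{l}\t{p:.10g}\n")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated divergence dataset."""

    x_myr: float
    n_fragments: int
    d_total_myr: float = D_TOTAL_MYR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_total_myr <= 0:
            raise ParameterError("d_total_myr must be positive")
        if not 0.0 <= self.x_myr <= self.d_total_myr / 2.0:
            raise ParameterError("x_myr must lie in [0, d_total/2]")
        if self.n_fragments < 1:
            raise ParameterError("n_fragments must be >= 1")


@dataclass
class TruthRecord:
    """Per-step change log; replay over the source substring reproduces
    the read exactly (see :func:`replay_truth`)."""

    lineage_subs: list[tuple[int, int, int]] = field(default_factory=list)
    random_subs: list[tuple[int, int, int]] = field(default_factory=list)
    indels: list[tuple[int, str, str]] = field(default_factory=list)
    damage: list[tuple[int, int, int]] = field(default_factory=list)
    overhang_5: int = 0
    overhang_3: int = 0
    nick_complement: bool = False


@dataclass
class AncientFragment:
    """A simulated read with its source interval and truth record.

    ``start``/``end`` are forward-strand genome-A coordinates; for
    minus-strand fragments the read is the reverse complement of the
    (mutated) forward-strand sequence.  Substitution offsets in the
    truth record refer to the forward-strand source substring; damage
    positions refer to final read coordinates.
    """

    fragment_id: str
    sequence: str
    source_name: str
    start: int
    end: int
    strand: str
    truth: TruthRecord = field(default_factory=TruthRecord)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ParameterError("fragment sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


def fragment_header(fragment: AncientFragment) -> str:
    """FASTA header encoding source name, start and strand
    (``N_chr15-75613688_-`` style)."""
    return f"N_{fragment.source_name}-{fragment.start}_{fragment.strand}"


def parse_fragment_header(header: str) -> tuple[str, int, str]:
    """Parse a simulated-read FASTA header into (name, start, strand)."""
    text = header[1:] if header.startswith(">") else header
    parts = text.split("_")
    if len(parts) < 3 or parts[0] != "N":
        raise ParameterError(f"not a simulated-read header: {header!r}")
    name, start = parts[1].rsplit("-", 1)
    strand = parts[2][0]
    if strand not in "+-":
        raise ParameterError(f"bad strand in header: {header!r}")
    return name, int(start), strand


def sample_fragments(
    genome_a: SyntheticGenome,
    alignment: GenomePairAlignment,
    lengths: LengthDistribution,
    n: int,
    seed: int = 0,
    max_attempts_factor: int = 100,
) -> list[AncientFragment]:
    """Sample undamaged genome-A fragments passing the liftover pre-filter.

    Positions are uniform over the genome, strands uniform, lengths from
    ``lengths``.  A candidate is kept only if lifting its interval to
    genome B and back recovers exactly the original interval (the
    round-trip filter that guarantees unambiguous orthology).  Rejected
    candidates are resampled, up to ``max_attempts_factor * n`` draws.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    glen = len(genome_a)
    if glen < int(lengths.lengths.max()):
        raise ParameterError("genome shorter than the maximum fragment length")
    rng = np.random.default_rng(seed)
    fragments: list[AncientFragment] = []
    used_ids: dict[str, int] = {}
    attempts = 0
    cap = max_attempts_factor * n
    while len(fragments) < n:
        if attempts >= cap:
            raise SamplingExhaustedError(
                f"{len(fragments)}/{n} fragments accepted after {attempts} draws"
            )
        batch = min(n - len(fragments) + 64, cap - attempts)
        ls = lengths.sample(rng, batch)
        starts = rng.integers(0, glen - ls + 1)
        strands = rng.integers(0, 2, batch)
        attempts += batch
        for ln, st, sd in zip(ls, starts, strands):
            start, end = int(st), int(st + ln)
            mapped = alignment.liftover(start, end, "A->B")
            if mapped is None:
                continue
            back = alignment.liftover(mapped[0], mapped[1], "B->A")
            if back != (start, end):
                continue
            strand = "+" if sd == 0 else "-"
            base_id = f"N_{genome_a.name}-{start}_{strand}"
            if base_id in used_ids:
                used_ids[base_id] += 1
                frag_id = f"{base_id}.{used_ids[base_id]}"
            else:
                used_ids[base_id] = 1
                frag_id = base_id
            seq = genome_a.sequence[start:end]
            fragments.append(
                AncientFragment(
                    fragment_id=frag_id,
                    sequence=seq,
                    source_name=genome_a.name,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            if len(fragments) == n:
                break
    return fragments


def _check_x(x_myr: float, d_total: float) -> None:
    if not 0.0 <= x_myr <= d_total:
        raise ParameterError("x_myr must lie in [0, d_total]")


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or a ready Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def apply_lineage_divergence(
    fragment: AncientFragment,
    alignment: GenomePairAlignment,
    x_myr: float,
    rng: np.random.Generator,
    d_total: float = D_TOTAL_MYR,
) -> AncientFragment:
    """Step 1: switch genome-A bases to the genome-B variant with
    probability X/D at aligned mismatch columns."""
    rng = as_rng(rng)
    _check_x(x_myr, d_total)
    if fragment.end > alignment.length_a:
        raise CoordinateError("fragment outside the genome-pair alignment")
    pos, var = alignment.mismatch_positions()
    lo = np.searchsorted(pos, fragment.start)
    hi = np.searchsorted(pos, fragment.end)
    codes = encode(fragment.sequence)
    subs: list[tuple[int, int, int]] = []
    p = x_myr / d_total
    if hi > lo:
        take = rng.random(hi - lo) < p
        for idx in np.flatnonzero(take):
            gpos = int(pos[lo + idx])
            off = gpos - fragment.start
            old = int(codes[off])
            new = int(var[lo + idx])
            if old != new:
                codes[off] = new
                subs.append((off, old, new))
    truth = replace(fragment.truth, lineage_subs=subs)
    return replace(fragment, sequence=decode(codes), truth=truth)


def apply_random_substitutions(
    fragment: AncientFragment,
    x_myr: float,
    stats: GenomePairStats,
    rng: np.random.Generator,
    d_total: float = D_TOTAL_MYR,
) -> AncientFragment:
    """Step 2: mutate every site with probability X/D * r, drawing the
    replacement from the substitution matrix row of the original base."""
    rng = as_rng(rng)
    _check_x(x_myr, d_total)
    codes = encode(fragment.sequence)
    p = x_myr / d_total * stats.r
    hit = np.flatnonzero(rng.random(codes.size) < p)
    subs: list[tuple[int, int, int]] = []
    for off in hit:
        old = int(codes[off])
        new = int(rng.choice(4, p=stats.matrix.probs[old]))
        codes[off] = new
        subs.append((int(off), old, new))
    truth = replace(fragment.truth, random_subs=subs)
    return replace(fragment, sequence=decode(codes), truth=truth)


def _indel_lookup(alignment: GenomePairAlignment):
    """Events plus sorted a0 array and maximum event span (cached)."""
    cached = getattr(alignment, "_indel_lookup_cache", None)
    if cached is None:
        events = alignment.indel_events()
        a0s = np.array([e[1] for e in events], dtype=np.int64)
        span = max((e[2] - e[1] for e in events), default=0)
        cached = (events, a0s, span)
        alignment._indel_lookup_cache = cached
    return cached


def _apply_indel_list(seq: str, indels: list[tuple[int, str, str]]) -> str:
    """Apply (offset, kind, bases) events right-to-left; deterministic
    tie order (deletion before insertion at equal offsets)."""
    for off, kind, bases in sorted(indels, key=lambda t: (-t[0], t[1])):
        if kind == "del":
            seq = seq[:off] + seq[off + len(bases) :]
        else:
            seq = seq[:off] + bases + seq[off:]
    return seq


def apply_indels(
    fragment: AncientFragment,
    alignment: GenomePairAlignment,
    x_myr: float,
    rng: np.random.Generator,
    d_total: float = D_TOTAL_MYR,
) -> AncientFragment:
    """Step 3: apply each genome-B indel event overlapping the fragment
    with probability X/D (clipped to the fragment)."""
    rng = as_rng(rng)
    _check_x(x_myr, d_total)
    if fragment.end > alignment.length_a:
        raise CoordinateError("fragment outside the genome-pair alignment")
    p = x_myr / d_total
    events, a0s, span = _indel_lookup(alignment)
    lo = int(np.searchsorted(a0s, fragment.start - span, side="left"))
    hi = int(np.searchsorted(a0s, fragment.end, side="left"))
    applied: list[tuple[int, str, str]] = []
    for kind, a0, a1, bases in events[lo:hi]:
        if kind == "del_in_b":
            s = max(a0, fragment.start)
            e = min(a1, fragment.end)
            if s >= e:
                continue
            if rng.random() < p:
                off = s - fragment.start
                applied.append((off, "del", fragment.sequence[off : off + (e - s)]))
        else:  # ins_in_b between a0-1 and a0
            if not fragment.start < a0 < fragment.end:
                continue
            if rng.random() < p:
                applied.append((a0 - fragment.start, "ins", bases))
    seq = _apply_indel_list(fragment.sequence, applied)
    if not seq:  # a deletion may consume a whole tiny fragment
        return replace(fragment, truth=replace(fragment.truth, indels=[]))
    truth = replace(fragment.truth, indels=sorted(applied))
    return replace(fragment, sequence=seq, truth=truth)


def _sample_overhang(params: DamageParams, rng: np.random.Generator) -> int:
    """Overhang length under P(L=k) = (1-p) p^k for k >= 0."""
    if params.overhang_p == 0.0:
        return 0
    return int(rng.geometric(1.0 - params.overhang_p)) - 1


def orient_read(fragment: AncientFragment) -> AncientFragment:
    """Flip a minus-strand fragment into read orientation (the molecule
    as sequenced).  Plus-strand fragments are returned unchanged."""
    if fragment.strand == "+":
        return fragment
    return replace(fragment, sequence=decode(revcomp_codes(encode(fragment.sequence))))


def apply_damage(
    fragment: AncientFragment,
    params: DamageParams,
    rng: np.random.Generator,
) -> AncientFragment:
    """Step 4: terminal deamination damage.

    Expects the fragment in read orientation (see :func:`orient_read`);
    damage positions are recorded in final read coordinates.  Only C->T
    (and, on the nicked 3' end, G->A) changes are introduced, so the
    transversion content of the read is untouched.
    """
    rng = as_rng(rng)
    codes = encode(fragment.sequence)
    n = codes.size
    l5 = min(_sample_overhang(params, rng), n)
    l3 = min(_sample_overhang(params, rng), n)
    if l5 + l3 > n:  # truncate the longer draw
        if l5 >= l3:
            l5 = n - l3
        else:
            l3 = n - l5
    nick_complement = bool(rng.random() < params.nick_prob)
    damage: list[tuple[int, int, int]] = []
    C, G, T, A = 1, 2, 3, 0
    for i in range(l5):  # 5' single-stranded overhang: C->T
        if codes[i] == C and rng.random() < params.delta_ss:
            codes[i] = T
            damage.append((i, C, T))
    for i in range(n - l3, n):  # 3' overhang
        if nick_complement:
            # read as the complementary strand's filled-in copy: G->A
            if codes[i] == G and rng.random() < params.delta_ss:
                codes[i] = A
                damage.append((i, G, A))
        else:
            if codes[i] == C and rng.random() < params.delta_ss:
                codes[i] = T
                damage.append((i, C, T))
    for i in range(l5, n - l3):  # double-stranded interior, both strands
        if codes[i] == C and rng.random() < params.delta_ds:
            codes[i] = T
            damage.append((i, C, T))
        elif codes[i] == G and rng.random() < params.delta_ds:
            codes[i] = A
            damage.append((i, G, A))
    truth = replace(
        fragment.truth,
        damage=damage,
        overhang_5=l5,
        overhang_3=l3,
        nick_complement=nick_complement,
    )
    return replace(fragment, sequence=decode(codes), truth=truth)


def replay_truth(fragment: AncientFragment, genome_a: SyntheticGenome) -> str:
    """Rebuild the read from the genome and the truth record.

    Independent of the simulator's own bookkeeping: applies the logged
    substitutions, indels, strand flip and damage in order.
    """
    codes = genome_a.codes[fragment.start : fragment.end].copy()
    for off, _old, new in fragment.truth.lineage_subs:
        codes[off] = new
    for off, _old, new in fragment.truth.random_subs:
        codes[off] = new
    seq = decode(codes)
    seq = _apply_indel_list(seq, fragment.truth.indels)
    codes = encode(seq)
    if fragment.strand == "-":
        codes = revcomp_codes(codes)
    for pos, _old, new in fragment.truth.damage:
        codes[pos] = new
    return decode(codes)


def simulate_dataset(
    config: SimulationConfig,
    genome_a: SyntheticGenome,
    alignment: GenomePairAlignment,
    stats: GenomePairStats,
    damage: DamageParams | None = None,
    lengths: LengthDistribution | None = None,
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> list[AncientFragment]:
    """Run steps 0-4 and optionally write the reads FASTA and truth TSV.

    With a fixed seed the outputs are byte-identical across runs.
    """
    if lengths is None:
        lengths = LengthDistribution.lognormal()
    rng = np.random.default_rng(config.seed)
    frag_seed = int(rng.integers(0, 2**31 - 1))
    fragments = sample_fragments(
        genome_a, alignment, lengths, config.n_fragments, seed=frag_seed
    )
    out: list[AncientFragment] = []
    for frag in fragments:
        frag = apply_lineage_divergence(
            frag, alignment, config.x_myr, rng, config.d_total_myr
        )
        frag = apply_random_substitutions(
            frag, config.x_myr, stats, rng, config.d_total_myr
        )
        frag = apply_indels(frag, alignment, config.x_myr, rng, config.d_total_myr)
        if len(frag.sequence) == 0:
            continue
        frag = orient_read(frag)
        if damage is not None:
            frag = apply_damage(frag, damage, rng)
        out.append(frag)
    if fasta_path is not None:
        write_fasta([(f.fragment_id, f.sequence) for f in out], fasta_path)
    if truth_path is not None:
        write_truth_table(out, truth_path)
    return out


def write_truth_table(fragments: Sequence[AncientFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tsource\tstart\tend\tstrand\tlength\t"
            "n_lineage_subs\tn_random_subs\tn_indels\tn_damage\tdamage_positions\n"
        )
        for f in fragments:
            dmg = ",".join(str(p) for p, _o, _n in f.truth.damage)
            fh.write(
                f"{f.fragment_id}\t{f.source_name}\t{f.start}\t{f.end}\t{f.strand}\t"
                f"{len(f.sequence)}\t{len(f.truth.lineage_subs)}\t"
                f"{len(f.truth.random_subs)}\t{len(f.truth.indels)}\t"
                f"{len(f.truth.damage)}\t{dmg}\n"
            )
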