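"""Pairwise difference statistics, lineage assignment and divergence
triangulation.

In a three-way alignment of an ancient read (N) with two reference
genomes (H, closer; C, farther) the ancient sequence acts like an
outgroup: a column where H differs while N = C is a human-lineage
change (Hs), a column where C differs while N = H is a chimpanzee-
lineage change (Cs), and a column where only N differs (Ns) is ignored
-- this is what makes the estimator robust to ancient-DNA
misincorporations, which land almost exclusively on the N lineage.
Assuming a molecular clock, the divergence of the ancient lineage from
H is ``Hs / (Hs + Cs) * D`` with D the total H-to-C path length in Myr
(13 for the human/chimpanzee calibration: 2 x 6.5).

Deamination damage is transitional (C->T / G->A), so restricting the
tallies to transversions removes its influence entirely.  No multiple-
hit correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aligners import SemiGlobalAlignment, ThreeWayAlignment
from .errors import ParameterError, UndefinedEstimateError
from .seq import GAP_CODE, encode

D_TOTAL_MYR = 13.0


@dataclass
class PairwiseDiffStats:
    """Differences per site over a set of pairwise alignments."""

    sites: int
    differences: int
    transversions: int
    flavor: str = "semiglobal"  # local | semiglobal | semiglobal+positive

    def __post_init__(self) -> None:
        if not 0 <= self.transversions <= self.differences <= max(self.sites, 0):
            raise ParameterError("invalid difference counts")

    @property
    def diff_rate(self) -> float:
        return self.differences / self.sites if self.sites else 0.0

    @property
    def transversion_rate(self) -> float:
        return self.transversions / self.sites if self.sites else 0.0


@dataclass
class LineageCounts:
    """Lineage-specific change tallies from three-way alignments."""

    hs: int = 0  # H differs, N = C
    cs: int = 0  # C differs, N = H
    ns: int = 0  # N differs, H = C (ignored by the estimator)
    hs_tv: int = 0
    cs_tv: int = 0
    ns_tv: int = 0
    sites: int = 0  # gap-free columns examined

    def __post_init__(self) -> None:
        if min(self.hs, self.cs, self.ns, self.hs_tv, self.cs_tv, self.ns_tv) < 0:
            raise ParameterError("counts must be >= 0")

    def __add__(self, other: "LineageCounts") -> "LineageCounts":
        return LineageCounts(
            self.hs + other.hs,
            self.cs + other.cs,
            self.ns + other.ns,
            self.hs_tv + other.hs_tv,
            self.cs_tv + other.cs_tv,
            self.ns_tv + other.ns_tv,
            self.sites + other.sites,
        )


@dataclass(frozen=True)
class TriangulationConfig:
    d_total_myr: float = D_TOTAL_MYR
    transversions_only: bool = False

    def __post_init__(self) -> None:
        if self.d_total_myr <= 0:
            raise ParameterError("calibration D must be positive")


@dataclass
class DivergenceEstimate:
    point_myr: float
    ci_low_myr: float | None = None
    ci_high_myr: float | None = None
    n_informative: int = 0
    n_sites: int = 0
    transversions_only: bool = False
    filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ci_low_myr is not None and self.ci_high_myr is not None:
            if not self.ci_low_myr <= self.point_myr <= self.ci_high_myr:
                raise ParameterError("CI must bracket the point estimate")


def pairwise_differences(
    alignments: Iterable[SemiGlobalAlignment | tuple[str, str]],
    flavor: str = "semiglobal",
) -> PairwiseDiffStats:
    """Count differences per ungapped column over pairwise alignments.

    Transitions are A<->G and C<->T; no multiple-hit correction is
    applied.  Accepts alignment objects or raw (row_a, row_b) tuples.
    """
    sites = diffs = tvs = 0
    n_alignments = 0
    for aln in alignments:
        n_alignments += 1
        if isinstance(aln, SemiGlobalAlignment):
            row_a, row_b = aln.query_row, aln.target_row
        else:
            row_a, row_b = aln
        a = encode(row_a)
        b = encode(row_b)
        mask = (a != GAP_CODE) & (b != GAP_CODE)
        sites += int(mask.sum())
        diff_mask = mask & (a != b)
        diffs += int(diff_mask.sum())
        # transversions: complementary pairs have opposite parity
        tvs += int((diff_mask & ((a & 1) != (b & 1))).sum())
    if n_alignments == 0:
        raise ParameterError("at least one alignment is required")
    return PairwiseDiffStats(sites, diffs, tvs, flavor)


def assign_lineage_changes(threeway: ThreeWayAlignment) -> LineageCounts:
    """Tally lineage-specific changes per ungapped three-way column.

    Columns containing any gap and columns where all three bases differ
    are ignored (the latter cannot be assigned with a single change).

    The transversion tallies are computed transition-blind: bases are
    collapsed to their purine/pyrimidine class, so only transversion
    differences are visible and a column counts as Hs when H's class
    differs while N and C share a class (equivalently, for a plain Hs
    column, when the H-vs-(N,C) pair is a transversion).  Because C->T
    and G->A damage never changes a base's class, step-4 damage leaves
    the transversion tallies exactly unchanged given the same rows.
    """
    n, h, c = (encode(r) for r in threeway.rows)
    ungapped = (n != GAP_CODE) & (h != GAP_CODE) & (c != GAP_CODE)
    hs_mask = ungapped & (h != n) & (n == c)
    cs_mask = ungapped & (c != n) & (n == h)
    ns_mask = ungapped & (n != h) & (h == c)
    # all-different columns satisfy none of the three masks
    kn, kh, kc = n & 1, h & 1, c & 1  # purine/pyrimidine class
    return LineageCounts(
        hs=int(hs_mask.sum()),
        cs=int(cs_mask.sum()),
        ns=int(ns_mask.sum()),
        hs_tv=int((ungapped & (kh != kn) & (kn == kc)).sum()),
        cs_tv=int((ungapped & (kc != kn) & (kn == kh)).sum()),
        ns_tv=int((ungapped & (kn != kh) & (kh == kc)).sum()),
        sites=int(ungapped.sum()),
    )


def triangulate(
    counts: LineageCounts,
    config: TriangulationConfig = TriangulationConfig(),
    filters: tuple[str, ...] = (),
) -> DivergenceEstimate:
    """Point estimate ``Hs / (Hs + Cs) * D`` (transversion tallies when
    configured)."""
    hs = counts.hs_tv if config.transversions_only else counts.hs
    cs = counts.cs_tv if config.transversions_only else counts.cs
    if hs + cs == 0:
        raise UndefinedEstimateError("no informative lineage-specific changes")
    point = hs / (hs + cs) * config.d_total_myr
    return DivergenceEstimate(
        point_myr=point,
        n_informative=hs + cs,
        n_sites=counts.sites,
        transversions_only=config.transversions_only,
        filters=filters,
    )


def bootstrap_ci(
    per_fragment_counts: Sequence[LineageCounts],
    config: TriangulationConfig = TriangulationConfig(),
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Percentile bootstrap over fragments.

    Fragments are resampled with replacement ``n_replicates`` times;
    replicates whose resampled denominator is zero are skipped and
    counted.  Returns (ci_low, ci_high, n_skipped) in Myr.
    """
    if len(per_fragment_counts) < 2:
        raise ParameterError("need >= 2 fragments to bootstrap")
    if n_replicates < 100:
        raise ParameterError("need >= 100 bootstrap replicates")
    if config.transversions_only:
        hs = np.array([c.hs_tv for c in per_fragment_counts], dtype=np.int64)
        cs = np.array([c.cs_tv for c in per_fragment_counts], dtype=np.int64)
    else:
        hs = np.array([c.hs for c in per_fragment_counts], dtype=np.int64)
        cs = np.array([c.cs for c in per_fragment_counts], dtype=np.int64)
    n = hs.size
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_replicates)
    skipped = 0
    chunk = max(1, min(n_replicates, 1 << 22 // max(n, 1)))
    filled = 0
    while filled < n_replicates:
        b = min(chunk, n_replicates - filled)
        idx = rng.integers(0, n, size=(b, n))
        hs_sum = hs[idx].sum(axis=1)
        cs_sum = cs[idx].sum(axis=1)
        denom = hs_sum + cs_sum
        for r in range(b):
            if denom[r] == 0:
                skipped += 1
                estimates[filled] = np.nan
            else:
                estimates[filled] = hs_sum[r] / denom[r] * config.d_total_myr
            filled += 1
    valid = estimates[~np.isnan(estimates)]
    if valid.size == 0:
        raise UndefinedEstimateError("every bootstrap replicate was degenerate")
    lo = float(np.percentile(valid, 100 * alpha / 2))
    hi = float(np.percentile(valid, 100 * (1 - alpha / 2)))
    return lo, hi, skipped


def bias_experiment(
    x_values: Sequence[float] = (1, 2, 3, 4, 5, 6),
    n_fragments: int = 10_000,
    seed: int = 0,
    filter_sets: dict[str, tuple[str, ...]] | None = None,
    transversion_modes: Sequence[bool] = (False, True),
    with_ci: bool = False,
    **study_kwargs,
):
    """Measure the deviation of triangulated estimates from the
    simulated divergence over a grid of filter sets and modes.

    Thin front end over the full simulation/analysis chain; returns a
    table with one row per (X, filter set, transversion mode) holding
    the estimate, the deviation from X and surviving-read counts.
    """
    from .pipeline import run_divergence_study  # deferred: avoids an import cycle

    return run_divergence_study(
        x_values=x_values,
        n_fragments=n_fragments,
        seed=seed,
        filter_sets=filter_sets,
        transversion_modes=transversion_modes,
        with_ci=with_ci,
        **study_kwargs,
    )


def estimate_with_ci(
    per_fragment_counts: Sequence[LineageCounts],
    config: TriangulationConfig = TriangulationConfig(),
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    filters: tuple[str, ...] = (),
) -> DivergenceEstimate:
    """Triangulate pooled counts and attach a bootstrap CI."""
    total = LineageCounts()
    for c in per_fragment_counts:
        total = total + c
    est = triangulate(total, config, filters)
    lo, hi, _skipped = bootstrap_ci(
        per_fragment_counts, config, n_replicates, alpha, seed
    )
    est.ci_low_myr = min(lo, est.point_myr)
    est.ci_high_myr = max(hi, est.point_myr)
    return est
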