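"""End-to-end orchestration of the ancient-DNA analysis chain.

Two headline workflows:

* :func:`run_classification` -- search reads against target genome(s)
  and decoy databases, label them endogenous/contaminant/unclassified,
  re-align endogenous reads semi-globally and report the three headline
  counts (best-hit / unique-best / positive-semi-global) together with
  the corresponding average lengths.
* :func:`run_divergence_study` -- the full simulate -> search ->
  classify -> semi-global -> three-way -> filter -> triangulate chain,
  evaluated over a grid of simulated divergences, filter combinations
  and transversion modes.  Deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import adna_sim, divergence as div
from .aligners import semiglobal_align, threeway_align_dijkstra
from .errors import ConfigError
from .hit_filters import FILTER_ORDER, FilterConfig, FilterReport, ReadContext, apply_filters
from .local_search import (
    ClassificationRecord,
    LocalHit,
    SearchDatabase,
    classify_read,
    search,
)
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .seq import revcomp
from .synth_genomes import (
    GenomePairAlignment,
    SyntheticGenome,
    estimate_substitution_stats,
    simulate_genome_pair,
)

# Figure-4-style filter combinations: name -> filters enabled in the
# survival conjunction ("raw" keeps every read with a usable three-way
# alignment)
FILTER_SETS: dict[str, tuple[str, ...]] = {
    "raw": (),
    "verified": ("unique", "orthology", "bitscore_gap"),
    "length": ("length",),
    "all": FILTER_ORDER,
}


@dataclass
class PipelineConfig:
    """Run configuration loaded from a JSON/YAML file.

    ``paths`` may reference input files (genomes, reads, length
    histograms); every referenced file must exist.  ``params`` holds
    per-module parameter blocks passed through to the workflows; a seed
    is mandatory whenever a simulation stage is enabled.
    """

    seed: int | None = None
    stages: tuple[str, ...] = ()
    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    _SIMULATION_STAGES = {"simulate-genomes", "simulate-reads", "divergence-study"}

    def __post_init__(self) -> None:
        for key, value in self.paths.items():
            if not Path(value).exists():
                raise ConfigError(f"configured path {key!r} does not exist: {value}")
        if self.seed is None and set(self.stages) & self._SIMULATION_STAGES:
            raise ConfigError("a seed is mandatory for simulation stages")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        return cls(
            seed=data.get("seed"),
            stages=tuple(data.get("stages", ())),
            paths=dict(data.get("paths", {})),
            params={k: dict(v) for k, v in data.get("params", {}).items()},
        )

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "stages": list(self.stages),
                "paths": self.paths,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of a pipeline run: tool version, configuration
    hash, per-stage input/output counts and timestamps.  Counts are
    conserved per stage (reads in = reads out across categories)."""

    tool_version: str
    config_hash: str
    started: float = field(default_factory=time.time)
    finished: float | None = None
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = dict(counts)

    def close(self) -> None:
        self.finished = time.time()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "config_hash": self.config_hash,
                    "started": self.started,
                    "finished": self.finished,
                    "stage_counts": self.stage_counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


@dataclass
class ReadAnalysis:
    """Everything computed for one read along the divergence chain."""

    read_id: str
    length: int
    hits_a: list[LocalHit] = field(default_factory=list)
    hits_b: list[LocalHit] = field(default_factory=list)
    unique_a: bool = False
    unique_b: bool = False
    semiglobal_score: int | None = None
    semiglobal_span: tuple[int, int] | None = None
    counts: div.LineageCounts | None = None
    flags: dict[str, bool] = field(default_factory=dict)


def _unique_best(hits: list[LocalHit]) -> bool:
    if not hits:
        return False
    return len(hits) == 1 or hits[0].bitscore > hits[1].bitscore


def analyze_reads(
    reads: Sequence[tuple[str, str]],
    genome_a: SyntheticGenome,
    genome_b: SyntheticGenome,
    alignment: GenomePairAlignment,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    filter_config: FilterConfig = FilterConfig(),
    extra_databases: Sequence[SearchDatabase] = (),
    databases: tuple[SearchDatabase, SearchDatabase] | None = None,
) -> tuple[list[ReadAnalysis], FilterReport]:
    """Run search, semi-global re-alignment and three-way lineage
    assignment for every read; attach filter outcomes.

    The three-way alignment uses the read in the orientation of its best
    genome-A hit, the semi-globally aligned genome-A segment, and the
    genome-B segment obtained by lifting that segment's coordinates.
    """
    if databases is None:
        db_a = SearchDatabase.build(genome_a.name, [(genome_a.name, genome_a.sequence)])
        db_b = SearchDatabase.build(genome_b.name, [(genome_b.name, genome_b.sequence)])
    else:
        db_a, db_b = databases
    all_dbs = [db_a, db_b, *extra_databases]
    analyses: list[ReadAnalysis] = []
    contexts: list[ReadContext] = []
    for read_id, seq in reads:
        hits = search(read_id, seq, all_dbs, scheme)
        ra = ReadAnalysis(read_id=read_id, length=len(seq))
        ra.hits_a = hits.get(db_a.name, [])
        ra.hits_b = hits.get(db_b.name, [])
        ra.unique_a = _unique_best(ra.hits_a)
        ra.unique_b = _unique_best(ra.hits_b)
        if ra.hits_a:
            best = ra.hits_a[0]
            oriented = seq if best.strand == "+" else revcomp(seq)
            pad = len(seq)
            ws = max(0, best.target_start - pad)
            we = min(len(genome_a), best.target_end + pad)
            sg = semiglobal_align(
                oriented,
                genome_a.sequence[ws:we],
                scheme,
                query_id=read_id,
                target_name=genome_a.name,
                window_offset=ws,
                strand=best.strand,
            )
            ra.semiglobal_score = sg.score
            ra.semiglobal_span = (sg.target_start, sg.target_end)
            lifted = (
                alignment.liftover(sg.target_start, sg.target_end, "A->B")
                if sg.target_end > sg.target_start
                else None
            )
            if lifted is not None and lifted[1] > lifted[0]:
                h_seg = genome_a.sequence[sg.target_start : sg.target_end]
                c_seg = genome_b.sequence[lifted[0] : lifted[1]]
                if h_seg and c_seg:
                    three = threeway_align_dijkstra(oriented, h_seg, c_seg, scheme)
                    ra.counts = div.assign_lineage_changes(three)
        analyses.append(ra)
        contexts.append(
            ReadContext(
                read_id=read_id,
                length=len(seq),
                hits_a=ra.hits_a,
                hits_b=ra.hits_b,
                unique_a=ra.unique_a,
                unique_b=ra.unique_b,
                semiglobal_score=ra.semiglobal_score,
            )
        )
    report = apply_filters(contexts, alignment, filter_config)
    for ra in analyses:
        ra.flags = report.per_read[ra.read_id]
    return analyses, report


def estimate_divergence(
    analyses: Sequence[ReadAnalysis],
    filter_set: tuple[str, ...] = (),
    transversions_only: bool = False,
    d_total_myr: float = div.D_TOTAL_MYR,
    with_ci: bool = False,
    n_replicates: int = 2000,
    seed: int = 0,
) -> div.DivergenceEstimate:
    """Triangulate over all reads with a three-way alignment that pass
    the given filter subset."""
    per_read = [
        ra.counts
        for ra in analyses
        if ra.counts is not None and all(ra.flags.get(f, False) for f in filter_set)
    ]
    config = div.TriangulationConfig(d_total_myr, transversions_only)
    if with_ci and len(per_read) >= 2:
        return div.estimate_with_ci(
            per_read, config, n_replicates=n_replicates, seed=seed, filters=filter_set
        )
    total = div.LineageCounts()
    for c in per_read:
        total = total + c
    return div.triangulate(total, config, filters=filter_set)


def run_classification(
    reads: Sequence[tuple[str, str]],
    target_databases: Sequence[SearchDatabase],
    contaminant_databases: Sequence[SearchDatabase] = (),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, dict]:
    """Classify reads by best local hit and semi-globally re-align.

    The summary reports, for each target genome database, the headline
    counts (reads with a best hit to the genome, the unique-best subset
    and the positive-semi-global subset) and the three average lengths
    (best local alignment length, fragment length of unique-best reads,
    fragment length of positive-score reads).
    """
    if not reads:
        raise ConfigError("no reads supplied")
    if not target_databases:
        raise ConfigError("at least one target genome database is required")
    target_names = {db.name for db in target_databases}
    target_seqs = {
        db.name: dict(zip(db.index.seq_names, db.index.seq_codes))
        for db in target_databases
    }
    all_dbs = [*target_databases, *contaminant_databases]
    rows = []
    for read_id, seq in reads:
        hits = search(read_id, seq, all_dbs, scheme)
        record: ClassificationRecord = classify_read(read_id, hits, target_names)
        row = {
            "read_id": read_id,
            "length": len(seq),
            "label": record.label,
            "unique_best": record.unique_best,
            "local_len": np.nan,
            "semiglobal_score": np.nan,
            "semiglobal_len": np.nan,
            "positive": False,
            "best_db": "",
        }
        if record.label == "endogenous":
            best_db = max(
                (n for n in record.best_hits if n in target_names),
                key=lambda n: record.best_hits[n].bitscore,
            )
            best = record.best_hits[best_db]
            row["best_db"] = best_db
            row["local_len"] = best.alignment_length
            if record.unique_best:
                from .seq import decode  # local import to avoid cycle noise

                oriented = seq if best.strand == "+" else revcomp(seq)
                tcodes = target_seqs[best_db][best.target_name]
                pad = len(seq)
                ws = max(0, best.target_start - pad)
                we = min(tcodes.size, best.target_end + pad)
                sg = semiglobal_align(
                    oriented,
                    decode(tcodes[ws:we]),
                    scheme,
                    query_id=read_id,
                    target_name=best.target_name,
                    window_offset=ws,
                    strand=best.strand,
                )
                row["semiglobal_score"] = sg.score
                row["semiglobal_len"] = len(seq)
                row["positive"] = sg.score > 0
        rows.append(row)
    table = pd.DataFrame(rows)
    endo = table[table.label == "endogenous"]
    uniq = endo[endo.unique_best]
    pos = uniq[uniq.positive]
    summary = {
        "n_reads": len(table),
        "n_best_hit": int(len(endo)),
        "n_unique_best": int(len(uniq)),
        "n_positive_semiglobal": int(len(pos)),
        "avg_local_alignment_length": float(endo.local_len.mean()) if len(endo) else 0.0,
        "avg_unique_fragment_length": float(uniq.length.mean()) if len(uniq) else 0.0,
        "avg_positive_fragment_length": float(pos.length.mean()) if len(pos) else 0.0,
    }
    return table, summary


def run_divergence_study(
    x_values: Sequence[float],
    n_fragments: int,
    seed: int = 0,
    genome_length: int = 1_000_000,
    pair_divergence: float = 0.012,
    indel_rate: float = 5e-4,
    damage: adna_sim.DamageParams | None = adna_sim.DamageParams(),
    filter_sets: dict[str, tuple[str, ...]] | None = None,
    transversion_modes: Sequence[bool] = (False, True),
    d_total_myr: float = div.D_TOTAL_MYR,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    filter_config: FilterConfig = FilterConfig(),
    with_ci: bool = False,
) -> pd.DataFrame:
    """Simulate and analyze one dataset per divergence value.

    Returns one row per (X, filter set, transversion mode) with the
    triangulated estimate, its deviation from X and surviving-read
    counts.  Every random draw derives from ``seed``, so rerunning with
    the same arguments reproduces the table byte for byte.
    """
    if filter_sets is None:
        filter_sets = FILTER_SETS
    rng = np.random.default_rng(seed)
    genome_seed = int(rng.integers(0, 2**31 - 1))
    genome_a, genome_b, alignment = simulate_genome_pair(
        genome_length, pair_divergence, indel_rate, seed=genome_seed
    )
    stats = estimate_substitution_stats(alignment)
    rows = []
    for x in x_values:
        sim_seed = int(rng.integers(0, 2**31 - 1))
        config = adna_sim.SimulationConfig(
            x_myr=x, n_fragments=n_fragments, d_total_myr=d_total_myr, seed=sim_seed
        )
        fragments = adna_sim.simulate_dataset(config, genome_a, alignment, stats, damage)
        reads = [(f.fragment_id, f.sequence) for f in fragments]
        analyses, _report = analyze_reads(
            reads, genome_a, genome_b, alignment, scheme, filter_config
        )
        for fname, fset in filter_sets.items():
            for tv in transversion_modes:
                try:
                    est = estimate_divergence(
                        analyses,
                        fset,
                        transversions_only=tv,
                        d_total_myr=d_total_myr,
                        with_ci=with_ci,
                        seed=sim_seed,
                    )
                    point = est.point_myr
                    n_info = est.n_informative
                    ci_low, ci_high = est.ci_low_myr, est.ci_high_myr
                except div.UndefinedEstimateError:
                    point, n_info, ci_low, ci_high = np.nan, 0, None, None
                n_surv = sum(
                    1
                    for ra in analyses
                    if ra.counts is not None
                    and all(ra.flags.get(f, False) for f in fset)
                )
                rows.append(
                    {
                        "x_myr": x,
                        "filter_set": fname,
                        "transversions_only": tv,
                        "estimate_myr": point,
                        "deviation_myr": point - x,
                        "relative_deviation": (point - x) / x if x else np.nan,
                        "n_reads": len(reads),
                        "n_used": n_surv,
                        "n_informative": n_info,
                        "ci_low_myr": ci_low,
                        "ci_high_myr": ci_high,
                    }
                )
    return pd.DataFrame(rows)
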