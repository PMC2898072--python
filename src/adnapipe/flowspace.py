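"""454-style preprocessing: key filter, flow-space adapter trimming and
emulsion-PCR duplicate clustering.

A flowgram holds one signal value per nucleotide flow (repeating TACG
cycle by default), proportional to homopolymer length.  Since binary SFF
parsing is out of scope, flowgrams are synthesized from sequences (with
optional bounded noise) or read from TSV.

A flow value is considered *positive* when it calls at least one base,
i.e. value >= 0.5; two flows agree when their difference stays within
tau = 0.49 (the same homopolymer call).  Both constants are decided
conventions, documented here and used consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aligners import semiglobal_align
from .errors import ParameterError
from .scoring import DEFAULT_SCHEME, ScoringScheme

DEFAULT_FLOW_ORDER = "TACG"
POSITIVE_FLOW_THRESHOLD = 0.5
FLOW_AGREEMENT_TAU = 0.49
DUPLICATE_IDENTITY_THRESHOLD = 0.89


@dataclass
class Flowgram:
    """Per-flow signal values for one read."""

    read_id: str
    flow_order: str
    values: np.ndarray
    called_sequence: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ParameterError("flow values must be >= 0")

    def call(self) -> str:
        """Round values and expand along the flow order."""
        out = []
        for i, v in enumerate(self.values):
            out.append(self.flow_order[i % len(self.flow_order)] * int(round(v)))
        return "".join(out)

    def positive_flows(self) -> list[tuple[int, int]]:
        """(flow index, rounded value) of flows calling >= 1 base."""
        return [
            (i, int(round(v)))
            for i, v in enumerate(self.values)
            if v >= POSITIVE_FLOW_THRESHOLD
        ]


@dataclass
class DuplicateCluster:
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ParameterError("representative must be a cluster member")


def filter_by_key(
    reads: list[tuple[str, str]], key: str
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Retain reads whose first four bases equal the library key.

    Reads shorter than the key are removed and tallied separately.
    Returns (retained, {"key_mismatch": ..., "too_short": ...}).
    """
    if len(key) != 4:
        raise ParameterError("key must be 4 bases")
    key = key.upper()
    kept: list[tuple[str, str]] = []
    counts = {"key_mismatch": 0, "too_short": 0}
    for rid, seq in reads:
        if len(seq) < 4:
            counts["too_short"] += 1
        elif seq[:4].upper() == key:
            kept.append((rid, seq))
        else:
            counts["key_mismatch"] += 1
    return kept, counts


def ideal_flows(sequence: str, flow_order: str = DEFAULT_FLOW_ORDER, phase: int = 0) -> np.ndarray:
    """Noise-free flow values of a sequence starting at a cycle phase."""
    seq = sequence.upper()
    values: list[int] = []
    i = 0
    f = phase
    while i < len(seq):
        base = flow_order[f % len(flow_order)]
        run = 0
        while i < len(seq) and seq[i] == base:
            run += 1
            i += 1
        values.append(run)
        f += 1
    return np.asarray(values, dtype=float)


def synthesize_flowgram(
    read_id: str,
    sequence: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    flow_order: str = DEFAULT_FLOW_ORDER,
) -> Flowgram:
    """Exact homopolymer flows plus truncated-Gaussian noise.

    Noise is truncated to +/-0.49 so rounding always recovers the called
    sequence (the invariant the clustering bucketing relies on);
    ``noise_sd=0`` gives integer flows.
    """
    values = ideal_flows(sequence, flow_order)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = np.clip(rng.normal(0.0, noise_sd, values.size), -0.49, 0.49)
        values = np.maximum(values + eps, 0.0)
    return Flowgram(read_id, flow_order, values, sequence.upper())


def trim_adapter(
    flowgram: Flowgram,
    adapter: str,
    tau: float = FLOW_AGREEMENT_TAU,
    min_overlap: int = 4,
) -> int | None:
    """Locate the adapter in flow space; return the trim point (flow index).

    Every candidate trim point is scored by comparing read flow values
    against the adapter's ideal flows at the matching cycle phase:
    agreeing flows (|difference| <= tau) score +1, disagreements are
    penalized by their magnitude; the total is normalized by the overlap
    length.  The 5'-most positively scoring trim point is returned, or
    None when no candidate scores positive.
    """
    if not adapter:
        raise ParameterError("adapter must be non-empty")
    order = flowgram.flow_order
    nflows = flowgram.values.size
    # the adapter's signal starts at its first base's flow, so only flow
    # indices whose cycle position matches that base are candidates
    first_phase = order.index(adapter[0].upper())
    ideal = ideal_flows(adapter, order, first_phase)
    for t in range(first_phase, nflows - min_overlap + 1, len(order)):
        ov = min(nflows - t, ideal.size)
        if ov < min_overlap:
            continue
        window = flowgram.values[t : t + ov]
        diff = np.abs(window - ideal[:ov])
        score = float(np.where(diff <= tau, 1.0, -diff).sum()) / ov
        if score > 0:
            return t
    return None


def flow_trim_to_base(flowgram: Flowgram, trim_flow: int) -> int:
    """Number of called bases before a flow-space trim point."""
    return int(np.round(flowgram.values[:trim_flow]).sum())


def sequence_identity(
    seq_a: str, seq_b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Global identity over the full length of the shorter read.

    The shorter read is aligned globally against the longer one with
    free end gaps on the longer (affine costs); identity is the number
    of matching columns divided by the shorter read's length.
    """
    if not seq_a or not seq_b:
        return 0.0
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    aln = semiglobal_align(short, long_, scheme)
    matches = sum(
        1 for a, b in zip(aln.query_row, aln.target_row) if a == b and a != "-"
    )
    return matches / len(short)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_duplicates(
    flowgrams: list[Flowgram],
    identity_threshold: float = DUPLICATE_IDENTITY_THRESHOLD,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[DuplicateCluster]:
    """Single-linkage duplicate clustering in flow space.

    Reads are bucketed by the indices and rounded values of their first
    six positive flows (emulsion-PCR duplicates share their start, so
    true duplicates land in the same bucket even with signal noise);
    within a bucket two reads are linked when their global identity over
    the shorter read's full length reaches the threshold.  Clusters are
    the connected components of the link graph, so the result does not
    depend on input order.
    """
    if not flowgrams:
        raise ParameterError("at least one read is required")
    ids = [fg.read_id for fg in flowgrams]
    if len(set(ids)) != len(ids):
        raise ParameterError("read ids must be unique")
    uf = _UnionFind(ids)
    buckets: dict[tuple, list[Flowgram]] = {}
    for fg in flowgrams:
        buckets.setdefault(tuple(fg.positive_flows()[:6]), []).append(fg)
    for members in buckets.values():
        members = sorted(members, key=lambda f: f.read_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = sequence_identity(
                    members[i].called_sequence, members[j].called_sequence, scheme
                )
                if ident >= identity_threshold:
                    uf.union(members[i].read_id, members[j].read_id)
    groups: dict[str, set[str]] = {}
    for rid in ids:
        groups.setdefault(uf.find(rid), set()).add(rid)
    return [
        DuplicateCluster(member_ids=frozenset(g), representative_id=min(g))
        for _root, g in sorted(groups.items())
    ]


def select_cluster_representative(
    cluster: DuplicateCluster, best_bitscores: dict[str, float]
) -> str | None:
    """Member with the best hit bitscore (ties: lexicographically
    smallest id); None when no member has any hit (cluster dropped)."""
    if not cluster.member_ids:
        raise ParameterError("cluster must be non-empty")
    scored = [rid for rid in cluster.member_ids if rid in best_bitscores]
    if not scored:
        return None
    return min(scored, key=lambda rid: (-best_bitscores[rid], rid))


def write_flowgrams_tsv(flowgrams: list[Flowgram], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tflow_order\tvalues\n")
        for fg in flowgrams:
            vals = ",".join(f"{v:.3f}" for v in fg.values)
            fh.write(f"{fg.read_id}\t{fg.flow_order}\t{vals}\n")


def read_flowgrams_tsv(path: str | Path) -> list[Flowgram]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ParameterError("not a flowgram TSV")
        for line in fh:
            rid, order, vals = line.rstrip("\n").split("\t")
            values = np.array([float(v) for v in vals.split(",")])
            fg = Flowgram(rid, order, values, "")
            fg.called_sequence = fg.call()
            out.append(fg)
    return out


def write_clusters_tsv(clusters: list[DuplicateCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmembers\n")
        for i, cl in enumerate(sorted(clusters, key=lambda c: c.representative_id)):
            fh.write(
                f"c{i:06d}\t{cl.representative_id}\t{','.join(sorted(cl.member_ids))}\n"
            )
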