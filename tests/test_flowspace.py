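"""454 preprocessing: key filter, flowgrams, adapter trim, clustering."""

import numpy as np
import pytest

from adnapipe import flowspace
from adnapipe.errors import ParameterError
from adnapipe.flowspace import (
    cluster_duplicates,
    filter_by_key,
    flow_trim_to_base,
    select_cluster_representative,
    synthesize_flowgram,
    trim_adapter,
)

from .conftest import random_seq


class TestKeyFilter:
    def test_matching_key_retained_mismatch_removed(self):
        reads = [("a", "TCAGAAAA"), ("b", "TCGGAAAA"), ("c", "GCAGAAAA")]
        kept, counts = filter_by_key(reads, "TCAG")
        assert [r[0] for r in kept] == ["a"]
        assert counts == {"key_mismatch": 2, "too_short": 0}

    def test_short_read_counted_separately(self):
        kept, counts = filter_by_key([("a", "TCA")], "TCAG")
        assert kept == [] and counts["too_short"] == 1

    def test_idempotent(self):
        reads = [("a", "TCAGAAAA"), ("b", "AAAAAAAA"), ("c", "TC")]
        once, _ = filter_by_key(reads, "TCAG")
        twice, counts = filter_by_key(once, "TCAG")
        assert twice == once
        assert counts == {"key_mismatch": 0, "too_short": 0}


class TestFlowgrams:
    def test_cycle_sequence_gives_unit_flows(self):
        fg = synthesize_flowgram("r", "TACG")
        assert fg.values.tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_homopolymer_flow_value(self):
        fg = synthesize_flowgram("r", "TTACG")
        assert fg.values[0] == 2.0

    def test_noise_free_round_trip(self, rng):
        for _ in range(20):
            seq = random_seq(rng, int(rng.integers(5, 60)))
            fg = synthesize_flowgram("r", seq)
            assert fg.call() == seq

    def test_noisy_round_trip_still_calls_same_sequence(self, rng):
        for seed in range(10):
            seq = random_seq(rng, 40)
            fg = synthesize_flowgram("r", seq, noise_sd=0.2, seed=seed)
            assert fg.call() == seq


class TestAdapterTrim:
    ADAPTER = "GCCTCCCTCGCG"

    def test_exact_adapter_found_at_insert_end(self, rng):
        # A/T-only inserts cannot mimic the CG-rich adapter's flow
        # pattern, so the true junction is the unique positive point
        for _ in range(10):
            insert = "".join("AT"[i] for i in rng.integers(0, 2, int(rng.integers(20, 50))))
            fg = synthesize_flowgram("r", insert + self.ADAPTER)
            t = trim_adapter(fg, self.ADAPTER)
            assert t is not None
            assert flow_trim_to_base(fg, t) == len(insert)

    def test_trim_point_is_five_prime_most_positive(self, rng):
        # with an arbitrary insert the returned point may precede the
        # true junction, but never follow it
        for _ in range(10):
            insert = random_seq(rng, 30)
            if insert[-1] == self.ADAPTER[0]:
                insert = insert[:-1] + "A"
            fg = synthesize_flowgram("r", insert + self.ADAPTER)
            t = trim_adapter(fg, self.ADAPTER)
            assert t is not None
            assert flow_trim_to_base(fg, t) <= len(insert)

    def test_read_without_adapter_returns_none(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 60)
            fg = synthesize_flowgram("r", seq)
            # an adapter whose flow pattern cannot arise from the read
            assert trim_adapter(fg, "GGGGGGCCCCCCGGGGGG") is None

    def test_five_prime_most_occurrence_wins(self):
        insert = "TTTTAAAACCCC"
        read = insert + self.ADAPTER + "TATA" + self.ADAPTER
        fg = synthesize_flowgram("r", read)
        t = trim_adapter(fg, self.ADAPTER)
        assert flow_trim_to_base(fg, t) == len(insert)


def _noisy_copy(rng, seq, n_subs):
    """Copy with n substitutions (duplicate-like read)."""
    s = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
    return "".join(s)


class TestClustering:
    def test_identical_reads_form_one_cluster(self):
        fgs = [synthesize_flowgram(i, "TCAG" + "ACGT" * 10) for i in ("a", "b")]
        clusters = cluster_duplicates(fgs)
        assert len(clusters) == 1
        assert clusters[0].member_ids == frozenset({"a", "b"})

    def test_low_identity_reads_stay_apart(self, rng):
        seq = random_seq(rng, 100)
        other = _noisy_copy(rng, seq, 15)  # 85% identity, same start kept
        other = seq[:8] + other[8:]  # preserve the first flows (same bucket)
        fgs = [synthesize_flowgram("a", seq), synthesize_flowgram("b", other)]
        ident = flowspace.sequence_identity(seq, other)
        assert ident < 0.89
        clusters = cluster_duplicates(fgs)
        assert len(clusters) == 2

    def test_single_linkage_transitivity(self, rng):
        # a~b and b~c above threshold, a~c below: one cluster {a, b, c}
        base = random_seq(rng, 100)
        b = base
        a = base[:12] + _noisy_copy(rng, base[12:], 8)   # ~92% to b
        c = base[:12] + _noisy_copy(rng, base[12:], 8)   # ~92% to b
        ia_b = flowspace.sequence_identity(a, b)
        ib_c = flowspace.sequence_identity(b, c)
        ia_c = flowspace.sequence_identity(a, c)
        assert ia_b >= 0.89 and ib_c >= 0.89
        assert ia_c < 0.89  # the two noisy copies differ from each other
        clusters = cluster_duplicates(
            [synthesize_flowgram(i, s) for i, s in (("a", a), ("b", b), ("c", c))]
        )
        assert len(clusters) == 1
        assert clusters[0].member_ids == frozenset({"a", "b", "c"})

    def test_clustering_invariant_to_input_order(self, rng):
        seqs = {}
        for g in range(4):
            base = random_seq(rng, 80)
            seqs[f"g{g}_0"] = base
            seqs[f"g{g}_1"] = base[:10] + _noisy_copy(rng, base[10:], 3)
        fgs = [synthesize_flowgram(i, s) for i, s in seqs.items()]
        c1 = cluster_duplicates(fgs)
        c2 = cluster_duplicates(fgs[::-1])
        assert sorted(c.member_ids for c in c1) == sorted(c.member_ids for c in c2)

    def test_planted_duplicate_groups_recovered_exactly(self, rng):
        k = 6
        fgs = []
        for g in range(k):
            base = random_seq(rng, 90)
            for copy in range(g % 3 + 1):
                seq = base if copy == 0 else base[:10] + _noisy_copy(rng, base[10:], 2)
                fgs.append(synthesize_flowgram(f"g{g}_{copy}", seq, noise_sd=0.1, seed=g * 10 + copy))
        clusters = cluster_duplicates(fgs)
        assert len(clusters) == k
        for cl in clusters:
            groups = {rid.split("_")[0] for rid in cl.member_ids}
            assert len(groups) == 1


class TestRepresentative:
    def test_singleton_is_its_own_representative(self):
        cl = flowspace.DuplicateCluster(frozenset({"a"}), "a")
        assert select_cluster_representative(cl, {"a": 50.0}) == "a"

    def test_best_bitscore_wins_and_ties_break_lexicographically(self):
        cl = flowspace.DuplicateCluster(frozenset({"a", "b", "c"}), "a")
        assert select_cluster_representative(cl, {"a": 50.0, "b": 60.0}) == "b"
        assert select_cluster_representative(cl, {"b": 60.0, "c": 60.0}) == "b"

    def test_no_hits_signals_dropped_cluster(self):
        cl = flowspace.DuplicateCluster(frozenset({"a", "b"}), "a")
        assert select_cluster_representative(cl, {}) is None

    def test_representative_must_be_member(self):
        with pytest.raises(ParameterError):
            flowspace.DuplicateCluster(frozenset({"a"}), "z")
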