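"""Seeded local search: indexing, X-drop extension, hit ranking,
classification."""

import numpy as np

from adnapipe.local_search import (
    SearchDatabase,
    build_seed_index,
    classify_read,
    extend_seed,
    hits_to_blast6,
    search,
)
from adnapipe.scoring import DEFAULT_SCHEME, rescore_alignment
from adnapipe.seq import encode, revcomp

from .conftest import random_seq
from .oracles import smith_waterman_py


class TestSeedIndex:
    def test_sixteen_bp_target_has_one_key(self):
        idx = build_seed_index([("t", "ACGTACGTACGTACGT")])
        assert idx.sorted_kmers.size == 1

    def test_no_shared_kmer_gives_no_candidates(self, rng):
        target = "A" * 100
        idx = build_seed_index([("t", target)])
        query_kmers = np.array([0xFFFF], dtype=np.uint64)
        assert list(idx.lookup_many(query_kmers)) == []

    def test_planted_unique_kmer_yields_one_candidate(self, rng):
        # an A-free word cannot match anywhere inside the A-run flanks
        kmer = "".join("CGT"[i] for i in rng.integers(0, 3, 16))
        target = "A" * 50 + kmer + "A" * 50
        db = SearchDatabase.build("t", [("t", target)])
        hits = search("q", kmer, [db])["t"]
        assert len(hits) == 1
        assert hits[0].target_start == 50

    def test_short_sequence_indexes_empty(self):
        idx = build_seed_index([("t", "ACGT")])
        assert idx.sorted_kmers.size == 0


class TestExtendSeed:
    def test_identical_sequences_score_full_length(self, rng):
        q = random_seq(rng, 40)
        t = "TT" + q + "GG"
        raw, qs, qe, ts, te, _rq, _rt = extend_seed(encode(q), encode(t), 0, 2, 16)
        assert raw == 40
        assert (qs, qe, ts, te) == (0, 40, 2, 42)

    def test_single_central_mismatch_scores_39_minus_3(self, rng):
        q = list(random_seq(rng, 40))
        t = "".join(q)
        q[20] = "ACGT"[("ACGT".index(q[20]) + 1) % 4]
        q = "".join(q)
        raw, *_ = extend_seed(encode(q), encode(t), 0, 0, 16)
        assert raw == 39 * 1 - 3

    def test_matches_smith_waterman_on_indel_free_instances(self, rng):
        for _ in range(100):
            t = random_seq(rng, 120)
            start = int(rng.integers(0, 60))
            q = list(t[start : start + 50])
            for p in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
                q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
            q = "".join(q)
            # seed at an exact 16-mer match inside the planted copy
            seed_q = next(
                (i for i in range(0, 35) if q[i : i + 16] == t[start + i : start + i + 16]),
                None,
            )
            if seed_q is None:  # mutations broke every seed window
                continue
            raw, *_ = extend_seed(encode(q), encode(t), seed_q, start + seed_q, 16)
            assert raw == smith_waterman_py(q, t)

    def test_two_bp_indel_instance_matches_smith_waterman(self, rng):
        for _ in range(20):
            t = random_seq(rng, 80)
            q = t[10:70]
            cut = int(rng.integers(20, 40))
            q = q[:cut] + q[cut + 2 :]  # 2-bp deletion in the read
            raw, qs, qe, ts, te, rq, rt = extend_seed(encode(q), encode(t), 0, 10, 16)
            assert raw == smith_waterman_py(q, t)

    def test_reported_rows_reproduce_raw_score(self, rng):
        from adnapipe.seq import decode

        for _ in range(20):
            t = random_seq(rng, 100)
            q = list(t[20:70])
            for p in rng.choice(50, size=3, replace=False):
                q[p] = "ACGT"[("ACGT".index(q[p]) + 1) % 4]
            q = "".join(q)
            seed_q = next(
                (i for i in range(0, 35) if q[i : i + 16] == t[20 + i : 20 + i + 16]),
                None,
            )
            if seed_q is None:
                continue
            raw, qs, qe, ts, te, rq, rt = extend_seed(encode(q), encode(t), seed_q, 20 + seed_q, 16)
            row_q = decode(np.array(rq, dtype=np.uint8))
            row_t = decode(np.array(rt, dtype=np.uint8))
            assert rescore_alignment(row_q, row_t, DEFAULT_SCHEME) == raw


class TestSearch:
    def test_no_shared_kmer_means_no_hit(self, rng):
        db = SearchDatabase.build("t", [("t", "AC" * 200)])
        hits = search("q", "TTTGGGTTTGGGTTTGGGTTTGGG", [db])
        assert hits["t"] == []

    def test_planted_read_is_significant(self, rng):
        genome = random_seq(rng, 5000)
        db = SearchDatabase.build("t", [("t", genome)])
        read = genome[1000:1060]
        hits = search("q", read, [db])["t"]
        assert hits and hits[0].evalue < 1e-3
        assert hits[0].target_start == 1000

    def test_reverse_strand_hit_found(self, rng):
        genome = random_seq(rng, 3000)
        db = SearchDatabase.build("t", [("t", genome)])
        read = revcomp(genome[500:560])
        hits = search("q", read, [db])["t"]
        assert hits and hits[0].strand == "-"
        assert hits[0].target_start == 500

    def test_top_n_cap_with_twelve_plantings(self, rng):
        core = random_seq(rng, 60)
        spacer = lambda: random_seq(rng, 30)
        genome = "".join(spacer() + core for _ in range(12)) + spacer()
        db = SearchDatabase.build("t", [("t", genome)])
        hits = search("q", core, [db], top_n=10)["t"]
        assert len(hits) == 10

    def test_blast6_table_shape(self, rng):
        genome = random_seq(rng, 2000)
        db = SearchDatabase.build("t", [("t", genome)])
        hits = search("q", genome[100:160], [db])["t"]
        table = hits_to_blast6(hits)
        assert list(table.columns)[:4] == ["qseqid", "sseqid", "pident", "length"]
        assert len(table) == len(hits)
        assert table.iloc[0].pident == 100.0


class TestClassification:
    def _dbs(self, rng):
        genome = random_seq(rng, 4000)
        decoy = random_seq(rng, 4000)
        return (
            genome,
            decoy,
            SearchDatabase.build("genome", [("chr1", genome)]),
            SearchDatabase.build("decoys", [("d1", decoy)]),
        )

    def test_genome_read_is_endogenous_and_unique(self, rng):
        genome, _decoy, db_g, db_d = self._dbs(rng)
        read = genome[200:260]
        hits = search("q", read, [db_g, db_d])
        rec = classify_read("q", hits, {"genome"})
        assert rec.label == "endogenous" and rec.unique_best

    def test_decoy_read_is_contaminant(self, rng):
        _genome, decoy, db_g, db_d = self._dbs(rng)
        read = decoy[200:260]
        hits = search("q", read, [db_g, db_d])
        rec = classify_read("q", hits, {"genome"})
        assert rec.label == "contaminant"

    def test_no_hits_is_unclassified(self, rng):
        _genome, _decoy, db_g, db_d = self._dbs(rng)
        hits = search("q", "ACGT" * 15, [db_g, db_d])
        rec = classify_read("q", hits, {"genome"})
        assert rec.label == "unclassified"

    def test_duplicated_locus_flags_non_unique(self, rng):
        core = random_seq(rng, 80)
        genome = random_seq(rng, 500) + core + random_seq(rng, 500) + core + random_seq(rng, 500)
        db = SearchDatabase.build("genome", [("chr1", genome)])
        read = core[10:70]
        rec = classify_read("q", search("q", read, [db]), {"genome"})
        assert rec.label == "endogenous"
        assert not rec.unique_best

    def test_contaminant_tie_is_conservative(self, rng):
        shared = random_seq(rng, 60)
        db_g = SearchDatabase.build("genome", [("chr1", random_seq(rng, 500) + shared)])
        db_d = SearchDatabase.build("decoys", [("d1", random_seq(rng, 500) + shared)])
        rec = classify_read("q", search("q", shared, [db_g, db_d]), {"genome"})
        assert rec.label == "contaminant"


class TestSearchBiases:
    def test_detection_drops_with_database_divergence(self, rng):
        """The seeding sensitivity loss: detection of planted reads is
        non-increasing as the database diverges from the reads."""
        from adnapipe.synth_genomes import simulate_genome_pair

        rates = []
        for div in (0.0, 0.10, 0.25):
            ga, gb, _aln = simulate_genome_pair(30_000, div, 0.0, seed=31)
            db = SearchDatabase.build("g", [("g", gb.sequence)])
            rng_local = np.random.default_rng(5)
            found = 0
            n = 150
            for _ in range(n):
                s = int(rng_local.integers(0, len(ga) - 50))
                hits = search(f"r{s}", ga.sequence[s : s + 50], [db])["g"]
                found += bool(hits)
            rates.append(found / n)
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] > rates[2]

    def test_longer_reads_detected_at_least_as_often(self, rng):
        from adnapipe.synth_genomes import simulate_genome_pair

        ga, gb, _aln = simulate_genome_pair(30_000, 0.12, 0.0, seed=33)
        db = SearchDatabase.build("g", [("g", gb.sequence)])
        rng_local = np.random.default_rng(6)
        rates = []
        for length in (30, 90):
            found = 0
            n = 120
            for _ in range(n):
                s = int(rng_local.integers(0, len(ga) - length))
                hits = search(f"r{s}", ga.sequence[s : s + length], [db])["g"]
                found += bool(hits)
            rates.append(found / n)
        assert rates[1] >= rates[0]
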