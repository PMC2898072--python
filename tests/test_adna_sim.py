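"""Fragment simulator: step semantics, damage closed forms, truth replay."""

import numpy as np
import pytest

from adnapipe import adna_sim
from adnapipe.adna_sim import (
    DamageParams,
    LengthDistribution,
    SimulationConfig,
    apply_damage,
    apply_indels,
    apply_lineage_divergence,
    apply_random_substitutions,
    parse_fragment_header,
    replay_truth,
    sample_fragments,
    simulate_dataset,
)
from adnapipe.errors import ParameterError
from adnapipe.synth_genomes import (
    AlignmentBlock,
    GenomePairAlignment,
    GenomePairStats,
    SubstitutionMatrix,
    simulate_genome_pair,
)


def make_fragment(seq, start=0, strand="+", name="gA"):
    return adna_sim.AncientFragment(
        fragment_id=f"N_{name}-{start}_{strand}",
        sequence=seq,
        source_name=name,
        start=start,
        end=start + len(seq),
        strand=strand,
    )


class TestSampling:
    def test_indel_free_pair_accepts_everything(self):
        ga, _gb, aln = simulate_genome_pair(10_000, 0.01, 0.0, seed=3)
        lengths = LengthDistribution.from_histogram({40: 1.0})
        frags = sample_fragments(ga, aln, lengths, 200, seed=1)
        assert len(frags) == 200
        for f in frags:
            assert ga.sequence[f.start : f.end] == f.sequence

    def test_fixed_seed_reproduces_fragment_set(self, small_pair):
        ga, _gb, aln = small_pair
        lengths = LengthDistribution.lognormal()
        a = sample_fragments(ga, aln, lengths, 50, seed=4)
        b = sample_fragments(ga, aln, lengths, 50, seed=4)
        assert [(f.fragment_id, f.sequence) for f in a] == [
            (f.fragment_id, f.sequence) for f in b
        ]

    def test_histogram_mean_length(self, small_pair):
        ga, _gb, aln = small_pair
        lengths = LengthDistribution.from_histogram({60: 0.5, 70: 0.5})
        frags = sample_fragments(ga, aln, lengths, 10_000, seed=5)
        mean = np.mean([len(f.sequence) for f in frags])
        se = 5.0 / np.sqrt(10_000)  # half-spread of the two-point mixture
        assert abs(mean - 65.0) < 3 * se

    def test_default_length_distribution_mean_is_63(self):
        d = LengthDistribution.lognormal()
        assert float((d.lengths * d.probs).sum()) == pytest.approx(63.0, abs=0.5)


class TestStep1LineageDivergence:
    def test_x_zero_is_identity(self, small_pair):
        ga, _gb, aln = small_pair
        frag = make_fragment(ga.sequence[100:200], 100)
        out = apply_lineage_divergence(frag, aln, 0.0, 11)
        assert out.sequence == frag.sequence
        assert out.truth.lineage_subs == []

    def test_substitution_count_is_binomial_in_mismatch_columns(self):
        # X = 13/2 -> switch probability 1/2 at each of 40 mismatch columns
        a = "ACGT" * 25
        b = "TTGG" * 10 + a[40:]  # first 40 columns mismatch by construction
        n_mismatch = sum(x != y for x, y in zip(a, b))
        aln = GenomePairAlignment("x", "y", 100, 100, [AlignmentBlock(0, 100, 0, 100, "+", a, b)])
        rng = np.random.default_rng(0)
        counts = []
        frag = make_fragment(a, 0, name="x")
        for _ in range(1000):
            out = apply_lineage_divergence(frag, aln, 13 / 2, rng)
            counts.append(len(out.truth.lineage_subs))
        expected = n_mismatch / 2
        se = np.sqrt(n_mismatch * 0.25 / 1000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_identical_region_unchanged_for_any_x(self, identical_pair):
        ga, _gb, aln = identical_pair
        frag = make_fragment(ga.sequence[:80], 0)
        out = apply_lineage_divergence(frag, aln, 6.5, 3)
        assert out.sequence == frag.sequence


class TestStep2RandomSubstitutions:
    def _stats(self, r):
        return GenomePairStats(r=r, indel_rate=0.0, matrix=SubstitutionMatrix.uniform())

    def test_x_zero_and_r_zero_are_identity(self):
        frag = make_fragment("ACGT" * 20)
        for x, r in ((0.0, 0.012), (13.0, 0.0)):
            out = apply_random_substitutions(frag, x, self._stats(r), 5)
            assert out.sequence == frag.sequence

    def test_mutated_fraction_matches_rate(self):
        n = 1_000_000
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        frag = make_fragment(seq)
        out = apply_random_substitutions(frag, 13.0, self._stats(0.012), 7)
        frac = len(out.truth.random_subs) / n
        se = np.sqrt(0.012 * 0.988 / n)
        assert abs(frac - 0.012) < 3 * se


class TestStep3Indels:
    def test_indel_free_alignment_is_identity(self, identical_pair):
        ga, _gb, aln = identical_pair
        frag = make_fragment(ga.sequence[:60], 0)
        out = apply_indels(frag, aln, 13.0, 1)
        assert out.sequence == frag.sequence

    def _deletion_alignment(self):
        # genome A: 60 bp; B lacks a 3-bp run in the middle
        rng = np.random.default_rng(9)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        ga_row = a
        gb_row = a[:30] + "---" + a[33:]
        blk = AlignmentBlock(0, 60, 0, 57, "+", ga_row, gb_row)
        return a, GenomePairAlignment("x", "y", 60, 57, [blk])

    def test_x_max_applies_every_overlapping_indel(self):
        a, aln = self._deletion_alignment()
        frag = make_fragment(a, 0, name="x")
        out = apply_indels(frag, aln, 13.0, 2)
        assert len(out.sequence) == 57
        assert out.sequence == a[:30] + a[33:]

    def test_half_probability_application_rate(self):
        a, aln = self._deletion_alignment()
        frag = make_fragment(a, 0, name="x")
        rng = np.random.default_rng(3)
        applied = sum(
            bool(apply_indels(frag, aln, 6.5, rng).truth.indels) for _ in range(1000)
        )
        se = np.sqrt(0.25 / 1000)
        assert abs(applied / 1000 - 0.5) < 3 * se


class TestStep4Damage:
    def test_zero_rates_are_identity(self):
        frag = make_fragment("CCGGCCGG" * 10)
        params = DamageParams(delta_ss=0.0, delta_ds=0.0)
        out = apply_damage(frag, params, 4)
        assert out.sequence == frag.sequence

    def test_terminal_ct_rate_matches_closed_form(self):
        # P(5' position 0 is deaminated | it is C) =
        #   q * delta_ss + (1 - q) * delta_ds  with  q = P(overhang >= 1)
        params = DamageParams()
        q = params.overhang_p
        expected = q * params.delta_ss + (1 - q) * params.delta_ds
        rng = np.random.default_rng(6)
        n = 20_000
        hits = 0
        for _ in range(n):
            out = apply_damage(make_fragment("C" + "A" * 59), params, rng)
            hits += out.sequence[0] == "T"
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_interior_rate_matches_delta_ds(self):
        params = DamageParams()
        rng = np.random.default_rng(7)
        mid_hits = 0
        n = 20_000
        for _ in range(n):
            out = apply_damage(make_fragment("A" * 30 + "C" + "A" * 29), params, rng)
            mid_hits += out.sequence[30] == "T"
        # position 30 of a 60-mer is essentially never inside an overhang
        expected = params.delta_ds
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(mid_hits / n - expected) < 3 * se

    def test_damage_is_transition_only(self, rng):
        params = DamageParams()
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        for seed in range(50):
            out = apply_damage(make_fragment(seq), params, seed)
            for pos, old, new in out.truth.damage:
                assert (old, new) in ((1, 3), (2, 0))  # C->T or G->A

    def test_five_prime_ct_rate_decays_toward_interior(self):
        params = DamageParams()
        rng = np.random.default_rng(8)
        n = 30_000
        hits = np.zeros(6)
        for _ in range(n):
            out = apply_damage(make_fragment("CCCCCC" + "A" * 54), params, rng)
            for i in range(6):
                hits[i] += out.sequence[i] == "T"
        rates = hits / n
        # expected rate at depth i: P(overhang > i) * delta_ss + ... -> decreasing
        assert all(rates[i] > rates[i + 1] - 0.01 for i in range(5))
        assert rates[0] > 0.2
        assert rates[5] < 0.05


class TestDatasetAndTruth:
    def test_header_parse_roundtrip(self):
        assert parse_fragment_header(">N_chr15-75613688_-") == ("chr15", 75613688, "-")
        assert parse_fragment_header("N_gA-123_+") == ("gA", 123, "+")
        with pytest.raises(ParameterError):
            parse_fragment_header(">X_chr1-5_+")

    def test_x_zero_no_damage_reads_are_exact_substrings(self, small_pair, small_pair_stats):
        ga, _gb, aln = small_pair
        config = SimulationConfig(x_myr=0.0, n_fragments=50, seed=3)
        frags = simulate_dataset(config, ga, aln, small_pair_stats, damage=None)
        for f in frags:
            sub = ga.sequence[f.start : f.end]
            if f.strand == "-":
                from adnapipe.seq import revcomp

                sub = revcomp(sub)
            assert f.sequence == sub

    def test_truth_replay_reproduces_reads_exactly(self, small_pair, small_pair_stats):
        ga, _gb, aln = small_pair
        config = SimulationConfig(x_myr=6.0, n_fragments=300, seed=13)
        frags = simulate_dataset(config, ga, aln, small_pair_stats, DamageParams())
        assert len(frags) > 0
        for f in frags:
            assert replay_truth(f, ga) == f.sequence

    def test_fixed_seed_outputs_byte_identical(self, small_pair, small_pair_stats, tmp_path):
        ga, _gb, aln = small_pair
        config = SimulationConfig(x_myr=2.0, n_fragments=40, seed=21)
        for run in (1, 2):
            simulate_dataset(
                config,
                ga,
                aln,
                small_pair_stats,
                DamageParams(),
                fasta_path=tmp_path / f"r{run}.fa",
                truth_path=tmp_path / f"t{run}.tsv",
            )
        assert (tmp_path / "r1.fa").read_bytes() == (tmp_path / "r2.fa").read_bytes()
        assert (tmp_path / "t1.tsv").read_bytes() == (tmp_path / "t2.tsv").read_bytes()

    def test_step1_rate_over_many_fragments(self, small_pair):
        # aggregate step-1 substitutions ~ Binomial(covered mismatch cols, X/13)
        ga, _gb, aln = small_pair
        x = 3.0
        rng = np.random.default_rng(17)
        total_cols = 0
        total_subs = 0
        pos, _var = aln.mismatch_positions()
        for _ in range(2000):
            start = int(rng.integers(0, len(ga) - 60))
            frag = make_fragment(ga.sequence[start : start + 60], start)
            covered = int(np.searchsorted(pos, frag.end) - np.searchsorted(pos, frag.start))
            out = apply_lineage_divergence(frag, aln, x, rng)
            total_cols += covered
            total_subs += len(out.truth.lineage_subs)
        p = x / 13.0
        se = np.sqrt(total_cols * p * (1 - p))
        assert abs(total_subs - total_cols * p) < 3 * se
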