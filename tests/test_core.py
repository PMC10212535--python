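"""fimpera core: discretization, s-abundance, build and query."""

import itertools

import numpy as np
import pytest

from fimpera.core import (
    DiscretizationSpec,
    FimperaConfig,
    FimperaIndex,
    compute_sab,
)
from fimpera.sequence_io import CountedKmerTable, canonical, write_fasta, SequenceRecord
from fimpera.synthetic import (
    counted_kmers_from_genome,
    disjoint_genome,
    generate_genome,
    geometric_abundance,
    sample_reads,
)


class TestDiscretization:
    def test_log2_rank_and_decode(self):
        spec = DiscretizationSpec("log2", 5)
        assert spec.discretize(8) == 3
        assert spec.decode(3) == (8, 15)

    @pytest.mark.parametrize("mode", ["identity", "log2", "log10"])
    def test_abundance_one(self, mode):
        spec = DiscretizationSpec(mode, 5)
        assert spec.discretize(1) == (1 if mode == "identity" else 0)

    def test_saturation(self):
        assert DiscretizationSpec("log2", 5).discretize(2**40) == 31

    def test_exact_powers_no_float_slip(self):
        spec2 = DiscretizationSpec("log2", 8)
        for e in range(0, 30):
            assert spec2.discretize(2**e) == e
            if e > 0:
                assert spec2.discretize(2**e - 1) == e - 1
        spec10 = DiscretizationSpec("log10", 8)
        for e in range(0, 10):
            assert spec10.discretize(10**e) == e

    def test_array_matches_scalar(self, rng):
        xs = rng.integers(1, 10**6, 500)
        for mode in ("identity", "log2", "log10"):
            spec = DiscretizationSpec(mode, 5)
            assert spec.discretize_array(xs).tolist() == [
                spec.discretize(int(x)) for x in xs
            ]

    def test_monotone_and_surjective_onto_used_range(self):
        spec = DiscretizationSpec("log2", 3)
        ranks = [spec.discretize(x) for x in range(1, 1000)]
        assert ranks == sorted(ranks)
        assert set(ranks) == set(range(0, 8))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            DiscretizationSpec("log2", 5).discretize(0)


class TestComputeSab:
    def test_shared_smer_takes_max(self, tiny_table):
        assert compute_sab(tiny_table, 4) == {"ACGT": 5, "CGTA": 5, "GTAC": 3}

    def test_single_contributor(self):
        table = CountedKmerTable([("ACGTA", 7)], k=5)
        assert compute_sab(table, 4) == {"ACGT": 7, "CGTA": 7}

    def test_matches_brute_force(self, random_table):
        s = 18
        sab = compute_sab(random_table, s)
        smers = {w[i : i + s] for w, _ in random_table for i in range(len(w) - s + 1)}
        brute = {
            m: max(c for w, c in random_table if m in w) for m in smers
        }
        assert sab == brute

    def test_canonical_keys(self, tiny_table):
        sab = compute_sab(tiny_table, 4, canonical=True)
        assert set(sab) == {canonical(m) for m in ("ACGT", "CGTA", "GTAC")}
        assert sab[canonical("GTAC")] == 3

    def test_s_larger_than_k_raises(self, tiny_table):
        with pytest.raises(ValueError):
            compute_sab(tiny_table, 6)


class TestBuild:
    def test_z0_degenerates_to_plain_counting_filter(self, random_table):
        cfg = FimperaConfig(
            k=21, z=0, b=8, nb_slots=1 << 22, discretization="identity"
        )
        idx = FimperaIndex.build(random_table, cfg)
        for kmer, count in random_table:
            assert idx.filter.lookup(kmer) == min(count + 1, idx.filter.cap)

    def test_small_worked_example(self, tiny_table):
        cfg = FimperaConfig(k=5, z=1, b=8, nb_slots=1 << 16, discretization="identity")
        idx = FimperaIndex.build(tiny_table, cfg)
        # CGTA is shared by both k-mers: s_ab = max(5, 3) = 5, stored shifted
        assert idx.filter.lookup("CGTA") == 6

    def test_lookup_dominates_sab_oracle(
        self, random_table, collision_free_index, collision_free_truth
    ):
        """lookup(m) >= stored s_ab for every s-mer, equality without collisions."""
        idx = collision_free_index
        spec = idx.config.spec()
        for smer, sab in collision_free_truth.sab.items():
            expect = min(spec.discretize(sab) + 1, idx.filter.cap)
            assert idx.filter.lookup(smer) >= expect

    def test_collision_free_equality(self, collision_free_index, collision_free_truth):
        """At generous sizing, slot collisions vanish and equality holds."""
        idx = collision_free_index
        spec = idx.config.spec()
        mismatches = sum(
            idx.filter.lookup(m) != min(spec.discretize(v) + 1, idx.filter.cap)
            for m, v in collision_free_truth.sab.items()
        )
        assert mismatches == 0

    def test_wrong_word_length_rejected(self, tiny_table):
        cfg = FimperaConfig(k=7, z=2, b=5, nb_slots=64)
        with pytest.raises(ValueError):
            FimperaIndex.build(tiny_table, cfg)

    def test_raw_smer_mode_indexes_smer_table(self):
        smers = CountedKmerTable([("ACGT", 9), ("CGTA", 2)], k=4)
        cfg = FimperaConfig(
            k=6, z=2, b=8, nb_slots=1 << 16,
            discretization="identity", abundance_mode="raw",
        )
        idx = FimperaIndex.build(smers, cfg)
        assert idx.filter.lookup("ACGT") == 10
        assert idx.filter.lookup("CGTA") == 3


class TestConfig:
    def test_invalid_parameters_rejected(self):
        for bad in (
            {"k": 0},
            {"z": -1},
            {"z": 31},
            {"b": 0},
            {"discretization": "sqrt"},
            {"abundance_mode": "other"},
            {"k": 40, "z": 2},
        ):
            with pytest.raises(ValueError):
                FimperaConfig(**{"k": 31, "z": 3, **bad})

    def test_round_trips_through_dict(self):
        cfg = FimperaConfig(k=21, z=4, b=3, nb_slots=777, canonical=True)
        assert FimperaConfig.from_dict(cfg.to_dict()) == cfg


class TestQuery:
    def test_ranks_are_sliding_min_of_responses(self, collision_free_index, rng):
        idx = collision_free_index
        genome = generate_genome(520, seed=7)
        read = genome[40:140]
        from fimpera.sliding_extrema import sliding_window_min

        responses = idx.smer_responses(read)
        expected = sliding_window_min(responses, idx.config.z + 1)
        assert np.array_equal(idx.query_sequence(read, optimize=False), expected)
        assert np.array_equal(idx.query_sequence(read, optimize=True), expected)

    def test_zero_response_zeroes_covering_kmers(self, collision_free_index):
        idx = collision_free_index
        k = idx.config.k
        read = generate_genome(520, seed=7)[100 : 100 + k]
        # poison the middle with an N: every window is invalid or broken
        poisoned = read[: k // 2] + "N" + read[k // 2 + 1 :]
        assert idx.query_sequence(poisoned).tolist() == [0]

    def test_short_sequence_empty_vector(self, collision_free_index):
        assert collision_free_index.query_sequence("ACGT").size == 0

    def test_optimized_bit_identical_on_mixed_reads(self, collision_free_index, rng):
        """1000 random reads spanning present and absent stretches."""
        idx = collision_free_index
        genome = generate_genome(520, seed=7)
        other = disjoint_genome(genome, 2000, idx.config.k, seed=11)
        for i in range(1000):
            mode = i % 4
            if mode == 0:
                start = int(rng.integers(0, len(genome) - 60))
                read = genome[start : start + 60]
            elif mode == 1:
                start = int(rng.integers(0, len(other) - 60))
                read = other[start : start + 60]
            elif mode == 2:  # chimeric: absent stretch inside present context
                a = int(rng.integers(0, len(genome) - 40))
                b = int(rng.integers(0, len(other) - 30))
                read = genome[a : a + 40] + other[b : b + 30]
            else:  # with an ambiguous base
                start = int(rng.integers(0, len(genome) - 60))
                read = genome[start : start + 30] + "N" + genome[start + 31 : start + 60]
            assert np.array_equal(
                idx.query_sequence(read, optimize=True),
                idx.query_sequence(read, optimize=False),
            ), read

    def test_query_kmers_matches_query_sequence(self, collision_free_index, rng):
        idx = collision_free_index
        genome = generate_genome(520, seed=7)
        k = idx.config.k
        kmers = [genome[i : i + k] for i in rng.integers(0, len(genome) - k, 50)]
        batch = idx.query_kmers(kmers)
        singles = [int(idx.query_sequence(w)[0]) for w in kmers]
        assert batch.tolist() == singles

    def test_no_underestimation_end_to_end(
        self, random_table, collision_free_index, collision_free_truth
    ):
        """Every indexed k-mer reports at least its discretized abundance."""
        idx = collision_free_index
        spec = idx.config.spec()
        kmers = [w for w, _ in random_table]
        reported = idx.query_kmers(kmers)
        for (kmer, count), rep in zip(random_table, reported.tolist()):
            assert rep >= min(spec.discretize(count) + 1, idx.filter.cap)

    def test_z0_query_equals_plain_cbf_answer(self, random_table, rng):
        cfg = FimperaConfig(k=21, z=0, b=5, nb_slots=1 << 10)
        idx = FimperaIndex.build(random_table, cfg)
        kmers = [w for w, _ in random_table][:200]
        absent = ["".join(rng.choice(list("ACGT"), 21)) for _ in range(200)]
        for w in kmers + absent:
            assert idx.query_sequence(w).tolist() == [idx.filter.lookup(w)]


class TestQueryFile:
    @pytest.fixture
    def query_fasta(self, tmp_path, collision_free_index):
        genome = generate_genome(520, seed=7)
        recs = [
            SequenceRecord(id="r1", seq=genome[10:80]),
            SequenceRecord(id="r2", seq=genome[200:280]),
            SequenceRecord(id="short", seq="ACGT"),
        ]
        p = tmp_path / "q.fasta"
        write_fasta(recs, p)
        return p

    def test_per_kmer_shapes(self, collision_free_index, query_fasta):
        out = list(collision_free_index.query_file(query_fasta, "per_kmer"))
        k = collision_free_index.config.k
        assert [rid for rid, _ in out] == ["r1", "r2", "short"]
        assert [v.size for _, v in out] == [70 - k + 1, 80 - k + 1, 0]

    def test_per_read_mean(self, collision_free_index, query_fasta):
        out = dict(collision_free_index.query_file(query_fasta, "per_read_mean"))
        assert "short" not in out  # shorter than k: no value
        ranks = dict(collision_free_index.query_file(query_fasta, "per_kmer"))
        for rid, mean in out.items():
            assert mean == pytest.approx(np.maximum(ranks[rid] - 1, 0).mean())

    def test_constant_rank_read_mean(self, tmp_path):
        table = CountedKmerTable([("ACGTAACGTA", 2)], k=10)
        cfg = FimperaConfig(k=10, z=0, b=8, nb_slots=1 << 16, discretization="identity")
        idx = FimperaIndex.build(table, cfg)
        p = tmp_path / "one.fasta"
        write_fasta([SequenceRecord(id="r", seq="ACGTAACGTA")], p)
        out = dict(idx.query_file(p, "per_read_mean"))
        assert out["r"] == 2.0

    def test_threshold_filters_absent_reads(self, tmp_path, collision_free_index):
        genome = generate_genome(520, seed=7)
        other = disjoint_genome(genome, 1000, collision_free_index.config.k, seed=3)
        p = tmp_path / "absent.fasta"
        write_fasta([SequenceRecord(id=f"a{i}", seq=other[i * 60 : i * 60 + 60])
                     for i in range(5)], p)
        assert list(collision_free_index.query_file(p, "threshold", threshold=0.0)) == []


class TestPersistence:
    def test_index_round_trip(self, tmp_path, random_table):
        cfg = FimperaConfig(k=21, z=2, b=4, nb_slots=4096, canonical=True)
        idx = FimperaIndex.build(random_table, cfg)
        idx.save(tmp_path / "i.idx")
        back = FimperaIndex.load(tmp_path / "i.idx")
        assert back.config == cfg
        assert back.filter == idx.filter
        read = generate_genome(520, seed=7)[:80]
        assert np.array_equal(back.query_sequence(read), idx.query_sequence(read))
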