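from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sexmark.io import Read, mates, revcomp
from sexmark.screen import (
    KmerScreenParams,
    TrimParams,
    count_pool_kmers,
    extract_candidate_read_pairs,
    extract_prefixed_kmers,
    filter_and_select_msks,
    quality_trim,
    run_screen,
    trimmed_length,
)
from sexmark.synthetic import MSR_ID, parse_read_origin


def q(phred, n):
    return chr(phred + 33) * n


def naive_prefixed_kmers(seq, k, prefix):
    """Position-by-position oracle for prefix-anchored k-mer extraction."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer.startswith(prefix) and "N" not in kmer:
            out.append(kmer)
    return out


class TestQualityTrim:
    params = TrimParams(window=4, min_mean_quality=20, min_length=50)

    def test_clean_reads_pass_untouched(self):
        pair = (Read("a", "ACGT" * 25, q(37, 100)), Read("a", "TGCA" * 25, q(37, 100)))
        assert quality_trim([pair], self.params) == [pair]

    def test_low_quality_tail_is_trimmed_to_oracle_length(self):
        # 150 bp read whose final 60 bases are Q2: windowed + trailing trim keeps 90
        quals = [37] * 90 + [2] * 60
        read = Read("r", "A" * 150, "".join(chr(v + 33) for v in quals))
        mate = Read("r", "C" * 150, q(37, 150))
        (kept,) = quality_trim([(read, mate)], self.params)
        assert len(kept[0].seq) == 90
        assert kept[0].seq == "A" * 90
        # independent oracle: longest prefix whose every 4-window mean and
        # terminal base clear Q20
        def oracle(qs):
            best = 0
            for n in range(len(qs) + 1):
                prefix = qs[:n]
                windows_ok = all(
                    sum(prefix[j - 4 : j]) / 4 >= 20 for j in range(4, n + 1)
                )
                if windows_ok and (n == 0 or prefix[-1] >= 20):
                    best = n
            return best

        assert trimmed_length(quals, self.params) == oracle(quals) == 90

    def test_entirely_bad_read_drops_the_pair(self):
        bad = Read("r", "A" * 150, q(2, 150))
        good = Read("r", "C" * 150, q(37, 150))
        assert quality_trim([(bad, good)], self.params) == []
        assert quality_trim([(good, bad)], self.params) == []

    def test_trim_only_removes_three_prime_bases(self):
        quals = [2] * 10 + [37] * 90
        read = Read("r", "G" * 100, "".join(chr(v + 33) for v in quals))
        (kept,) = quality_trim([(read, Read("r", "C" * 100, q(37, 100)))], self.params)
        assert kept[0].seq == "G" * 100  # low-quality 5' bases stay

    def test_malformed_record_reports_index(self):
        good = (Read("a", "ACGT" * 25, q(37, 100)), Read("a", "ACGT" * 25, q(37, 100)))
        bad = Read.__new__(Read)
        object.__setattr__(bad, "name", "b")
        object.__setattr__(bad, "seq", "ACGT")
        object.__setattr__(bad, "qual", "FF")
        with pytest.raises(ValueError, match="index 1"):
            quality_trim([good, (bad, good[0])], self.params)


class TestExtractPrefixedKmers:
    def test_too_short_sequence_is_empty(self):
        assert extract_prefixed_kmers("A" * 34, KmerScreenParams()) == []

    def test_hand_worked_example(self):
        params = KmerScreenParams(k=3, required_prefix="AG")
        assert extract_prefixed_kmers("AGAAGT", params) == ["AGA", "AGT"]

    def test_single_exact_length_kmer(self):
        seq = "AG" + "C" * 33
        assert extract_prefixed_kmers(seq, KmerScreenParams()) == [seq]

    def test_kmers_containing_n_are_skipped(self):
        params = KmerScreenParams(k=4, required_prefix="AG")
        assert extract_prefixed_kmers("AGNNAGCT", params) == ["AGCT"]

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_matches_naive_scan(self, seq):
        params = KmerScreenParams(k=7, required_prefix="AG")
        assert extract_prefixed_kmers(seq, params) == naive_prefixed_kmers(seq, 7, "AG")


class TestCountPoolKmers:
    def test_multiplicity_within_one_read(self):
        params = KmerScreenParams(k=3, required_prefix="AG")
        table = count_pool_kmers([Read("r", "AGAAGA", q(37, 6))], [], params)
        assert table == {"AGA": (2, 0)}

    def test_identical_pools_are_symmetric(self):
        params = KmerScreenParams(k=5, required_prefix="AG")
        reads = [Read(f"r{i}", "AGACGTAGCCA", q(37, 11)) for i in range(4)]
        table = count_pool_kmers(reads, reads, params)
        assert table
        assert all(m == f for m, f in table.values())

    def test_empty_pools_give_empty_table(self):
        assert count_pool_kmers([], [], KmerScreenParams()) == {}

    def test_presence_mode_counts_once_per_read(self):
        params = KmerScreenParams(k=3, required_prefix="AG", count_multiplicity=False)
        table = count_pool_kmers([Read("r", "AGAAGA", q(37, 6))], [], params)
        assert table == {"AGA": (1, 0)}

    @pytest.mark.parametrize("partitions", [4, 16])
    def test_partitioned_counting_equals_single_pass(self, partitions, small_pools):
        male, female = small_pools
        params = KmerScreenParams()
        male_reads = list(mates(male[:300]))
        female_reads = list(mates(female[:300]))
        single = count_pool_kmers(male_reads, female_reads, params)
        parted = count_pool_kmers(male_reads, female_reads, params, partitions=partitions)
        assert single == parted


class TestFilterAndSelect:
    @pytest.mark.parametrize(
        "male,female,in_table,is_msk",
        [
            (1, 0, False, False),  # total below the minimum of two
            (2, 0, True, True),  # minimal pure MSK
            (201, 0, False, False),  # total above 200
            (150, 1, True, False),  # female evidence disqualifies
            (0, 2, True, False),
            (100, 100, True, False),
        ],
    )
    def test_threshold_semantics(self, male, female, in_table, is_msk):
        params = KmerScreenParams()
        kmer = "AG" + "A" * 33
        filtered, msks = filter_and_select_msks({kmer: (male, female)}, params)
        assert (kmer in filtered) == in_table
        assert (kmer in msks) == is_msk

    @given(
        lo=st.integers(1, 5),
        hi=st.integers(5, 50),
        widen=st.integers(0, 5),
        counts=st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60)), max_size=30),
    )
    def test_widening_the_band_never_shrinks_outputs(self, lo, hi, widen, counts):
        table = {f"AG{i:05d}".replace("0", "C").replace("1", "G").replace("2", "T")
                 .replace("3", "A").replace("4", "C").replace("5", "G")
                 .replace("6", "T").replace("7", "A").replace("8", "C").replace("9", "G"): mf
                 for i, mf in enumerate(counts)}
        narrow = KmerScreenParams(k=7, required_prefix="AG", min_total_count=lo, max_total_count=hi)
        wide = KmerScreenParams(
            k=7, required_prefix="AG",
            min_total_count=max(1, lo - widen), max_total_count=hi + widen,
        )
        f_narrow, m_narrow = filter_and_select_msks(table, narrow)
        f_wide, m_wide = filter_and_select_msks(table, wide)
        assert set(f_narrow) <= set(f_wide)
        assert m_narrow <= m_wide

    def test_msk_invariant_holds(self):
        params = KmerScreenParams(k=3, required_prefix="A", min_total_count=2, max_total_count=10)
        table = {"AAA": (3, 0), "AAC": (1, 1), "AAG": (0, 4), "AAT": (11, 0)}
        filtered, msks = filter_and_select_msks(table, params)
        for kmer in msks:
            m, f = filtered[kmer]
            assert f == 0 and m >= params.min_total_count


class TestExtractCandidates:
    params = KmerScreenParams(k=5, required_prefix="AG")

    def test_msk_in_either_mate_retains_pair(self):
        msks = {"AGCCA"}
        hit = Read("r", "TTAGCCATT", q(37, 9))
        miss = Read("r", "TTTTTTTTT", q(37, 9))
        assert extract_candidate_read_pairs([(hit, miss)], msks, self.params) == [(hit, miss)]
        assert extract_candidate_read_pairs([(miss, hit)], msks, self.params) == [(miss, hit)]
        assert extract_candidate_read_pairs([(miss, miss)], msks, self.params) == []

    def test_candidates_originate_from_msr_fragments(self, small_genomes, small_pools):
        male, female = small_pools
        _, msks, candidates = run_screen(male, female, KmerScreenParams(), trim=None)
        assert candidates
        origins = Counter(parse_read_origin(m1.name)[0] for m1, _ in candidates)
        # nearly all MSK-bearing pairs come from the planted MSR; rare
        # sampling-dropout false MSKs may pull in a few background pairs
        assert origins[MSR_ID] / len(candidates) > 0.9


class TestScreenOnSimulation:
    def test_msks_come_from_male_genome_with_minimal_female_leakage(
        self, small_genomes, small_pools
    ):
        # every MSK is real male sequence; a small residue may also occur in
        # the female genome when the female pool misses an oriented window by
        # sampling (the map-back stage downstream removes those)
        male, female = small_pools

        def space(seqs, k=35):
            parts = []
            for _, s in seqs:
                circ = s + s[: k - 1]
                parts.extend((circ, revcomp(circ)))
            return " ".join(parts)

        _, msks, _ = run_screen(male, female, KmerScreenParams(), trim=None)
        assert len(msks) > 50
        male_space = space(small_genomes.male)
        female_space = space(small_genomes.female)
        for kmer in msks:
            assert kmer in male_space
        leaked = sum(kmer in female_space for kmer in msks)
        assert leaked / len(msks) <= 0.01

    def test_every_table_key_has_the_prefix(self, small_pools):
        male, female = small_pools
        params = KmerScreenParams()
        table = count_pool_kmers(
            list(mates(male[:200])), list(mates(female[:200])), params
        )
        assert table
        assert all(k.startswith("AG") and len(k) == 35 for k in table)
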