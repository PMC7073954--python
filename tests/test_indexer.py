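import numpy as np
import pytest

from kmercn.codec import EncodedKmer, canonical, decode_kmer, encode_kmer
from kmercn.indexer import (
    ControlRegions,
    IndexFormatError,
    IndexerConfig,
    ParameterMismatchError,
    build_catalog,
    enumerate_occurrences,
    filter_catalog,
    locate_and_annotate,
    near_match_count,
    near_match_counts,
    prepare_control,
    read_index,
    select_candidates,
    write_index,
    write_index_tsv,
)
from kmercn.simulate import implant_duplication, make_reference

from oracles import allpairs_near_counts, blocked_near_counts, oracle_retained_set


def cval(s: str) -> int:
    return canonical(encode_kmer(s)).value


def names_of(values, k):
    return {decode_kmer(EncodedKmer(int(v), k)) for v in values}


class TestEnumerate:
    def test_worked_example(self):
        occ = enumerate_occurrences({"c": "ACGTACGT"}, 4)
        got = {int(key): int(n) for key, n in zip(occ.keys, occ.counts)}
        assert got == {cval("ACGT"): 2, cval("CGTA"): 2, cval("GTAC"): 1}
        assert cval("CGTA") == cval("TACG")  # mutual reverse complements share one entry

    def test_homopolymer(self):
        occ = enumerate_occurrences({"c": "AAAA"}, 4)
        assert {int(k): int(n) for k, n in zip(occ.keys, occ.counts)} == {cval("AAAA"): 1}

    def test_n_discards_windows(self):
        occ = enumerate_occurrences({"c": "ACNGT"}, 4)
        assert len(occ) == 0

    def test_empty_reference(self):
        assert len(enumerate_occurrences({}, 4)) == 0

    def test_sequence_shorter_than_k(self):
        assert len(enumerate_occurrences({"c": "ACG"}, 4)) == 0

    def test_counts_strand_combined(self):
        # a k-mer on one strand and its reverse complement on the other
        occ = enumerate_occurrences({"a": "ACGTA", "b": "TACGT"}, 5)
        assert occ.get(cval("ACGTA")) == 2


class TestSelectCandidates:
    def test_worked_example(self):
        occ = enumerate_occurrences({"c": "ACGTACGT"}, 4)
        assert set(map(int, select_candidates(occ))) == {cval("GTAC")}

    def test_all_unique(self):
        occ = enumerate_occurrences({"c": "ACGGTCA"}, 4)
        assert len(select_candidates(occ)) == len(occ)

    def test_none_unique(self):
        occ = enumerate_occurrences({"c": "ACGTACGTACGT"}, 4)
        assert select_candidates(occ).size == 0


def plant_neighbors(kmer: str, n_occurrences: int, seed=0):
    """Genome = k-mer + repeated single-substitution neighbors, N-separated."""
    rng = np.random.default_rng(seed)
    singles = []
    for p in range(len(kmer)):
        for b in "ACGT":
            if b != kmer[p]:
                singles.append(kmer[:p] + b + kmer[p + 1 :])
    rng.shuffle(singles)
    picks = [singles[i % len(singles)] for i in range(n_occurrences)]
    return {"c": "N".join([kmer] + picks)}


KMER30 = "ACGTTGCAGGTCCATAGACTGATCCGTTAC"


class TestNearMatch:
    def test_j0_empty_neighborhood(self):
        occ = enumerate_occurrences(plant_neighbors(KMER30, 50), 30)
        assert near_match_count(cval(KMER30), occ, 0) == 0
        assert near_match_counts(np.array([cval(KMER30)], dtype=np.uint64), occ, 0)[0] == 0

    def test_gtac_has_no_neighbors(self):
        occ = enumerate_occurrences({"c": "ACGTACGT"}, 4)
        assert near_match_count(cval("GTAC"), occ, 2) == 0

    def test_planted_150_neighbor_occurrences(self):
        occ = enumerate_occurrences(plant_neighbors(KMER30, 150), 30)
        assert occ.get(cval(KMER30)) == 1
        assert near_match_count(cval(KMER30), occ, 1) == 150
        assert near_match_count(cval(KMER30), occ, 2) == 150

    def test_batch_agrees_with_single(self, toy_genome):
        seqs, _ = toy_genome
        occ = enumerate_occurrences(seqs, 30)
        cands = select_candidates(occ)[::37]  # subsample for speed
        for j in (1, 2):
            batch = near_match_counts(cands, occ, j)
            singles = [near_match_count(int(v), occ, j) for v in cands]
            assert list(batch) == singles

    def test_agrees_with_allpairs_oracle(self):
        base = make_reference(5_000, 0.5, seed=3)
        seq, _ = implant_duplication(base, (500, 1500), 3_000, divergence=0.03, seed=4)
        occ = enumerate_occurrences({"c": seq}, 30)
        cands = select_candidates(occ)
        for j in (1, 2):
            assert np.array_equal(
                near_match_counts(cands, occ, j), allpairs_near_counts(cands, occ, j)
            )


class TestFilter:
    def config(self, **kw):
        defaults = dict(k=30, edit_distance=1, max_near=100)
        defaults.update(kw)
        return IndexerConfig(**defaults)

    def test_zero_near_retained(self):
        occ = enumerate_occurrences({"c": KMER30}, 30)
        retained = filter_catalog(select_candidates(occ), occ, self.config())
        assert cval(KMER30) in set(map(int, retained))

    def test_99_retained_100_dropped(self):
        for n, expect in ((99, True), (100, False)):
            occ = enumerate_occurrences(plant_neighbors(KMER30, n), 30)
            retained = set(map(int, filter_catalog(select_candidates(occ), occ, self.config())))
            assert (cval(KMER30) in retained) is expect

    def test_monotone_in_max_near(self, toy_genome):
        seqs, _ = toy_genome
        occ = enumerate_occurrences(seqs, 30)
        cands = select_candidates(occ)
        prev: set = set()
        for max_near in (1, 2, 5, 100):
            cur = set(map(int, filter_catalog(cands, occ, self.config(max_near=max_near))))
            assert prev <= cur
            prev = cur

    def test_antitone_in_j(self, toy_genome):
        seqs, _ = toy_genome
        occ = enumerate_occurrences(seqs, 30)
        cands = select_candidates(occ)
        sets = [
            set(map(int, filter_catalog(cands, occ, self.config(edit_distance=j, max_near=2))))
            for j in (0, 1, 2)
        ]
        assert sets[2] <= sets[1] <= sets[0]

    def test_thread_invariance(self, toy_genome):
        seqs, _ = toy_genome
        control = ControlRegions.from_intervals([("chr1", 0, len(seqs["chr1"]))])
        cats = [
            build_catalog(seqs, control, IndexerConfig(threads=t)) for t in (1, 4)
        ]
        assert cats[0] == cats[1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_retained_set_matches_bruteforce_oracle(self, seed):
        base = make_reference(6_000, 0.5, seed=seed)
        seqs = {"chr1": implant_duplication(base, (800, 2_000), 4_000,
                                            divergence=0.04, seed=seed + 50)[0]}
        for j in (1, 2):
            config = IndexerConfig(k=30, edit_distance=j, max_near=100)
            occ = enumerate_occurrences(seqs, 30)
            got = set(map(int, filter_catalog(select_candidates(occ), occ, config)))
            assert got == oracle_retained_set(seqs, 30, j, 100, blocked=False)


class TestDuplicationEffects:
    def test_perfect_duplication_excludes_inner_kmers(self):
        k = 30
        base = make_reference(4_000, 0.5, seed=9)
        seq, rep = implant_duplication(base, (1_000, 1_400), 3_000, divergence=0.0, seed=9)
        occ = enumerate_occurrences({"c": seq}, k)
        retained = names_of(
            filter_catalog(select_candidates(occ), occ, IndexerConfig(edit_distance=2)), k
        )
        s, e = rep["copy"]
        for i in range(s, e - k + 1):
            w = seq[i : i + k]
            assert decode_kmer(canonical(encode_kmer(w))) not in retained

    def test_single_substitution_rescues_overlapping_kmers(self):
        k = 30
        base = make_reference(4_000, 0.5, seed=10)
        # keep mutating until exactly one substitution lands mid-segment
        for trial in range(200):
            seq, rep = implant_duplication(base, (1_000, 1_400), 3_000,
                                           divergence=0.004, seed=trial)
            if len(rep["diverged_positions"]) == 1:
                mut = rep["diverged_positions"][0]
                if rep["copy"][0] + k <= mut <= rep["copy"][1] - k:
                    break
        else:
            pytest.fail("no single-mid-segment-substitution trial found")
        occ = enumerate_occurrences({"c": seq}, k)
        retained = names_of(
            filter_catalog(select_candidates(occ), occ, IndexerConfig(edit_distance=2)), k
        )
        # k-mers overlapping the diverged site exist once per copy: both retained
        src_mut = rep["source"][0] + (mut - rep["copy"][0])
        for pos in (mut, src_mut):
            w = seq[pos - k // 2 : pos - k // 2 + k]
            assert occ.get(cval(w)) == 1
            assert decode_kmer(canonical(encode_kmer(w))) in retained


class TestAnnotate:
    def test_control_covering_chromosome_flags_all(self, toy_genome, toy_catalog):
        assert toy_catalog.is_control.all()

    def test_partial_control_containment(self):
        seq = make_reference(2_000, 0.5, seed=21)
        config = IndexerConfig(k=30, edit_distance=0)
        control = ControlRegions.from_intervals([("chr1", 500, 1_000)])
        cat = build_catalog({"chr1": seq}, control, config)
        inside = (cat.start >= 500) & (cat.start + 30 <= 1_000)
        assert np.array_equal(cat.is_control, inside)
        # straddling k-mers exist and are not control
        straddle = (cat.start < 1_000) & (cat.start + 30 > 1_000)
        assert straddle.any() and not cat.is_control[straddle].any()

    def test_gc_extremes(self):
        # GC-only context -> 1.0; AT-only -> 0.0 (k-mers must avoid homopolymer dups)
        gc_seq = "GCCGGCGCGGCCGCGGGCCGCGCCGGCGCCGGGCGCGCC"
        at_seq = "ATTAATATAATTATAATTTATAATATTAATTTAATATTA"
        config = IndexerConfig(k=30, edit_distance=0, gc_window_bp=400)
        for seq, expect in ((gc_seq, 1.0), (at_seq, 0.0)):
            control = ControlRegions.from_intervals([("chr1", 0, len(seq))])
            cat = build_catalog({"chr1": seq}, control, config)
            assert len(cat) > 0
            assert np.allclose(cat.gc_fraction, expect)

    def test_gc_window_clipped_at_ends(self):
        seq = make_reference(300, 0.5, seed=22)
        config = IndexerConfig(k=30, edit_distance=0, gc_window_bp=400)
        control = ControlRegions.from_intervals([("chr1", 0, 300)])
        cat = build_catalog({"chr1": seq}, control, config)
        for s, got in zip(cat.start, cat.gc_fraction):
            mid = int(s) + config.k // 2
            lo, hi = max(0, mid - 200), min(len(seq), mid + 200)
            window = seq[lo:hi]
            assert got == pytest.approx(sum(c in "GC" for c in window) / len(window))

    def test_positions_recover_sequence(self, toy_genome, toy_catalog):
        seqs, _ = toy_genome
        seq = seqs["chr1"]
        k = toy_catalog.k
        for i in np.random.default_rng(0).choice(len(toy_catalog), 50, replace=False):
            s = int(toy_catalog.start[i])
            assert cval(seq[s : s + k]) == int(toy_catalog.value[i])

    def test_sorted_chromosomally_and_distinct(self, toy_catalog):
        assert np.all(np.diff(toy_catalog.chrom_id.astype(int)) >= 0)
        same = np.diff(toy_catalog.chrom_id.astype(int)) == 0
        assert np.all(np.diff(toy_catalog.start)[same] > 0)
        assert len(np.unique(toy_catalog.value)) == len(toy_catalog)


class TestSerialization:
    def test_roundtrip_bit_exact(self, toy_catalog, tmp_path):
        p = tmp_path / "toy.idx"
        write_index(toy_catalog, p)
        assert read_index(p) == toy_catalog

    def test_truncated_file_rejected(self, toy_catalog, tmp_path):
        p = tmp_path / "toy.idx"
        write_index(toy_catalog, p)
        blob = p.read_bytes()
        p.write_bytes(blob[: len(blob) - 17])
        with pytest.raises(IndexFormatError):
            read_index(p)

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "junk.idx"
        p.write_bytes(b"not an index at all")
        with pytest.raises(IndexFormatError):
            read_index(p)

    def test_parameter_mismatch(self, toy_catalog, tmp_path):
        p = tmp_path / "toy.idx"
        write_index(toy_catalog, p)
        with pytest.raises(ParameterMismatchError):
            read_index(p, expect=IndexerConfig(k=31))

    def test_tsv_dump(self, toy_catalog, tmp_path):
        p = tmp_path / "toy.tsv"
        write_index_tsv(toy_catalog, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == len(toy_catalog) + 1
        chrom, start, end, kmer, ctl, gc = lines[1].split("\t")
        assert int(end) - int(start) == toy_catalog.k
        assert set(kmer) <= set("ACGT")


class TestControlRegions:
    def test_merging_overlaps_and_abutting(self):
        cr = ControlRegions.from_intervals(
            [("c", 0, 10), ("c", 10, 20), ("c", 15, 30), ("c", 50, 60)]
        )
        assert list(cr.intervals()) == [("c", 0, 30), ("c", 50, 60)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            ControlRegions.from_intervals([("c", 10, 10)])

    def test_contains_half_open(self):
        cr = ControlRegions.from_intervals([("c", 100, 200)])
        starts = np.array([100, 170, 99, 150])
        ends = np.array([130, 200, 129, 201])
        assert list(cr.contains("c", starts, ends)) == [True, True, False, False]
        assert not cr.contains("other", starts, ends).any()

    def test_prepare_control_complement(self):
        inc = prepare_control(
            {"c1": 100, "c2": 50},
            [("c1", 10, 20), ("c1", 15, 30), ("c2", 0, 50), ("c3", 0, 10)],
        )
        assert list(inc.intervals()) == [("c1", 0, 10), ("c1", 30, 100)]

    def test_prepare_control_no_exclusions(self):
        inc = prepare_control({"c1": 100}, [])
        assert list(inc.intervals()) == [("c1", 0, 100)]

    def test_bed_roundtrip(self, tmp_path):
        cr = ControlRegions.from_intervals([("c", 5, 15), ("d", 0, 7)])
        p = tmp_path / "x.bed"
        cr.to_bed(p)
        assert list(ControlRegions.from_bed(p).intervals()) == list(cr.intervals())


class TestOracleCrossValidation:
    def test_blocked_equals_allpairs(self):
        base = make_reference(8_000, 0.5, seed=33)
        seq, _ = implant_duplication(base, (1_000, 2_000), 5_000, divergence=0.05, seed=34)
        occ = enumerate_occurrences({"c": seq}, 30)
        cands = select_candidates(occ)
        for j in (1, 2):
            assert np.array_equal(
                blocked_near_counts(cands, occ, j), allpairs_near_counts(cands, occ, j)
            )
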