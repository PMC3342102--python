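"""Exact mapping: index contents, strand conventions, naive-scan oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnaprofiler import Reference, build_index, map_exact, map_library
from pirnaprofiler.dna import reverse_complement
from pirnaprofiler.preprocess import TrimmedRead, trim_and_filter


def naive_scan(insert, references):
    """Independent all-offsets, both-strands scan."""
    hits = set()
    rc = reverse_complement(insert)
    n = len(insert)
    for ref in references:
        for s in range(len(ref.sequence) - n + 1):
            window = ref.sequence[s : s + n]
            if window == insert:
                hits.add((ref.id, s, s + n, "+"))
            if window == rc:
                hits.add((ref.id, s, s + n, "-"))
    return hits


def as_set(hits):
    return {(h.reference_id, h.start, h.end, h.strand) for h in hits}


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBuildIndex:
    def test_window_count_single_reference(self, rng):
        ref = Reference("r1", _rand_seq(rng, 100))
        index = build_index([ref], key_length=23)
        assert sum(len(v) for v in index.table.values()) == 100 - 23 + 1

    def test_windows_with_n_skipped(self):
        seq = "ACGT" * 10 + "N" + "ACGT" * 10
        index = build_index([Reference("r", seq)], key_length=23)
        for key in index.table:
            assert "N" not in key

    def test_deterministic_rebuild(self, rng):
        refs = [Reference("a", _rand_seq(rng, 200))]
        i1, i2 = build_index(refs), build_index(refs)
        assert i1.table == i2.table

    def test_membership_matches_substring_extraction(self, rng):
        refs = [Reference(f"r{i}", _rand_seq(rng, 150)) for i in range(3)]
        index = build_index(refs, key_length=23)
        seqs = {r.id: r.sequence for r in refs}
        for key, sites in index.table.items():
            for rid, start in sites:
                assert seqs[rid][start : start + 23] == key

    @pytest.mark.parametrize("k", [0, -1, 31])
    def test_invalid_key_length(self, k):
        with pytest.raises(ValueError):
            build_index([Reference("r", "ACGT" * 20)], key_length=k)


class TestMapExact:
    def test_forward_hit_coordinates(self, rng):
        ref = Reference("r", _rand_seq(rng, 120))
        index = build_index([ref])
        insert = ref.sequence[10:35]
        assert (("r", 10, 35, "+")) in as_set(map_exact(insert, index))

    def test_reverse_hit_coordinates(self, rng):
        ref = Reference("r", _rand_seq(rng, 120))
        index = build_index([ref])
        insert = reverse_complement(ref.sequence[10:35])
        assert (("r", 10, 35, "-")) in as_set(map_exact(insert, index))

    def test_single_substitution_kills_hit(self, rng):
        ref = Reference("r", _rand_seq(rng, 120))
        index = build_index([ref])
        insert = list(ref.sequence[10:35])
        insert[12] = {"A": "C", "C": "G", "G": "T", "T": "A"}[insert[12]]
        assert naive_scan("".join(insert), [ref]) == as_set(map_exact("".join(insert), index))

    def test_insert_with_n_maps_nowhere(self, rng):
        ref = Reference("r", _rand_seq(rng, 120))
        index = build_index([ref])
        assert map_exact("N" + ref.sequence[11:35], index) == []

    @pytest.mark.parametrize("n", [22, 31])
    def test_length_contract(self, n):
        index = build_index([Reference("r", "ACGT" * 30)])
        with pytest.raises(ValueError):
            map_exact("A" * n, index)

    def test_agrees_with_naive_scan_randomized(self, rng):
        # 1,000 random (read, reference) pairs, half with a planted exact site.
        for i in range(1000):
            refs = [Reference(f"r{j}", _rand_seq(rng, 80)) for j in range(2)]
            index = build_index(refs)
            n = int(rng.integers(23, 31))
            if i % 2 == 0:
                ref = refs[int(rng.integers(0, 2))]
                s = int(rng.integers(0, len(ref.sequence) - n + 1))
                insert = ref.sequence[s : s + n]
                if rng.random() < 0.5:
                    insert = reverse_complement(insert)
            else:
                insert = _rand_seq(rng, n)
            assert as_set(map_exact(insert, index)) == naive_scan(insert, refs)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_strand_involution(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=60, max_size=120))
        ref = Reference("r", seq)
        index = build_index(refs := [ref])
        s = data.draw(st.integers(0, len(seq) - 25))
        insert = seq[s : s + 25]
        fwd = as_set(map_exact(insert, index))
        rev = as_set(map_exact(reverse_complement(insert), index))
        flip = {"+": "-", "-": "+"}
        assert rev == {(r, a, b, flip[st_]) for r, a, b, st_ in fwd}


class TestMapLibrary:
    def test_roundtrip_on_error_free_library(self, small_refs, small_indexes, small_library):
        cfg, reads, truth = small_library
        genome_index, te_index = small_indexes
        kept, _ = trim_and_filter(reads, cfg.adapter)
        result = map_library(kept, genome_index, te_index)
        # every non-junk read maps to the genome (copies are embedded verbatim)
        non_junk = {t.read_id for t in truth if t.source != "junk"}
        assert result.genome_mapped_read_ids == non_junk
        # every transposon-derived read recovers its source and strand
        truth_by_id = {t.read_id: t for t in truth}
        te_ids = {m.id for m in small_refs.transposons}
        for rid, hits in result.transposon_hits.items():
            t = truth_by_id[rid]
            if t.source in te_ids:
                assert any(h.reference_id == t.source and h.strand == t.strand for h in hits)

    def test_multi_reference_read_hits_both(self):
        shared = "ACGTTGCAACGGTTAACCGGTTAACAGTC"  # 29 nt
        pad1, pad2 = "GGGG" * 10, "CCCC" * 10
        refs = [Reference("A", pad1 + shared), Reference("B", shared + pad2)]
        index = build_index(refs)
        tr = [TrimmedRead("x", shared, len(shared), 0)]
        result = map_library(tr, build_index([]), index)
        assert {h.reference_id for h in result.transposon_hits["x"]} == {"A", "B"}

    def test_distinct_read_denominator_counts_reads_not_hits(self, rng):
        core = _rand_seq(rng, 25)
        genome = Reference("genome", core + _rand_seq(rng, 50) + core, "genome")
        gi = build_index([genome])
        tr = [TrimmedRead("multi", core, 25, 0)]
        result = map_library(tr, gi, build_index([]))
        assert result.genome_mapped_total == 1

    def test_empty_library(self, small_indexes):
        genome_index, te_index = small_indexes
        result = map_library([], genome_index, te_index)
        assert result.genome_mapped_total == 0
        assert result.transposon_hits == {}
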