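"""Virtual tag extraction, indexing, and mismatch-tolerant queries."""

import numpy as np
import pytest

from dgetag.index import (
    ReferenceUnigene,
    build_tag_index,
    extract_tags_for_sequence,
    query_tag,
    read_index_tsv,
    read_reference_fasta,
    reverse_complement,
    write_index_tsv,
)

from conftest import random_seq, random_tag


def brute_force_query(index, tag_seq, max_mismatch, anchor_strict=True):
    """Independent oracle: Hamming-scan every indexed tag."""
    exact, near = [], []
    for cand in index.tags:
        d = sum(a != b for a, b in zip(tag_seq, cand))
        if d == 0:
            exact.append(cand)
        elif d == 1:
            i = next(i for i in range(21) if tag_seq[i] != cand[i])
            if not anchor_strict or i >= 4:
                near.append(cand)
    if exact:
        return set(exact), "exact"
    if max_mismatch == 1 and near:
        return set(near), "one_mismatch"
    return set(), "none"


class TestExtraction:
    def test_single_site(self):
        seq = "AA" + "CATG" + "T" * 17 + "GGG"
        tags = extract_tags_for_sequence("g1", seq, both_strands=False)
        assert tags == [("CATG" + "T" * 17, "g1", "+", 2)]

    def test_no_site(self):
        assert extract_tags_for_sequence("g1", "A" * 24, both_strands=False) == []

    def test_short_downstream_window_yields_nothing(self):
        assert extract_tags_for_sequence("g1", "CATG" + "A" * 10, both_strands=False) == []

    def test_window_with_N_skipped(self):
        seq = "CATG" + "A" * 8 + "N" + "A" * 8
        assert extract_tags_for_sequence("g1", seq, both_strands=False) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty reference sequence"):
            extract_tags_for_sequence("g1", "", both_strands=False)

    def test_invalid_character_named(self):
        with pytest.raises(ValueError, match="'X'"):
            extract_tags_for_sequence("g1", "CATGX" + "A" * 20, both_strands=False)

    def test_reverse_strand_offset_is_plus_strand_leftmost(self):
        # the only CATG site lives on the - strand
        tag = random_tag(np.random.default_rng(7))
        seq = "TT" + reverse_complement(tag) + "AA"
        tags = extract_tags_for_sequence("g1", seq, both_strands=True)
        assert tags == [(tag, "g1", "-", 2)]

    def test_strand_closure(self, rng):
        """Indexing a sequence or its reverse complement gives the same tag set."""
        for _ in range(10):
            seq = random_seq(rng, 150)
            fwd = {t for t, *_ in extract_tags_for_sequence("g", seq, True)}
            rev = {t for t, *_ in extract_tags_for_sequence("g", reverse_complement(seq), True)}
            assert fwd == rev


class TestBuildIndex:
    def test_shared_tag_records_both_genes(self):
        tag = random_tag(np.random.default_rng(0))
        ref = [ReferenceUnigene("a", "GG" + tag), ReferenceUnigene("b", tag + "TT")]
        index = build_tag_index(ref, both_strands=False)
        assert index.tags[tag].gene_ids == {"a", "b"}

    def test_multiple_sites_one_gene(self, rng):
        tags = [random_tag(rng) for _ in range(3)]
        index = build_tag_index(
            [ReferenceUnigene("g", "".join(tags))], both_strands=False
        )
        assert set(tags) <= set(index.tags)

    def test_empty_reference(self):
        index = build_tag_index([], both_strands=True)
        assert len(index) == 0 and index.reference_size == 0

    def test_duplicate_gene_id_rejected(self):
        ref = [ReferenceUnigene("g", "A" * 30)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_tag_index(ref)

    def test_order_invariance(self, small_reference):
        a = build_tag_index(small_reference)
        b = build_tag_index(small_reference[::-1])
        assert a.tags.keys() == b.tags.keys()
        for t in a.tags:
            assert a.tags[t].occurrences == b.tags[t].occurrences


class TestQuery:
    def test_exact_hit(self, small_index):
        tag = next(iter(small_index.tags))
        rep = query_tag(small_index, tag)
        assert rep.match_tier == "exact"
        assert rep.gene_ids == small_index.tags[tag].gene_ids

    def test_one_mismatch_hit(self, small_index):
        tag = next(iter(small_index.tags))
        mutated = tag[:12] + ("A" if tag[12] != "A" else "C") + tag[13:]
        if mutated in small_index.tags:
            pytest.skip("mutation collided with another indexed tag")
        rep = query_tag(small_index, mutated)
        oracle_genes, oracle_tier = brute_force_query(small_index, mutated, 1)
        assert rep.match_tier == oracle_tier == "one_mismatch"
        assert set().union(
            *(small_index.tags[t].gene_ids for t in rep.matched_tags)
        ) == rep.gene_ids

    def test_anchor_mismatch_not_repaired_when_strict(self, small_index):
        tag = next(iter(small_index.tags))
        broken = "G" + tag[1:]
        assert query_tag(small_index, broken, anchor_strict=True).match_tier == "none"
        relaxed = query_tag(small_index, broken, anchor_strict=False)
        assert relaxed.match_tier == "one_mismatch"
        assert tag in relaxed.matched_tags

    def test_wrong_length_rejected(self, small_index):
        with pytest.raises(ValueError, match="21"):
            query_tag(small_index, "CATG")

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    @pytest.mark.parametrize("anchor_strict", [True, False])
    def test_oracle_equivalence(self, max_mismatch, anchor_strict):
        """Neighborhood lookup agrees tier- and gene-set-wise with a full
        Hamming scan, over random references and random/near-miss queries."""
        rng = np.random.default_rng(99)
        for rep_i in range(5):
            ref = [
                ReferenceUnigene(f"g{i}", random_seq(rng, 40) + random_tag(rng))
                for i in range(30)
            ]
            index = build_tag_index(ref, both_strands=True)
            indexed = list(index.tags)
            queries = []
            for _ in range(100):
                kind = rng.integers(3)
                if kind == 0:
                    queries.append(random_tag(rng))
                else:
                    base = indexed[rng.integers(len(indexed))]
                    n_mut = int(kind)  # 1 or 2 substitutions
                    pos = rng.choice(21, size=n_mut, replace=False)
                    q = list(base)
                    for p in pos:
                        q[p] = "ACGT"[(("ACGT".index(q[p])) + int(rng.integers(1, 4))) % 4]
                    queries.append("".join(q))
            for q in queries:
                rep = query_tag(index, q, max_mismatch, anchor_strict)
                genes, tier = brute_force_query(index, q, max_mismatch, anchor_strict)
                assert rep.match_tier == tier
                assert rep.gene_ids == frozenset().union(
                    *(index.tags[t].gene_ids for t in rep.matched_tags)
                ) if rep.matched_tags else rep.gene_ids == frozenset()
                oracle_gene_union = set()
                for t in genes:
                    oracle_gene_union |= index.tags[t].gene_ids
                assert set(rep.gene_ids) == oracle_gene_union


class TestIO:
    def test_fasta_and_index_roundtrip(self, small_reference, tmp_path):
        fa = tmp_path / "ref.fa"
        with open(fa, "w") as fh:
            for u in small_reference:
                fh.write(f">{u.gene_id} some description\n")
                for i in range(0, len(u.sequence), 60):
                    fh.write(u.sequence[i : i + 60] + "\n")
        loaded = read_reference_fasta(fa)
        assert [(u.gene_id, u.sequence) for u in loaded] == [
            (u.gene_id, u.sequence) for u in small_reference
        ]
        index = build_tag_index(loaded)
        path = tmp_path / "index.tsv"
        write_index_tsv(index, path)
        back = read_index_tsv(path)
        assert back.reference_size == index.reference_size
        assert back.tags.keys() == index.tags.keys()
        for t in index.tags:
            assert back.tags[t].occurrences == index.tags[t].occurrences
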