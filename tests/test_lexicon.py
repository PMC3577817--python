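import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gramprom import (
    CreditStats,
    SequenceRecord,
    build_part_library,
    default_library,
    default_patterns,
    expand_pattern,
    infer_patterns,
    parse_pattern,
    regex_strength,
    tokenize,
)
from gramprom.lexicon import PatternError, RegexPattern, library_to_tsv, random_patterns


def naive_matches(seq, terminals):
    """Oracle: brute-force substring scan for every terminal at every offset."""
    hits = []
    for term in terminals:
        for i in range(len(seq) - len(term) + 1):
            if seq[i : i + len(term)] == term:
                hits.append((i, term))
    return sorted(hits)


class TestExpandPattern:
    def test_tata_has_24_terminals(self):
        seqs = expand_pattern(parse_pattern("TATA", "ta[ta][ta][tag][ta]"))
        assert len(seqs) == 24
        assert "tataaa" in seqs and "tatata" in seqs

    def test_bre_has_8_terminals(self):
        assert len(expand_pattern(parse_pattern("BRE", "[gc][gc][ga]cgcc"))) == 8

    def test_dpe_has_24_terminals(self):
        assert len(expand_pattern(parse_pattern("DPE", "[ag]g[at][ct][cag]"))) == 24

    def test_single_fixed_class(self):
        assert expand_pattern(RegexPattern("TATA", (("a",),))) == ["a"]

    def test_gap_not_enumerable(self):
        with pytest.raises(PatternError):
            expand_pattern(parse_pattern("GAP", "[atcg]+"))

    def test_lexicographic_order(self):
        seqs = expand_pattern(parse_pattern("DPE", "[ga][ta]"))
        assert seqs == ["aa", "at", "ga", "gt"]


@st.composite
def small_patterns(draw):
    n_classes = draw(st.integers(2, 5))
    classes = tuple(
        tuple(
            sorted(
                draw(
                    st.sets(st.sampled_from("acgt"), min_size=1, max_size=4)
                ),
                key="acgt".index,
            )
        )
        for _ in range(n_classes)
    )
    return RegexPattern("TATA", classes)


@settings(max_examples=60, deadline=None)
@given(small_patterns())
def test_expansion_cardinality_uniqueness_rematch(pattern):
    seqs = expand_pattern(pattern)
    expected = 1
    for c in pattern.classes:
        expected *= len(c)
    assert len(seqs) == expected
    assert len(set(seqs)) == len(seqs)
    for s in seqs:
        assert all(b in c for b, c in zip(s, pattern.classes))


class TestPartLibrary:
    def test_default_sizes_and_ids(self, library):
        assert {el: len(lib) for el, lib in library.entries.items()} == {
            "TATA": 24,
            "INR": 288,
            "BRE": 8,
            "DPE": 24,
        }
        tata_ids = [tid for tid, _ in library.terminals("TATA")]
        assert tata_ids[0] == "t1" and tata_ids[-1] == "t24"
        bre_ids = [tid for tid, _ in library.terminals("BRE")]
        assert bre_ids == [f"b{i}" for i in range(1, 9)]

    def test_empty_pattern_set(self):
        lib = build_part_library([])
        assert len(lib) == 0
        assert lib.SPECIAL_IDS == ("c0", "g0")

    def test_duplicate_element_errors(self):
        pat = parse_pattern("TATA", "ta[ta]")
        with pytest.raises(PatternError):
            build_part_library([pat, pat])

    def test_tsv_serialization(self, library, tmp_path):
        p = tmp_path / "lib.tsv"
        library_to_tsv(library, p)
        rows = [l.split("\t") for l in p.read_text().splitlines()]
        assert rows[0][0] == "c0" and rows[1][0] == "g0"
        assert len(rows) == 2 + len(library)


class TestTokenize:
    def test_planted_tata_found_once(self, library):
        seq = "ca" * 20 + "tataaa" + "ca" * 20
        rec = SequenceRecord("x", seq)
        tata = [t for t in tokenize(rec, library) if t.element == "TATA"]
        assert [(t.start, t.length) for t in tata] == [(40, 6)]
        assert seq[40:46] == "tataaa"

    def test_no_elements_in_short_unmatching_seq(self, library):
        assert tokenize(SequenceRecord("x", "cacc"), library) == []

    def test_overlapping_tata_interpretations(self, library):
        # "tatata" (offset 0) and "tataaa" (offset 2) overlap; both are
        # reported as separate interpretations
        rec = SequenceRecord("x", "tatataaa")
        tata = [t for t in tokenize(rec, library) if t.element == "TATA"]
        assert {t.start for t in tata} == {0, 2}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_naive_scan(self, library, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("acgt"), size=2000, p=[0.3, 0.2, 0.2, 0.3]))
        tokens = tokenize(SequenceRecord("x", seq), library)
        for element, pairs in library.entries.items():
            got = sorted(
                (t.start, seq[t.start : t.end]) for t in tokens if t.element == element
            )
            assert got == naive_matches(seq, [s for _, s in pairs])

    def test_sorted_by_start_then_element(self, library):
        rec = SequenceRecord("x", "tataaa" + "g" * 10 + "tataaa")
        tokens = tokenize(rec, library)
        assert tokens == sorted(tokens, key=lambda t: (t.start, t.element))

    def test_token_invariant_sequence_matches(self, library):
        seq = "cc" + "ggacgcc" + "cc"
        for t in tokenize(SequenceRecord("x", seq), library):
            terminal = dict(library.terminals(t.element))[t.terminal_id]
            assert seq[t.start : t.end] == terminal


class TestCreditAssignment:
    @pytest.mark.parametrize(
        "stats,expected",
        [((8, 2, 10), 0.6), ((0, 0, 0), 0.0), ((5, 5, 10), 0.0)],
    )
    def test_strength_examples(self, stats, expected):
        assert regex_strength(CreditStats(*stats)) == pytest.approx(expected)

    def test_discriminating_candidate_wins(self):
        # A matches all positives, no negatives; B matches half of each
        a = parse_pattern("TATA", "tata")
        b = parse_pattern("TATA", "cccc")
        positives = ["aatataa"] * 10
        negatives = ["aacccca"] * 5 + ["aagggga"] * 5
        best, table = infer_patterns([a, b], positives, negatives)
        assert best["TATA"] is a
        stats = dict((str(p), s) for p, s in table["TATA"])
        assert regex_strength(stats["tata"]) == pytest.approx(1.0)
        # B accepts 5 negatives and rejects all 10 positives: mostly wrong
        assert regex_strength(stats["cccc"]) == pytest.approx(-0.5)

    def test_single_candidate_returned(self):
        pat = parse_pattern("TATA", "tata")
        best, _ = infer_patterns([pat], ["atata"], ["cccc"])
        assert best["TATA"] is pat

    def test_every_scan_counts_toward_fr(self):
        pat = parse_pattern("TATA", "tata")
        _, table = infer_patterns([pat], ["tata"] * 3, ["cccc"] * 2)
        (_, stats), = table["TATA"]
        assert stats.fr == 5
        assert stats.u_plus == 5 and stats.u_minus == 0

    def test_permutation_invariance(self):
        cands = [parse_pattern("TATA", p) for p in ("tata", "ta[tg]a")]
        pos = ["ttataa", "atatag", "cccccc"]
        neg = ["gggggg", "ctatga"]
        best1, _ = infer_patterns(cands, pos, neg)
        best2, _ = infer_patterns(cands, pos[::-1], neg[::-1])
        assert str(best1["TATA"]) == str(best2["TATA"])

    def test_all_zero_strengths_warns(self):
        pat = parse_pattern("TATA", "tata")
        with pytest.warns(UserWarning):
            best, _ = infer_patterns(
                [pat], ["tata", "cccc"], ["tata", "cccc"]
            )
        assert best["TATA"] is pat

    def test_empty_inputs_error(self):
        pat = parse_pattern("TATA", "tata")
        with pytest.raises(ValueError):
            infer_patterns([], ["a"], ["c"])
        with pytest.raises(ValueError):
            infer_patterns([pat], [], ["c"])


def test_random_patterns_seeded_and_valid():
    pats = random_patterns("INR", length=7, n=5, seed=42)
    again = random_patterns("INR", length=7, n=5, seed=42)
    assert [str(p) for p in pats] == [str(p) for p in again]
    for p in pats:
        assert len(p.classes) == 7
        assert p.n_expansions >= 1


def test_default_patterns_match_library(library):
    for pat in default_patterns():
        seqs = expand_pattern(pat)
        assert [s for _, s in library.terminals(pat.element)] == seqs
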