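import numpy as np
import pytest

from gramprom import (
    GapConstraint,
    SequenceRecord,
    Token,
    brute_force_accept,
    default_grammar,
    element_templates,
    grammar_from_text,
    has_cpg_island,
    parse,
    tokenize,
)
from gramprom.grammar import Grammar, TerminalClass, derivations_to_jsonl, grammar_to_text


def tok(element, start, length):
    return Token(element, "?", start, length)


class TestDefaultGrammar:
    def test_rule_count_and_ids(self, grammar):
        assert len(grammar.rules) == 19
        assert [r.id for r in grammar.rules] == [f"R{i}" for i in range(1, 20)]

    def test_lhs_symbols_are_nonterminals(self, grammar):
        assert {r.lhs for r in grammar.rules} <= set(grammar.nonterminals)

    def test_r10_structure(self, grammar):
        r10 = next(r for r in grammar.rules if r.id == "R10")
        elements = [s for s in r10.rhs if isinstance(s, str)]
        gaps = [s for s in r10.rhs if isinstance(s, GapConstraint)]
        assert elements == ["B", "T", "I", "D"]
        assert [(g.lo, g.hi) for g in gaps] == [(10, 30), (10, 40), (15, 37)]

    def test_duplicate_rules_kept_verbatim(self, grammar):
        r8 = next(r for r in grammar.rules if r.id == "R8")
        r13 = next(r for r in grammar.rules if r.id == "R13")
        assert r8.rhs == r13.rhs

    def test_text_roundtrip(self, grammar):
        again = grammar_from_text(grammar_to_text(grammar))
        assert [(r.id, r.lhs, r.rhs) for r in again.rules] == [
            (r.id, r.lhs, r.rhs) for r in grammar.rules
        ]


class TestTemplates:
    def test_nineteen_templates(self, grammar):
        templates = element_templates(grammar)
        assert len(templates) == 19
        cpg_only = [t for t in templates if not t.elements]
        assert len(cpg_only) == 1 and cpg_only[0].cpg_required
        with_cpg = [t for t in templates if t.cpg_required and t.elements]
        without = [t for t in templates if not t.cpg_required]
        assert len(with_cpg) == 9 and len(without) == 9

    def test_duplicate_pair_yields_duplicate_templates(self, grammar):
        templates = element_templates(grammar)
        sigs = [t.signature() for t in templates]
        assert len(sigs) - len(set(sigs)) == 2  # R8=R13 via both R3 and R4

    def test_minimal_grammar_single_template(self):
        g = grammar_from_text("R1. S -> G S1 G\nR2. S1 -> C\nR18. G -> g0\nR19. C -> c0")
        templates = element_templates(g)
        assert len(templates) == 1
        assert templates[0].cpg_required and templates[0].elements == ()

    def test_empty_grammar_errors(self):
        with pytest.raises(ValueError):
            element_templates(Grammar([]))

    def test_gap_constraint_validation(self):
        with pytest.raises(ValueError):
            GapConstraint(5, 3)
        with pytest.raises(ValueError):
            GapConstraint(-1, 3)


class TestParse:
    def test_cpg_only_acceptance(self, grammar):
        res = parse([], True, grammar)
        assert res.accepted
        assert res.derivations[0].rule_ids[:3] == ("R1", "R18", "R2")

    def test_no_tokens_no_cpg_rejected(self, grammar):
        assert not parse([], False, grammar).accepted

    def test_tata_inr_gap_inside_range(self, grammar):
        tokens = [tok("TATA", 94, 6), tok("INR", 125, 7)]
        res = parse(tokens, False, grammar)
        assert res.accepted
        assert any("R6" in d.rule_ids for d in res.derivations)
        assert res.inr_position == 125

    def test_lone_inr_accepted_via_r11(self, grammar):
        # R11 (S2 -> I) derives acceptance from a single initiator token
        tokens = [tok("TATA", 94, 6), tok("INR", 240, 7)]
        res = parse(tokens, False, grammar)
        assert res.accepted
        assert all(
            "R11" in d.rule_ids for d in res.derivations
        ), "only the I-only rule should fire at gap 140"

    def test_gap_violation_rejected_without_fallback_rule(self):
        g = grammar_from_text(
            """
            R1. S -> G S1 G
            R4. S1 -> S2
            R6. S2 -> T G(10,40) I
            R14. T -> TATA*
            R15. I -> INR*
            R18. G -> g0
            """
        )
        ok = parse([tok("TATA", 94, 6), tok("INR", 125, 7)], False, g)
        bad = parse([tok("TATA", 94, 6), tok("INR", 241, 7)], False, g)
        assert ok.accepted and not bad.accepted

    @pytest.mark.parametrize("gap,accepted", [(9, False), (10, True), (30, True), (31, False)])
    def test_bre_tata_gap_boundaries(self, grammar, gap, accepted):
        # B/T pairs have no single-element fallback: R7 gap bounds decide
        tokens = [tok("BRE", 50, 7), tok("TATA", 57 + gap, 6)]
        assert parse(tokens, False, grammar).accepted is accepted

    def test_cpg_monotonicity(self, grammar):
        tokens = [tok("TATA", 94, 6), tok("INR", 125, 7)]
        assert parse(tokens, False, grammar).accepted
        assert parse(tokens, True, grammar).accepted

    def test_added_junk_tokens_never_flip_acceptance(self, grammar):
        tokens = [tok("TATA", 94, 6), tok("INR", 125, 7)]
        junk = [tok("DPE", 3, 5), tok("BRE", 300, 7), tok("TATA", 500, 6)]
        res = parse(sorted(tokens + junk, key=lambda t: t.start), False, grammar)
        assert res.accepted

    def test_derivations_validate_and_capped(self, grammar):
        tokens = [tok("INR", 10 * i, 7) for i in range(30)]
        res = parse(tokens, True, grammar, max_derivations=20)
        assert len(res.derivations) == 20
        for d in res.derivations:
            d.validate()

    def test_derivation_gap_arithmetic(self, grammar):
        tokens = [tok("TATA", 94, 6), tok("INR", 125, 7)]
        d = next(
            d for d in parse(tokens, False, grammar).derivations if len(d.tokens) == 2
        )
        assert d.gap_lengths == (25,)

    def test_jsonl_trace(self, grammar):
        res = parse([tok("TATA", 94, 6), tok("INR", 125, 7)], False, grammar)
        lines = derivations_to_jsonl(res.derivations).splitlines()
        assert len(lines) == len(res.derivations)
        import json

        rec = json.loads(lines[0])
        assert set(rec) == {"rules", "tokens", "gaps"}


class TestBruteForceOracle:
    def test_all_a_sequence_rejected(self, library, grammar):
        assert not brute_force_accept(SequenceRecord("x", "a" * 300), library, grammar)

    def test_planted_r10_arrangement_accepted(self, library, grammar):
        seq = list("c" * 300)
        bre = dict(library.terminals("BRE"))["b1"]
        tata = dict(library.terminals("TATA"))["t1"]
        inr = dict(library.terminals("INR"))["i1"]
        dpe = dict(library.terminals("DPE"))["d1"]
        pos = 50
        for term, gap in ((bre, 20), (tata, 30), (inr, 20), (dpe, 0)):
            seq[pos : pos + len(term)] = list(term)
            pos += len(term) + gap
        rec = SequenceRecord("x", "".join(seq))
        assert brute_force_accept(rec, library, grammar)
        cpg = has_cpg_island(rec)
        assert parse(tokenize(rec, library), cpg, grammar).accepted

    @pytest.mark.parametrize("seed", range(12))
    def test_parser_agrees_with_oracle_on_random_sequences(
        self, library, grammar, seed
    ):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("acgt"), size=300, p=[0.3, 0.2, 0.2, 0.3]))
        rec = SequenceRecord("x", seq)
        expected = brute_force_accept(rec, library, grammar)
        got = parse(
            tokenize(rec, library), has_cpg_island(rec), grammar
        ).accepted
        assert got == expected
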