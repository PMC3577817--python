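"""The core-promoter context-free grammar and its parser.

The grammar is the 4-tuple (N, T, S, P): nonterminals
N = {S, S1, S2, T, I, D, B, G, C}, terminals drawn from the part library
(t1.., i1.., d1.., b1.., c0, g0), start symbol S, and production rules
with bounded gaps written ``G(lo,hi)``.  The default rule set couples the
CpG-island flag (C) with arrangements of TATA-box (T), initiator (I),
DPE (D) and BRE (B) separated by gap ranges; a window is accepted when
some ordered, non-overlapping choice of element tokens satisfies one of
the rule templates reachable from S.

Gap measurement convention: the distance between consecutive elements is
``start(next) - end(prev)`` in nt with *end* exclusive, so ``G(10,30)``
means 10 <= distance <= 30.  Flanking gaps from ``S -> G S1 G`` may have
length 0 (an element at the window edge is not rejected on a
technicality).
"""

from __future__ import annotations

import itertools
import re as _re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from . import cpg as _cpg
from .lexicon import PartLibrary, Token, default_library
from .seqio import SequenceRecord

#: nonterminal -> element name for the terminal-transform rules
ELEMENT_NONTERMINALS = {"T": "TATA", "I": "INR", "D": "DPE", "B": "BRE"}
NONTERMINALS = ("S", "S1", "S2", "T", "I", "D", "B", "G", "C")


@dataclass(frozen=True)
class GapConstraint:
    """A bounded or unbounded gap; ``hi=None`` means indefinite length."""

    lo: int = 0
    hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError("gap lower bound must be >= 0")
        if self.hi is not None and self.hi < self.lo:
            raise ValueError("gap upper bound below lower bound")

    def admits(self, length: int) -> bool:
        return length >= self.lo and (self.hi is None or length <= self.hi)

    def __str__(self) -> str:
        return "G(any)" if self.hi is None else f"G({self.lo},{self.hi})"


ANY_GAP = GapConstraint(0, None)


@dataclass(frozen=True)
class TerminalClass:
    """RHS marker: any terminal of *element* from the part library."""

    element: str


Symbol = Union[str, GapConstraint, TerminalClass]


@dataclass(frozen=True)
class ProductionRule:
    id: str
    lhs: str
    rhs: Tuple[Symbol, ...]

    def __post_init__(self) -> None:
        if self.lhs not in NONTERMINALS:
            raise ValueError(f"{self.id}: lhs {self.lhs!r} not a nonterminal")


@dataclass
class Grammar:
    """Context-free grammar with gap constraints over part-library tokens."""

    rules: List[ProductionRule]
    start: str = "S"

    @property
    def nonterminals(self) -> Tuple[str, ...]:
        return NONTERMINALS

    def by_lhs(self, lhs: str) -> List[ProductionRule]:
        return [r for r in self.rules if r.lhs == lhs]


def default_grammar() -> Grammar:
    """The 19 default production rules, duplicates kept verbatim."""
    text = """
    R1. S -> G S1 G
    R2. S1 -> C
    R3. S1 -> C S2
    R4. S1 -> S2
    R5. S2 -> B G(10,30) T G(10,40) I
    R6. S2 -> T G(10,40) I
    R7. S2 -> B G(10,30) T
    R8. S2 -> T G(10,40) I G(15,37) D
    R9. S2 -> I G(15,37) D
    R10. S2 -> B G(10,30) T G(10,40) I G(15,37) D
    R11. S2 -> I
    R12. S2 -> B G(10,50) I
    R13. S2 -> T G(10,40) I G(15,37) D
    R14. T -> TATA*
    R15. I -> INR*
    R16. D -> DPE*
    R17. B -> BRE*
    R18. G -> g0
    R19. C -> c0
    """
    return grammar_from_text(text)


_GAP_RE = _re.compile(r"^G\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)$")
_RULE_RE = _re.compile(r"^(?:(R\d+)\s*\.\s*)?(\w+)\s*->\s*(.+)$")


def grammar_from_text(text: str) -> Grammar:
    """Parse rules in Table-style notation, e.g. ``S2 -> B G(10,30) T``.

    Terminal-transform rules are written ``T -> TATA*`` (any TATA-box
    terminal), ``G -> g0`` and ``C -> c0``.  Rule ids (R1., R2., ...) are
    optional and autonumbered when absent.
    """
    rules: List[ProductionRule] = []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ValueError(f"cannot parse rule line {line!r}")
        rid, lhs, rhs_text = m.groups()
        rid = rid or f"R{len(rules) + 1}"
        # re-join split gap tokens like "G (15,37)"
        rhs_text = _re.sub(r"G\s+\(", "G(", rhs_text)
        symbols: List[Symbol] = []
        for tok in rhs_text.split():
            gm = _GAP_RE.match(tok)
            if gm:
                symbols.append(GapConstraint(int(gm.group(1)), int(gm.group(2))))
            elif tok.endswith("*"):
                element = tok[:-1]
                if element not in ELEMENT_NONTERMINALS.values():
                    raise ValueError(f"unknown element class {tok!r}")
                symbols.append(TerminalClass(element))
            elif tok in ("g0", "c0"):
                symbols.append(TerminalClass("GAP" if tok == "g0" else "CPG"))
            elif tok in NONTERMINALS:
                symbols.append(tok)
            else:
                raise ValueError(f"unknown symbol {tok!r} in {line!r}")
        rules.append(ProductionRule(rid, lhs, tuple(symbols)))
    return Grammar(rules)


def grammar_to_text(grammar: Grammar) -> str:
    lines = []
    for r in grammar.rules:
        parts = []
        for sym in r.rhs:
            if isinstance(sym, GapConstraint):
                parts.append(str(sym) if sym.hi is not None else "G")
            elif isinstance(sym, TerminalClass):
                parts.append(
                    {"GAP": "g0", "CPG": "c0"}.get(sym.element, sym.element + "*")
                )
            else:
                parts.append(sym)
        lines.append(f"{r.id}. {r.lhs} -> {' '.join(parts)}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# template expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    """One fully expanded alternative reachable from the start symbol.

    ``elements`` is the ordered element list; ``gaps[i]`` constrains the
    distance between elements i and i+1.  ``cpg_required`` is True when
    the expansion passed through the CpG nonterminal.
    """

    rule_ids: Tuple[str, ...]
    cpg_required: bool
    elements: Tuple[str, ...]
    gaps: Tuple[GapConstraint, ...]

    def signature(self) -> Tuple:
        return (self.cpg_required, self.elements, self.gaps)


def element_templates(grammar: Grammar) -> List[Template]:
    """Expand the grammar into flat element/gap templates.

    Recursion through nonterminals is depth-first in rule order, so the
    template list follows the printed rule order.  Duplicate rules yield
    duplicate templates here; the parser deduplicates for speed only.
    """
    if not grammar.rules:
        raise ValueError("grammar has no production rules")
    by_lhs: Dict[str, List[ProductionRule]] = {}
    for r in grammar.rules:
        by_lhs.setdefault(r.lhs, []).append(r)

    def expand(symbol: Symbol, stack: Tuple[str, ...]) -> List[Tuple[Tuple[str, ...], int, Tuple]]:
        """-> list of (rule_ids, cpg_count, items); items mix ('E', el) / ('G', gap)."""
        if isinstance(symbol, GapConstraint):
            return [((), 0, (("G", symbol),))]
        if isinstance(symbol, TerminalClass):
            if symbol.element == "GAP":
                return [((), 0, (("G", ANY_GAP),))]
            if symbol.element == "CPG":
                return [((), 1, ())]
            return [((), 0, (("E", symbol.element),))]
        # nonterminal
        if symbol in stack:
            raise ValueError(f"recursive nonterminal {symbol!r} unsupported")
        prods = by_lhs.get(symbol)
        if not prods:
            raise ValueError(f"no production for nonterminal {symbol!r}")
        out = []
        for rule in prods:
            partials = [((rule.id,), 0, ())]
            for sym in rule.rhs:
                nxt = []
                for ids, ncpg, items in partials:
                    for ids2, ncpg2, items2 in expand(sym, stack + (symbol,)):
                        nxt.append((ids + ids2, ncpg + ncpg2, items + items2))
                partials = nxt
            out.extend(partials)
        return out

    templates = []
    for rule_ids, ncpg, items in expand(grammar.start, ()):
        elements: List[str] = []
        gaps: List[GapConstraint] = []
        pending: Optional[GapConstraint] = None
        for kind, val in items:
            if kind == "G":
                if elements:
                    pending = val if pending is None else _compose(pending, val)
                # leading gaps are flanking: always satisfiable, dropped
            else:
                if elements:
                    gaps.append(pending if pending is not None else GapConstraint(0, 0))
                elements.append(val)
                pending = None
        # trailing pending gap is flanking: dropped
        templates.append(
            Template(rule_ids, ncpg > 0, tuple(elements), tuple(gaps))
        )
    return templates


def _compose(a: GapConstraint, b: GapConstraint) -> GapConstraint:
    hi = None if (a.hi is None or b.hi is None) else a.hi + b.hi
    return GapConstraint(a.lo + b.lo, hi)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Derivation:
    """An accepting assignment of tokens to one template."""

    rule_ids: Tuple[str, ...]
    tokens: Tuple[Token, ...]
    gap_lengths: Tuple[int, ...]

    def validate(self, template: Optional[Template] = None) -> None:
        """Recheck ordering, non-overlap and gap arithmetic."""
        for prev, nxt, gap in zip(self.tokens, self.tokens[1:], self.gap_lengths):
            if nxt.start - prev.end != gap:
                raise AssertionError("gap length mismatch")
            if gap < 0:
                raise AssertionError("overlapping tokens")
        if template is not None:
            if tuple(t.element for t in self.tokens) != template.elements:
                raise AssertionError("element order mismatch")
            for gap, constraint in zip(self.gap_lengths, template.gaps):
                if not constraint.admits(gap):
                    raise AssertionError("gap outside constraint")


@dataclass
class ParseResult:
    accepted: bool
    derivations: List[Derivation] = field(default_factory=list)
    inr_position: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.accepted == bool(self.derivations)


def parse(
    tokens: Sequence[Token],
    cpg_present: bool,
    grammar: Grammar,
    max_derivations: int = 100,
) -> ParseResult:
    """Decide derivability of a tokenized window from the start symbol.

    Accepts iff some template is satisfiable: its CpG requirement matches
    the c0 flag and an ordered non-overlapping token choice exists with
    every inter-element distance inside its gap constraint.  Derivations
    are collected in template order, tokens left to right, up to
    *max_derivations*; the first is the "best".  ``inr_position`` is the
    start of the initiator token of the highest-priority derivation that
    contains one (the grammar's TSS hint).
    """
    by_element: Dict[str, List[Token]] = {}
    for t in tokens:
        by_element.setdefault(t.element, []).append(t)
    for lst in by_element.values():
        lst.sort(key=lambda t: t.start)

    derivations: List[Derivation] = []
    seen_signatures = set()
    for template in element_templates(grammar):
        sig = template.signature()
        if sig in seen_signatures:
            continue  # duplicate rule (e.g. R8/R13): performance only
        seen_signatures.add(sig)
        if template.cpg_required and not cpg_present:
            continue
        if not template.elements:
            if template.cpg_required:  # CpG-only acceptance (R2 route)
                derivations.append(Derivation(template.rule_ids, (), ()))
            continue
        _assign(template, by_element, derivations, max_derivations)
        if len(derivations) >= max_derivations:
            break

    inr_pos = None
    for d in derivations:
        inr = next((t for t in d.tokens if t.element == "INR"), None)
        if inr is not None:
            inr_pos = inr.start
            break
    return ParseResult(bool(derivations), derivations, inr_pos)


def _assign(
    template: Template,
    by_element: Dict[str, List[Token]],
    out: List[Derivation],
    cap: int,
) -> None:
    """Backtracking search for token assignments satisfying *template*."""
    pools = [by_element.get(el, []) for el in template.elements]
    if any(not p for p in pools):
        return

    chosen: List[Token] = []

    def rec(i: int) -> None:
        if len(out) >= cap:
            return
        if i == len(template.elements):
            gaps = tuple(
                n.start - p.end for p, n in zip(chosen, chosen[1:])
            )
            out.append(Derivation(template.rule_ids, tuple(chosen), gaps))
            return
        for tok in pools[i]:
            if chosen:
                dist = tok.start - chosen[-1].end
                constraint = template.gaps[i - 1]
                if dist < constraint.lo:
                    continue
                if constraint.hi is not None and dist > constraint.hi:
                    # pools are start-sorted: later tokens only farther
                    break
            chosen.append(tok)
            rec(i + 1)
            chosen.pop()
            if len(out) >= cap:
                return

    rec(0)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_accept(
    record: SequenceRecord,
    library: PartLibrary,
    grammar: Grammar,
    cpg_params: Optional[_cpg.CpGParams] = None,
) -> bool:
    """Exhaustive acceptance check, independent of the parser's search.

    Element matches are found with Python's regex engine (overlapping via
    lookahead) from the library's bracket patterns, and token assignments
    are enumerated as full Cartesian products per template.  Intended as
    a test oracle on short sequences.
    """
    cpg_present = _cpg.has_cpg_island(record, cpg_params or _cpg.CpGParams())
    positions: Dict[str, List[Tuple[int, int]]] = {}
    for element, pat in library.patterns.items():
        regex = _re.compile(
            "(?=(" + "".join("[" + "".join(c) + "]" for c in pat.classes) + "))"
        )
        length = len(pat.classes)
        positions[element] = [
            (m.start(), m.start() + length) for m in regex.finditer(record.seq)
        ]
    for template in element_templates(grammar):
        if template.cpg_required and not cpg_present:
            continue
        if not template.elements:
            if template.cpg_required:
                return True
            continue
        pools = [positions.get(el, []) for el in template.elements]
        if any(not p for p in pools):
            continue
        for combo in itertools.product(*pools):
            ok = True
            for (s0, e0), (s1, e1), gap in zip(combo, combo[1:], template.gaps):
                if not gap.admits(s1 - e0):
                    ok = False
                    break
            if ok:
                return True
    return False


def derivations_to_jsonl(derivations: Iterable[Derivation]) -> str:
    """JSON-lines trace of derivations (rule ids + token coordinates)."""
    import json

    lines = []
    for d in derivations:
        lines.append(
            json.dumps(
                {
                    "rules": list(d.rule_ids),
                    "tokens": [
                        [t.element, t.terminal_id, t.start, t.end]
                        for t in d.tokens
                    ],
                    "gaps": list(d.gap_lengths),
                }
            )
        )
    return "\n".join(lines)
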