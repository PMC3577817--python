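"""The part library: core-promoter element motifs as enumerable patterns.

Each element (TATA-box, initiator, BRE, DPE) is described by an ordered
list of character classes over {a,c,g,t} written in bracket notation,
e.g. ``ta[ta][ta][tag][ta]`` for the TATA-box.  Expanding the Cartesian
product of the classes yields the concrete terminal sequences of the
grammar; each terminal gets a unique identifier (t1.., i1.., d1.., b1..).
The special identifiers c0 (CpG-island presence) and g0 (gap) carry no
sequence.  A credit-assignment scorer for choosing among candidate
patterns from positive/negative training sequences is included.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .seqio import SequenceRecord

ELEMENTS = ("TATA", "INR", "BRE", "DPE")
GAP_ELEMENT = "GAP"
#: identifier prefix per element in the part library
ID_PREFIX = {"TATA": "t", "INR": "i", "DPE": "d", "BRE": "b"}
_ORDER = "acgt"  # lexicographic base order


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class RegexPattern:
    """An element motif as an ordered list of character classes.

    The gap element uses the special non-enumerable pattern ``[atcg]+``.
    """

    element: str
    classes: Tuple[Tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS + (GAP_ELEMENT,):
            raise PatternError(f"unknown element {self.element!r}")
        if self.element != GAP_ELEMENT:
            if not self.classes:
                raise PatternError("pattern needs at least one class")
            for cls in self.classes:
                if not cls or not set(cls) <= set(_ORDER):
                    raise PatternError(f"invalid character class {cls!r}")

    @property
    def n_expansions(self) -> int:
        if self.element == GAP_ELEMENT:
            raise PatternError("gap pattern is not enumerable")
        return int(np.prod([len(c) for c in self.classes]))

    def __str__(self) -> str:
        if self.element == GAP_ELEMENT:
            return "[atcg]+"
        return "".join(
            c[0] if len(c) == 1 else "[" + "".join(c) + "]" for c in self.classes
        )


def parse_pattern(element: str, text: str) -> RegexPattern:
    """Parse bracket notation, e.g. ``[gc][gc][ga]cgcc``."""
    if element == GAP_ELEMENT:
        return RegexPattern(GAP_ELEMENT, ())
    classes: List[Tuple[str, ...]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' in {text!r}")
            body = text[i + 1 : j]
            if not body:
                raise PatternError(f"empty class in {text!r}")
            classes.append(tuple(sorted(set(body), key=_ORDER.index)))
            i = j + 1
        elif ch in _ORDER:
            classes.append((ch,))
            i += 1
        else:
            raise PatternError(f"unexpected character {ch!r} in {text!r}")
    return RegexPattern(element, tuple(classes))


#: the default element patterns of the part library
DEFAULT_PATTERNS: Dict[str, str] = {
    "TATA": "ta[ta][ta][tag][ta]",
    "INR": "[ctg][ctg]a[atgc][at][ct][ct]",
    "BRE": "[gc][gc][ga]cgcc",
    "DPE": "[ag]g[at][ct][cag]",
}


def default_patterns() -> List[RegexPattern]:
    return [parse_pattern(el, txt) for el, txt in DEFAULT_PATTERNS.items()]


def expand_pattern(pattern: RegexPattern) -> List[str]:
    """All terminal sequences of *pattern*, in lexicographic order (a<c<g<t).

    The count equals the product of the class sizes; the gap pattern is
    not enumerable and raises.
    """
    if pattern.element == GAP_ELEMENT:
        raise PatternError("gap pattern is not enumerable")
    classes = [sorted(c, key=_ORDER.index) for c in pattern.classes]
    return ["".join(parts) for parts in itertools.product(*classes)]


@dataclass
class PartLibrary:
    """Expanded terminal sequences per element, each with a unique id.

    ``c0`` (CpG presence) and ``g0`` (gap) are always present as special
    identifiers without sequences.
    """

    patterns: Dict[str, RegexPattern] = field(default_factory=dict)
    entries: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    SPECIAL_IDS = ("c0", "g0")

    def terminals(self, element: str) -> List[Tuple[str, str]]:
        """(id, sequence) pairs for *element*, in expansion order."""
        return self.entries.get(element, [])

    def id_of(self, element: str, seq: str) -> str:
        for tid, s in self.entries[element]:
            if s == seq:
                return tid
        raise KeyError(f"{seq!r} is not a {element} terminal")

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_part_library(patterns: Iterable[RegexPattern]) -> PartLibrary:
    """Expand *patterns* into a part library with per-element id prefixes."""
    lib = PartLibrary()
    for pat in patterns:
        if pat.element == GAP_ELEMENT:
            continue
        if pat.element in lib.patterns:
            raise PatternError(f"duplicate element {pat.element}")
        prefix = ID_PREFIX[pat.element]
        seqs = expand_pattern(pat)
        lib.patterns[pat.element] = pat
        lib.entries[pat.element] = [
            (f"{prefix}{i}", s) for i, s in enumerate(seqs, start=1)
        ]
    return lib


def default_library() -> PartLibrary:
    return build_part_library(default_patterns())


@dataclass(frozen=True)
class Token:
    """A positioned match of a part-library terminal in a sequence."""

    element: str
    terminal_id: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """Exclusive end coordinate."""
        return self.start + self.length


def tokenize(record: SequenceRecord, library: PartLibrary) -> List[Token]:
    """All element matches at all offsets (exhaustive, overlaps allowed).

    Every occurrence of every terminal sequence is reported as a separate
    interpretation; the parser later decides which tokens belong to a
    derivation.  Sorted by (start, element).
    """
    seq = record.seq
    out: List[Token] = []
    for element, pairs in library.entries.items():
        if not pairs:
            continue
        length = len(pairs[0][1])
        by_seq = {s: tid for tid, s in pairs}
        for start in range(len(seq) - length + 1):
            tid = by_seq.get(seq[start : start + length])
            if tid is not None:
                out.append(Token(element, tid, start, length))
    out.sort(key=lambda t: (t.start, t.element))
    return out


# ---------------------------------------------------------------------------
# credit assignment for pattern inference
# ---------------------------------------------------------------------------

@dataclass
class CreditStats:
    """Recognition tallies for one candidate pattern.

    u_plus counts correct recognitions (pattern matches a positive
    training sequence, or fails to match a negative one); u_minus counts
    the converse; fr counts every scan of a training sequence.
    """

    u_plus: int = 0
    u_minus: int = 0
    fr: int = 0


def regex_strength(stats: CreditStats) -> float:
    """Strength score (u+ - u-)/fr; 0 when the pattern was never used."""
    if stats.fr == 0:
        return 0.0
    return (stats.u_plus - stats.u_minus) / stats.fr


def _matches_anywhere(pattern: RegexPattern, seq: str) -> bool:
    terminals = set(expand_pattern(pattern))
    length = len(pattern.classes)
    return any(
        seq[i : i + length] in terminals for i in range(len(seq) - length + 1)
    )


def infer_patterns(
    candidate_patterns: Sequence[RegexPattern],
    positives: Sequence[str],
    negatives: Sequence[str],
) -> Tuple[Dict[str, RegexPattern], Dict[str, List[Tuple[RegexPattern, CreditStats]]]]:
    """Choose the strongest candidate pattern per element.

    Every candidate is scanned against every positive and negative
    sequence (once per sequence, regardless of match multiplicity).
    Matching a positive or rejecting a negative is a correct recognition;
    the converse is incorrect.  The highest-strength candidate wins; ties
    break toward fewer expansions, then the lexicographically smaller
    pattern string.  If all strengths are zero the first candidate is
    returned with a warning.
    """
    if not candidate_patterns:
        raise ValueError("candidate set must be nonempty")
    if not positives or not negatives:
        raise ValueError("positive and negative sets must be nonempty")
    by_element: Dict[str, List[RegexPattern]] = {}
    for pat in candidate_patterns:
        by_element.setdefault(pat.element, []).append(pat)

    best: Dict[str, RegexPattern] = {}
    table: Dict[str, List[Tuple[RegexPattern, CreditStats]]] = {}
    for element, cands in by_element.items():
        scored = []
        for pat in cands:
            stats = CreditStats()
            for seq in positives:
                stats.fr += 1
                if _matches_anywhere(pat, seq.lower()):
                    stats.u_plus += 1
                else:
                    stats.u_minus += 1
            for seq in negatives:
                stats.fr += 1
                if _matches_anywhere(pat, seq.lower()):
                    stats.u_minus += 1
                else:
                    stats.u_plus += 1
            scored.append((pat, stats))
        table[element] = scored
        strengths = [regex_strength(s) for _, s in scored]
        if max(strengths) <= 0 and min(strengths) >= 0:
            warnings.warn(
                f"{element}: all candidate strengths are zero; "
                "returning the first candidate"
            )
            best[element] = scored[0][0]
        else:
            best[element] = max(
                scored,
                key=lambda ps: (
                    regex_strength(ps[1]),
                    -ps[0].n_expansions,
                    _neg_str_key(str(ps[0])),
                ),
            )[0]
    return best, table


class _neg_str_key(str):
    """Inverts string comparison so max() prefers the smaller string."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def random_patterns(
    element: str,
    length: int,
    n: int,
    seed: int,
    class_size_probs: Sequence[float] = (0.55, 0.25, 0.15, 0.05),
) -> List[RegexPattern]:
    """Seeded random candidate patterns for credit-assignment inference.

    Each position draws a class size from *class_size_probs* (sizes 1..4)
    and samples that many distinct bases.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        classes = []
        for _ in range(length):
            size = int(rng.choice(4, p=class_size_probs)) + 1
            bases = rng.choice(list(_ORDER), size=size, replace=False)
            classes.append(tuple(sorted(bases, key=_ORDER.index)))
        out.append(RegexPattern(element, tuple(classes)))
    return out


def library_to_tsv(library: PartLibrary, path: str | Path) -> None:
    """Serialize as TSV (id, element, sequence); c0/g0 rows carry '.'."""
    with open(path, "w") as fh:
        fh.write("c0\tCPG\t.\n")
        fh.write("g0\tGAP\t.\n")
        for element, pairs in library.entries.items():
            for tid, seq in pairs:
                fh.write(f"{tid}\t{element}\t{seq}\n")
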