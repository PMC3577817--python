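"""Seeded synthetic fixtures exercising every pipeline stage.

Promoter windows are built constructively: i.i.d. background at a stated
G+C fraction, grammar-consistent element terminals inserted at
gap-consistent offsets, an optional CpG-island segment (>= 200 nt,
GC ~ 0.65, o/e ~ 1), and a structural extremum planted by substituting a
run of scale-extreme words around the TSS so the signal survives the
real profile computation path.  Backgrounds are i.i.d. (no higher-order
Markov structure): the method reads only motif matches, CpG statistics
and k-mer scale sums, so first-order composition is the operative
feature of real data being emulated.

All generators are seed-deterministic: identical spec + seed gives
identical bytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cpg import CpGParams, has_cpg_island
from .grammar import (
    Grammar,
    Template,
    brute_force_accept,
    default_grammar,
    element_templates,
    parse,
)
from .lexicon import PartLibrary, default_library, tokenize
from .predictor import PredictorParams, classify_window
from .seqio import SequenceRecord, TssAnnotation
from .structure import (
    SMOOTH_WINDOW,
    PropertyScale,
    builtin_scale,
    detect_extremum,
    structural_profile,
)

_BASES = np.array(list("acgt"))


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic promoter window.

    ``template`` names the S2-level rule of the arrangement ("R2" for the
    CpG-only route).  ``amplitude`` is the targeted extremum displacement
    in detector spread units; it saturates at what the scale's extreme
    words can express.  The TSS sits at ``tss_offset`` within the window
    (the -1000..+200 convention for 1201 nt windows).
    """

    template: str = "R6"
    gap_lengths: Optional[Tuple[int, ...]] = None  # random valid when None
    terminal_choice: str = "random"                # or "first"
    cpg_island: Optional[Tuple[int, int]] = None   # window-relative span
    property: str = "base_stacking"
    amplitude: float = 8.0        # spread units; 0 plants nothing
    extremum_offset: int = 0      # run center relative to the TSS
    extremum_width: int = 200     # nt; the promoter structural anomaly
                                  # spans a few hundred bp around the TSS
    background_gc: float = 0.4
    window: int = 1201
    tss_offset: int = 1000
    seed: int = 0


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    if length <= 0:
        raise ValueError("length must be positive")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _island_segment(rng: np.random.Generator, length: int, gc: float = 0.65) -> np.ndarray:
    return _background(rng, length, gc)


def _find_template(grammar: Grammar, rule_id: str, want_cpg: bool) -> Template:
    candidates = [
        t for t in element_templates(grammar) if rule_id in t.rule_ids
    ]
    if not candidates:
        raise ValueError(f"no template uses rule {rule_id!r}")
    for t in candidates:
        if t.cpg_required == want_cpg:
            return t
    return candidates[0]


def _extreme_run(scale: PropertyScale, width: int) -> Tuple[str, float]:
    """Greedy walk through scale words toward the extreme direction.

    Returns the run sequence and its mean word value.
    """
    sign = 1.0 if scale.direction == "peak" else -1.0
    best_word = max(scale.values, key=lambda w: sign * scale.values[w])
    seq = best_word
    while len(seq) < width:
        prefix = seq[-(scale.k - 1) :]
        nxt = max(
            "acgt", key=lambda b: sign * scale.values[prefix + b]
        )
        seq += nxt
    words = [seq[i : i + scale.k] for i in range(len(seq) - scale.k + 1)]
    return seq[:width], float(np.mean([scale.values[w] for w in words]))


def _detector_stats(seq: str, scale: PropertyScale, anchor: int, halfwidth: int = 500):
    """Baseline and spread as the detector would measure them."""
    prof = structural_profile(SequenceRecord("bg", seq), scale)
    sm = prof.smoothed
    lo, hi = max(0, anchor - halfwidth), min(len(sm), anchor + halfwidth)
    outside = np.concatenate([sm[:lo], sm[hi:]])
    if outside.size == 0:
        outside = sm
    baseline = float(np.median(outside))
    spread = max(float(np.median(np.abs(outside - baseline))) * 1.4826, 1e-9)
    return baseline, spread


def make_promoter_window(
    spec: PlantSpec,
    library: Optional[PartLibrary] = None,
    grammar: Optional[Grammar] = None,
    scale: Optional[PropertyScale] = None,
    cpg_params: CpGParams = CpGParams(),
    max_attempts: int = 20,
) -> Tuple[SequenceRecord, int, Dict]:
    """Build one promoter window; returns (record, tss, annotations).

    The window is re-verified post hoc: the parser must accept it and a
    requested CpG island must be detectable; failing drafts are
    regenerated from derived seeds (still deterministic in spec.seed).
    Raises when the element arrangement cannot fit the window.
    """
    library = library or default_library()
    grammar = grammar or default_grammar()
    scale = scale or builtin_scale(spec.property)
    want_cpg = spec.cpg_island is not None or spec.template == "R2"
    template = _find_template(grammar, spec.template, want_cpg)

    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, attempt])
        )
        arr = _background(rng, spec.window, spec.background_gc)

        island_span = spec.cpg_island
        if island_span is None and template.cpg_required:
            island_span = (
                max(0, spec.tss_offset - 200),
                min(spec.window, spec.tss_offset + 200),
            )
        if island_span is not None:
            lo, hi = island_span
            if hi - lo < cpg_params.min_len:
                raise ValueError("island span shorter than min_len")
            arr[lo:hi] = _island_segment(rng, hi - lo)

        run_span = None
        if spec.amplitude > 0:
            run_seq, v_run = _extreme_run(scale, spec.extremum_width)
            baseline, spread = _detector_stats(
                "".join(arr), scale, spec.tss_offset
            )
            target = spec.amplitude * spread
            frac = min(1.0, target / max(abs(v_run - baseline), 1e-9))
            run_len = int(round(frac * spec.extremum_width))
            if run_len >= scale.k:
                center = spec.tss_offset + spec.extremum_offset
                lo = max(0, center - run_len // 2)
                hi = min(spec.window, lo + run_len)
                arr[lo:hi] = list(run_seq[: hi - lo])
                run_span = (lo, hi)

        placements = _place_elements(template, library, spec, rng)
        for element, start, terminal in placements:
            arr[start : start + len(terminal)] = list(terminal)

        seq = "".join(arr)
        record = SequenceRecord(f"promoter_{spec.template}_s{spec.seed}", seq)
        cpg_flag = has_cpg_island(record, cpg_params)
        if island_span is not None and not cpg_flag:
            continue  # island drowned by composition noise; redraw
        result = parse(tokenize(record, library), cpg_flag, grammar)
        if not result.accepted:
            continue
        annotations = {
            "template": spec.template,
            "tss": spec.tss_offset,
            "elements": [
                (el, start, start + len(term))
                for el, start, term in placements
            ],
            "cpg_island": island_span,
            "extremum_run": run_span,
            "attempt": attempt,
        }
        return record, spec.tss_offset, annotations
    raise RuntimeError(
        f"could not realize spec {spec.template} seed {spec.seed} in "
        f"{max_attempts} attempts"
    )


def _place_elements(
    template: Template,
    library: PartLibrary,
    spec: PlantSpec,
    rng: np.random.Generator,
) -> List[Tuple[str, int, str]]:
    """Choose terminals and gap-consistent offsets for a template.

    The initiator is anchored at the TSS (it spans +1); without an
    initiator the arrangement's last element ends at the TSS.
    """
    if not template.elements:
        return []
    terminals = []
    for el in template.elements:
        pairs = library.terminals(el)
        if not pairs:
            raise ValueError(f"part library has no terminals for {el}")
        idx = 0 if spec.terminal_choice == "first" else int(rng.integers(len(pairs)))
        terminals.append(pairs[idx][1])
    if spec.gap_lengths is not None:
        gaps = list(spec.gap_lengths)
        if len(gaps) != len(template.gaps):
            raise ValueError("gap_lengths count mismatch")
        for g, c in zip(gaps, template.gaps):
            if not c.admits(g):
                raise ValueError(f"gap {g} violates {c}")
    else:
        gaps = [
            int(rng.integers(c.lo, (c.hi if c.hi is not None else c.lo + 20) + 1))
            for c in template.gaps
        ]
    # relative starts, element 0 at 0
    rel = [0]
    for term, gap in zip(terminals, gaps):
        rel.append(rel[-1] + len(term) + gap)
    if "INR" in template.elements:
        shift = spec.tss_offset - rel[template.elements.index("INR")]
    else:
        shift = spec.tss_offset - (rel[-1] + len(terminals[-1]))
    starts = [r + shift for r in rel]
    if starts[0] < 0 or starts[-1] + len(terminals[-1]) > spec.window:
        raise ValueError("element arrangement does not fit the window")
    return list(zip(template.elements, starts, terminals))


def make_nonpromoter_window(
    gc: float,
    length: int,
    seed: int,
    mode: str = "composite",
    library: Optional[PartLibrary] = None,
    grammar: Optional[Grammar] = None,
    scale: Optional[PropertyScale] = None,
    params: PredictorParams = PredictorParams(),
    cpg_params: CpGParams = CpGParams(),
    max_attempts: int = 50,
) -> SequenceRecord:
    """An i.i.d. background window guaranteed (or not) to be negative.

    mode='raw' draws one background with no rejection (for measuring
    false-positive rates).  mode='composite' resamples until the full
    classifier calls the window non-promoter and no CpG island is
    present.  mode='parse' additionally requires grammar rejection; with
    the exhaustive tokenizer a single initiator match anywhere accepts a
    window, so parse-purity is only attainable for short sequences and
    this mode is intended for parser-test fixtures.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    library = library or default_library()
    grammar = grammar or default_grammar()
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        record = SequenceRecord(
            f"nonpromoter_s{seed}", "".join(_background(rng, length, gc))
        )
        if mode == "raw":
            return record
        if has_cpg_island(record, cpg_params):
            continue
        if mode == "parse":
            if parse(tokenize(record, library), False, grammar).accepted:
                continue
            return record
        if mode == "composite":
            sc = scale or builtin_scale(params.property)
            if length >= params.min_unmasked:
                call = classify_window(
                    record, library, grammar, sc, params, cpg_params
                )
                if call.label != "non_promoter":
                    continue
            return record
        raise ValueError(f"unknown mode {mode!r}")
    raise RuntimeError(
        f"no {mode}-pure negative of length {length} found in "
        f"{max_attempts} attempts (try mode='raw')"
    )


def make_chromosome(
    n_promoters: int,
    spacing: int = 5000,
    seed: int = 0,
    templates: Sequence[str] = ("R2", "R5", "R6", "R10"),
    amplitude: float = 8.0,
    background_gc: float = 0.4,
    window: int = 1201,
    tss_offset: int = 1000,
    property: str = "base_stacking",
    margin: int = 1000,
    chrom_id: str = "synth_chr",
) -> Tuple[SequenceRecord, List[TssAnnotation]]:
    """A background chromosome with promoter windows planted at intervals.

    Templates cycle through *templates*; promoter i starts at
    ``margin + i * spacing``.  Returns the chromosome and its truth TSS
    annotations.  ``n_promoters=0`` gives pure background of one spacing
    plus margins.
    """
    if n_promoters < 0:
        raise ValueError("n_promoters must be >= 0")
    if spacing < window:
        raise ValueError("spacing must be at least the window width")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    length = 2 * margin + max(n_promoters, 1) * spacing
    arr = _background(rng, length, background_gc)
    truth: List[TssAnnotation] = []
    for i in range(n_promoters):
        spec = PlantSpec(
            template=templates[i % len(templates)],
            property=property,
            amplitude=amplitude,
            background_gc=background_gc,
            window=window,
            tss_offset=tss_offset,
            seed=int(
                np.random.default_rng(
                    np.random.SeedSequence([seed, 1 + i])
                ).integers(2**31)
            ),
        )
        record, tss, _ = make_promoter_window(spec)
        offset = margin + i * spacing
        arr[offset : offset + window] = list(record.seq)
        truth.append(TssAnnotation(chrom_id, offset + tss, "+"))
    return SequenceRecord(chrom_id, "".join(arr)), truth


def make_trainset(
    n_pos: int = 20,
    n_neg: int = 20,
    length: int = 151,
    seed: int = 0,
    element: str = "TATA",
    library: Optional[PartLibrary] = None,
    gc: float = 0.4,
) -> Tuple[List[str], List[str]]:
    """Positive/negative sequence sets for credit-assignment inference.

    Positives carry one planted terminal of *element* at a random
    offset; negatives are plain background.
    """
    library = library or default_library()
    pairs = library.terminals(element)
    rng = np.random.default_rng(seed)
    positives = []
    for _ in range(n_pos):
        arr = _background(rng, length, gc)
        term = pairs[int(rng.integers(len(pairs)))][1]
        start = int(rng.integers(length - len(term) + 1))
        arr[start : start + len(term)] = list(term)
        positives.append("".join(arr))
    negatives = ["".join(_background(rng, length, gc)) for _ in range(n_neg)]
    return positives, negatives
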