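"""Composite promoter classification, chromosome scanning, TSS clustering.

A window is classified by running the whole pipeline: CpG-island flag,
exhaustive tokenization, grammar parse, structural profile, peak/cleft
detection.  The structural check is two-tiered: a window the grammar
accepts only needs the laxer structural magnitude
(``threshold_grammar_backed``), while a grammar-rejected window must
show a stronger extremum (``threshold_structure_only``) — not every
promoter carries the sequence signatures, and the structural profile
recovers those.  Setting both tiers equal recovers a purely structural
decision for both branches.

The structural extremum locates the putative TSS; when the grammar
accepts the window, the estimate snaps to the nearest derivable
initiator token (the initiator spans +1), since with exhaustive
tokenization incidental element pairs make any single derivation's
initiator an unreliable anchor on its own.  Genome scanning cuts
1201 nt windows at 200 nt steps; promoter calls within
``cluster_radius`` merge by single linkage and report the mean member
position.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .cpg import CpGParams, has_cpg_island
from .grammar import Grammar, parse
from .lexicon import PartLibrary, tokenize
from .seqio import SequenceRecord, max_n_run, reverse_complement, windows
from .structure import PropertyScale, detect_extremum, structural_profile


@dataclass(frozen=True)
class PredictorParams:
    window: int = 1201                    # nt per scanned window
    step: int = 200                       # nt between window starts
    property: str = "base_stacking"       # structural scale name
    threshold_grammar_backed: float = 2.5  # z, grammar-accepted tier
    threshold_structure_only: float = 3.5  # z, grammar-rejected tier
    cluster_radius: int = 1000            # nt, single-linkage merge gap
    center_halfwidth: int = 500           # nt around the anchor searched
    feature_width: int = 50               # nt, extremum averaging width
    n_run_limit: int = 50                 # skip windows with longer n-runs
    min_unmasked: int = 50                # minimum n-free length
    max_derivations: int = 100
    inr_snap_dist: int = 100              # nt, extremum-to-initiator snap

    def __post_init__(self) -> None:
        if self.threshold_grammar_backed <= 0 or self.threshold_structure_only <= 0:
            raise ValueError("thresholds must be positive")
        if self.threshold_structure_only < self.threshold_grammar_backed:
            raise ValueError(
                "structure-only tier must be at least as strict as the "
                "grammar-backed tier"
            )


@dataclass(frozen=True)
class Evidence:
    grammar_accepted: bool = False
    cpg: bool = False
    structural_pass: bool = False
    magnitude: float = 0.0
    kind: str = "cleft"
    rules: Tuple[str, ...] = ()
    masked: bool = False

    def describe(self) -> str:
        flags = []
        if self.grammar_accepted:
            flags.append("grammar")
        if self.cpg:
            flags.append("cpg")
        if self.structural_pass:
            flags.append(f"struct{self.magnitude:+.1f}")
        if self.masked:
            flags.append("masked")
        return ",".join(flags) or "none"


@dataclass(frozen=True)
class PredictionCall:
    seq_id: str
    window_origin: int              # absolute window start
    window_len: int
    label: str                      # 'promoter' | 'non_promoter'
    tss_estimate: Optional[int]     # absolute position
    evidence: Evidence
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.label == "promoter":
            assert self.tss_estimate is not None
            assert self.evidence.structural_pass


def _largest_n_free_segment(seq: str) -> Tuple[int, str]:
    """(offset, subsequence) of the longest n-free stretch."""
    best = (0, "")
    for m in re.finditer(r"[acgt]+", seq):
        if len(m.group()) > len(best[1]):
            best = (m.start(), m.group())
    return best


def _tier_threshold(accepted: bool, params: PredictorParams) -> float:
    return (
        params.threshold_grammar_backed
        if accepted
        else params.threshold_structure_only
    )


def classify_window(
    record: SequenceRecord,
    library: PartLibrary,
    grammar: Grammar,
    scale: PropertyScale,
    params: PredictorParams = PredictorParams(),
    cpg_params: CpGParams = CpGParams(),
) -> PredictionCall:
    """Run the composite pipeline on one window.

    The extremum search is centered on the window midpoint and spans
    ``center_halfwidth`` either side.  If the grammar accepts and an
    initiator token lies within ``inr_snap_dist`` of the extremum, the
    TSS estimate snaps to that initiator; otherwise it is the extremum
    position.  Windows that are all-n (or whose largest n-free stretch
    is shorter than ``min_unmasked``) come back masked and non-promoter.
    """
    seg_off, segment = _largest_n_free_segment(record.seq)
    if len(segment) < params.min_unmasked:
        return PredictionCall(
            record.id,
            record.origin_start,
            len(record.seq),
            "non_promoter",
            None,
            Evidence(masked=True),
        )
    cpg_flag = has_cpg_island(record, cpg_params)
    tokens = tokenize(record, library)
    result = parse(tokens, cpg_flag, grammar, params.max_derivations)

    anchor = min(max(len(record.seq) // 2 - seg_off, 0), len(segment) - 1)
    profile = structural_profile(
        SequenceRecord(record.id, segment, record.origin_start + seg_off),
        scale,
    )
    ext = detect_extremum(
        profile,
        anchor - params.center_halfwidth,
        anchor + params.center_halfwidth,
        _tier_threshold(result.accepted, params),
        params.feature_width,
    )
    rules = result.derivations[0].rule_ids if result.accepted else ()
    evidence = Evidence(
        grammar_accepted=result.accepted,
        cpg=cpg_flag,
        structural_pass=ext.passes,
        magnitude=ext.magnitude,
        kind=ext.kind,
        rules=rules,
    )
    ext_window = seg_off + ext.position  # window coordinates
    tss = record.origin_start + ext_window
    if result.accepted:
        inr_starts = [t.start for t in tokens if t.element == "INR"]
        if inr_starts:
            nearest = min(inr_starts, key=lambda s: abs(s - ext_window))
            if abs(nearest - ext_window) <= params.inr_snap_dist:
                tss = record.origin_start + nearest
    label = "promoter" if ext.passes else "non_promoter"
    return PredictionCall(
        record.id, record.origin_start, len(record.seq), label, tss, evidence
    )


def scan_evidence(
    chromosome: SequenceRecord,
    library: PartLibrary,
    grammar: Grammar,
    scale: PropertyScale,
    params: PredictorParams = PredictorParams(),
    cpg_params: CpGParams = CpGParams(),
) -> List[PredictionCall]:
    """Classify every window of *chromosome*, returning all calls.

    Windows whose longest n-run exceeds ``n_run_limit`` are skipped
    (assembly gaps would pollute the structural profile).
    """
    calls = []
    for win in windows(chromosome, params.window, params.step):
        if max_n_run(win.seq) > params.n_run_limit:
            continue
        call = classify_window(win, library, grammar, scale, params, cpg_params)
        calls.append(replace(call, seq_id=chromosome.id))
    return calls


def apply_thresholds(
    calls: Sequence[PredictionCall], params: PredictorParams
) -> List[PredictionCall]:
    """Relabel evidence calls at a different threshold pair.

    The structural magnitude is threshold-independent, so sweeping
    thresholds only re-applies the two-tier pass rule to stored evidence.
    """
    out = []
    for c in calls:
        if c.evidence.masked:
            out.append(c)
            continue
        ev = c.evidence
        sign_ok = ev.magnitude > 0 if ev.kind == "peak" else ev.magnitude < 0
        passes = sign_ok and abs(ev.magnitude) >= _tier_threshold(
            ev.grammar_accepted, params
        )
        label = "promoter" if passes and c.tss_estimate is not None else "non_promoter"
        out.append(
            replace(
                c,
                label=label,
                evidence=replace(ev, structural_pass=passes),
            )
        )
    return out


def scan(
    chromosome: SequenceRecord,
    library: PartLibrary,
    grammar: Grammar,
    scale: PropertyScale,
    params: PredictorParams = PredictorParams(),
    cpg_params: CpGParams = CpGParams(),
    both_strands: bool = False,
) -> List[PredictionCall]:
    """Promoter calls over all windows of *chromosome*.

    With ``both_strands`` the reverse complement is additionally scanned
    and call coordinates are mapped back to the forward strand.
    """
    calls = [
        c
        for c in scan_evidence(chromosome, library, grammar, scale, params, cpg_params)
        if c.label == "promoter"
    ]
    if both_strands:
        L = len(chromosome.seq)
        rc = SequenceRecord(
            chromosome.id, reverse_complement(chromosome.seq), chromosome.origin_start
        )
        for c in scan_evidence(rc, library, grammar, scale, params, cpg_params):
            if c.label != "promoter":
                continue
            rel = c.tss_estimate - chromosome.origin_start
            fwd = chromosome.origin_start + (L - 1 - rel)
            calls.append(
                replace(
                    c,
                    strand="-",
                    tss_estimate=fwd,
                    window_origin=chromosome.origin_start
                    + L
                    - (c.window_origin - chromosome.origin_start)
                    - c.window_len,
                )
            )
    return calls


@dataclass(frozen=True)
class ClusteredPrediction:
    """Single-linkage merge of promoter calls within the cluster radius."""

    seq_id: str
    position: int                   # mean member position, rounded half-up
    strand: str
    n_members: int
    member_positions: Tuple[int, ...]
    evidence: Evidence


def cluster_tss(
    calls: Sequence[PredictionCall], radius: int = 1000
) -> List[ClusteredPrediction]:
    """Merge promoter calls whose consecutive TSS gaps are <= *radius*.

    Merging is single linkage per (sequence, strand): a chain of calls
    each within *radius* of the next forms one cluster regardless of its
    total span.  The cluster position is the arithmetic mean of member
    positions rounded half-up; evidence flags are OR-ed and the largest
    |magnitude| is kept.
    """
    groups: Dict[Tuple[str, str], List[PredictionCall]] = {}
    for c in calls:
        if c.label != "promoter":
            continue
        groups.setdefault((c.seq_id, c.strand), []).append(c)
    clusters: List[ClusteredPrediction] = []
    for (seq_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda c: c.tss_estimate)
        block: List[PredictionCall] = []
        for c in members + [None]:
            if block and (
                c is None or c.tss_estimate - block[-1].tss_estimate > radius
            ):
                positions = tuple(m.tss_estimate for m in block)
                strongest = max(block, key=lambda m: abs(m.evidence.magnitude))
                merged = Evidence(
                    grammar_accepted=any(m.evidence.grammar_accepted for m in block),
                    cpg=any(m.evidence.cpg for m in block),
                    structural_pass=True,
                    magnitude=strongest.evidence.magnitude,
                    kind=strongest.evidence.kind,
                    rules=tuple(
                        sorted({r for m in block for r in m.evidence.rules})
                    ),
                )
                clusters.append(
                    ClusteredPrediction(
                        seq_id,
                        int(math.floor(sum(positions) / len(positions) + 0.5)),
                        strand,
                        len(block),
                        positions,
                        merged,
                    )
                )
                block = []
            if c is not None:
                block.append(c)
    clusters.sort(key=lambda cl: (cl.seq_id, cl.position))
    return clusters


def clusters_to_bed6(clusters: Sequence[ClusteredPrediction]) -> List[tuple]:
    """BED6 rows; score is |magnitude| scaled by 100 and capped at 1000."""
    return [
        (
            cl.seq_id,
            cl.position,
            cl.position + 1,
            cl.evidence.describe(),
            min(1000, int(round(abs(cl.evidence.magnitude) * 100))),
            cl.strand,
        )
        for cl in clusters
    ]
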