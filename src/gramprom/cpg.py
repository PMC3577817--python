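"""CpG island statistics and detection.

A CpG island is a run of >= ``min_len`` bp whose sliding windows have G+C
content strictly above ``gc_min`` and an observed/expected CpG ratio of at
least ``oe_min`` (Gardiner-Garden & Frommer definitions):

    GC  = (#G + #C) / len
    o/e = #CpG * len / (#C * #G)

Island presence is the boolean core-promoter feature carried into the
grammar as the ``c0`` token.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .seqio import SequenceRecord


@dataclass(frozen=True)
class CpGParams:
    min_len: int = 200       # minimum island span, nt
    gc_min: float = 0.5      # strict lower bound on G+C fraction
    oe_min: float = 0.6      # inclusive lower bound on observed/expected CpG
    win: int = 200           # scanning window, nt
    step: int = 1            # scanning step, nt

    def __post_init__(self) -> None:
        if min(self.min_len, self.win, self.step) <= 0:
            raise ValueError("min_len, win and step must be positive")
        if self.gc_min <= 0 or self.oe_min <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CpGIsland:
    """A detected island: merged, edge-trimmed span of passing windows.

    ``mean_gc``/``mean_oe`` are the G+C fraction and o/e ratio of the
    island substring itself, so the type invariants (mean_gc > gc_min,
    mean_oe >= oe_min, length >= min_len) hold on the reported span.
    """

    start: int
    end: int
    mean_gc: float
    mean_oe: float


def gc_content(seq: str) -> float:
    """G+C fraction of *seq*; 'n' counts in the denominator."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    s = seq.lower()
    return (s.count("g") + s.count("c")) / len(s)


def cpg_obs_exp(seq: str) -> float:
    """Observed/expected CpG ratio: #CG * len / (#C * #G); 0 if #C*#G == 0."""
    if len(seq) < 2:
        raise ValueError("cpg_obs_exp needs length >= 2")
    s = seq.lower()
    nc, ng = s.count("c"), s.count("g")
    if nc == 0 or ng == 0:
        return 0.0
    ncg = s.count("cg")
    return ncg * len(s) / (nc * ng)


def _window_stats(seq: str, win: int, step: int):
    """Vectorized per-window (GC fraction, o/e ratio) via cumulative counts."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("c")
    is_g = arr == ord("g")
    is_cg = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
    starts = np.arange(0, len(seq) - win + 1, step)
    nc = cum_c[starts + win] - cum_c[starts]
    ng = cum_g[starts + win] - cum_g[starts]
    # CpG dinucleotides fully inside the window: starts in [i, i+win-1)
    ncg = cum_cg[np.minimum(starts + win - 1, len(is_cg))] - cum_cg[starts]
    gc = (nc + ng) / win
    denom = nc * ng
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, ncg * win / np.maximum(denom, 1), 0.0)
    return starts, gc, oe


def detect_cpg_islands(
    record: SequenceRecord, params: CpGParams = CpGParams()
) -> List[CpGIsland]:
    """Detect CpG islands by merging passing sliding windows.

    Overlapping/adjacent passing windows are merged into a span, the
    span's edges are trimmed to its first and last C/G base (window
    smearing otherwise drags A/T flanks into the island), and the
    trimmed substring is re-verified against all three criteria; spans
    failing length or either threshold are discarded.  Returned islands
    are sorted and non-overlapping; coordinates are relative to the
    record.
    """
    seq = record.seq
    if len(seq) < params.win:
        return []
    starts, gc, oe = _window_stats(seq, params.win, params.step)
    passing = (gc > params.gc_min) & (oe >= params.oe_min)
    islands: List[CpGIsland] = []
    i = 0
    idx = np.flatnonzero(passing)
    while i < len(idx):
        j = i
        # windows merge while their spans overlap or touch
        while (
            j + 1 < len(idx)
            and starts[idx[j + 1]] <= starts[idx[j]] + params.win
        ):
            j += 1
        span_start = int(starts[idx[i]])
        span_end = int(starts[idx[j]]) + params.win
        while span_start < span_end and seq[span_start] not in "gc":
            span_start += 1
        while span_end > span_start and seq[span_end - 1] not in "gc":
            span_end -= 1
        if span_end - span_start >= params.min_len:
            sub = seq[span_start:span_end]
            span_gc = gc_content(sub)
            span_oe = cpg_obs_exp(sub)
            if span_gc > params.gc_min and span_oe >= params.oe_min:
                islands.append(
                    CpGIsland(span_start, span_end, span_gc, span_oe)
                )
        i = j + 1
    return islands


def has_cpg_island(
    record: SequenceRecord, params: CpGParams = CpGParams()
) -> bool:
    """The ``c0`` token: True iff the record contains at least one island."""
    return bool(detect_cpg_islands(record, params))


def islands_to_bed4(record: SequenceRecord, islands: List[CpGIsland]):
    """BED4 rows (chrom, start, end, name) in source coordinates."""
    return [
        (
            record.id,
            record.origin_start + isl.start,
            record.origin_start + isl.end,
            f"CpG_gc{isl.mean_gc:.2f}_oe{isl.mean_oe:.2f}",
        )
        for isl in islands
    ]
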