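"""Distance-based scoring of TSS predictions.

A prediction within ``max_dist`` of an annotated TSS is a true positive
under greedy nearest-first one-to-one matching; unmatched annotations
are false negatives.  By default every unmatched prediction is a false
positive (stricter than restricting false positives to predictions
inside gene bodies, which requires gene annotation; pass
``gene_intervals`` to enable that policy).  Precision = TP/(TP+FP),
recall = TP/(TP+FN), F = 2PR/(P+R), with zero denominators mapping
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

Position = Union[int, Tuple[str, int]]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int
    max_dist: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_measure: float


def _group(positions: Iterable[Position]) -> Dict[str, List[int]]:
    groups: Dict[str, List[int]] = {}
    for p in positions:
        if isinstance(p, tuple):
            seq_id, pos = p
        else:
            seq_id, pos = "", p
        groups.setdefault(seq_id, []).append(int(pos))
    for lst in groups.values():
        lst.sort()
    return groups


def match_predictions(
    predicted: Iterable[Position],
    annotated: Iterable[Position],
    max_dist: int = 500,
    gene_intervals: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
) -> EvalCounts:
    """Greedy nearest-first one-to-one matching within *max_dist*.

    Candidate pairs are taken in order of increasing distance (ties
    broken toward the leftmost annotation, then the leftmost
    prediction); each prediction and each annotation matches at most
    once.  With *gene_intervals* (seq_id -> half-open intervals), an
    unmatched prediction only counts as FP when it falls inside a gene.
    """
    pred_groups = _group(predicted)
    truth_groups = _group(annotated)
    tp = 0
    fp = 0
    fn = 0
    for seq_id in sorted(set(pred_groups) | set(truth_groups)):
        preds = pred_groups.get(seq_id, [])
        truths = truth_groups.get(seq_id, [])
        pairs = sorted(
            (abs(p - t), t, p, ti, pi)
            for pi, p in enumerate(preds)
            for ti, t in enumerate(truths)
            if abs(p - t) <= max_dist
        )
        used_p: set = set()
        used_t: set = set()
        for _, _, p, ti, pi in pairs:
            if pi in used_p or ti in used_t:
                continue
            used_p.add(pi)
            used_t.add(ti)
            tp += 1
        fn += len(truths) - len(used_t)
        for pi, p in enumerate(preds):
            if pi in used_p:
                continue
            if gene_intervals is not None:
                inside = any(
                    lo <= p < hi for lo, hi in gene_intervals.get(seq_id, ())
                )
                if not inside:
                    continue
            fp += 1
    return EvalCounts(tp, fp, fn, max_dist)


def precision_recall_f(counts: EvalCounts) -> Metrics:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f)


def sweep_max_dist(
    predicted: Sequence[Position],
    annotated: Sequence[Position],
    distances: Sequence[int] = (200, 500, 1000),
) -> List[Tuple[int, EvalCounts, Metrics]]:
    """One (distance, counts, metrics) row per matching distance."""
    rows = []
    for d in distances:
        counts = match_predictions(predicted, annotated, d)
        rows.append((d, counts, precision_recall_f(counts)))
    return rows


def report_tsv(
    rows: Sequence[Tuple[int, EvalCounts, Metrics]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("distance\ttp\tfp\tfn\tprecision\trecall\tf\n")
        for d, c, m in rows:
            fh.write(
                f"{d}\t{c.tp}\t{c.fp}\t{c.fn}\t"
                f"{m.precision:.4f}\t{m.recall:.4f}\t{m.f_measure:.4f}\n"
            )
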