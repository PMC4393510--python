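"""Truth-set evaluation of deletion calls: breakpoint probes, exclusion
regions and a support-threshold ROC sweep.

Both predicted and truth breakpoints are reduced to fixed-width probe
intervals (default 200 bp, centered on the breakpoint-interval midpoint,
clipped at 0) so that tools with different native resolutions can be
compared on equal footing.  A predicted deletion is a true positive iff
both of its probes intersect both probes of some truth deletion; each
truth deletion is credited at most once.  Entries whose probes touch a
read-depth exclusion region are removed from both call and truth sets
before counting.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .cluster import SVCall
from .report import filter_calls

__all__ = [
    "EvaluationError",
    "TruthDeletion",
    "RocPoint",
    "call_to_probe_intervals",
    "truth_to_probe_intervals",
    "apply_exclusions",
    "roc_curve",
    "read_truth_bed",
    "read_bed_regions",
    "write_roc_tsv",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class TruthDeletion:
    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise EvaluationError(f"truth deletion {self.id}: end <= start")


@dataclass(frozen=True)
class RocPoint:
    min_support: int
    true_positives: int
    false_positives: int


def _probe(center: int, width: int) -> Tuple[int, int]:
    lo = center - width // 2
    hi = lo + width
    if lo < 0:
        lo = 0
    return lo, hi


def call_to_probe_intervals(call: SVCall, width: int = 200) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Two ``width``-bp probes centered on the midpoints of the call's
    breakpoint intervals, clipped at 0."""
    if width <= 0:
        raise EvaluationError(f"probe width must be positive, got {width}")
    mid1 = (call.start1 + call.end1) // 2
    mid2 = (call.start2 + call.end2) // 2
    return _probe(mid1, width), _probe(mid2, width)


def truth_to_probe_intervals(t: TruthDeletion, width: int = 200) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Probes around the truth deletion's two edges (start and end)."""
    if width <= 0:
        raise EvaluationError(f"probe width must be positive, got {width}")
    return _probe(t.start, width), _probe(t.end, width)


def _region_tree(regions: Iterable[Tuple[str, int, int]]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _probe_hits(trees: Dict[str, IntervalTree], chrom: str, probe: Tuple[int, int]) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(probe[0], probe[1]))


def apply_exclusions(items: Sequence, regions: Iterable[Tuple[str, int, int]], width: int = 200) -> List:
    """Drop calls/truth entries whose either probe overlaps (≥1 bp,
    half-open semantics) any exclusion region."""
    trees = _region_tree(regions)
    if not trees:
        return list(items)
    kept = []
    for item in items:
        if isinstance(item, TruthDeletion):
            p1, p2 = truth_to_probe_intervals(item, width)
            c1 = c2 = item.chrom
        else:
            p1, p2 = call_to_probe_intervals(item, width)
            c1, c2 = item.chrom1, item.chrom2
        if _probe_hits(trees, c1, p1) or _probe_hits(trees, c2, p2):
            continue
        kept.append(item)
    return kept


def _check_truth_nonoverlapping(truth: Sequence[TruthDeletion]) -> None:
    by_chrom: Dict[str, List[TruthDeletion]] = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t.start)
        for a, b in zip(items, items[1:]):
            if b.start < a.end:
                raise EvaluationError(
                    f"truth set entries overlap on {chrom}: {a.id} and {b.id}"
                )


def _match_calls(
    calls: Sequence[SVCall], truth: Sequence[TruthDeletion], width: int
) -> Dict[str, List[str]]:
    """call_id → list of truth ids whose both probes intersect the call's
    both probes (same chromosome)."""
    truth_by_chrom: Dict[str, List[TruthDeletion]] = {}
    for t in truth:
        truth_by_chrom.setdefault(t.chrom, []).append(t)
    matches: Dict[str, List[str]] = {}
    for c in calls:
        hit: List[str] = []
        if c.chrom1 == c.chrom2:
            p1, p2 = call_to_probe_intervals(c, width)
            for t in truth_by_chrom.get(c.chrom1, []):
                t1, t2 = truth_to_probe_intervals(t, width)
                if min(p1[1], t1[1]) > max(p1[0], t1[0]) and min(p2[1], t2[1]) > max(p2[0], t2[0]):
                    hit.append(t.id)
        matches[c.call_id] = hit
    return matches


def roc_curve(
    calls: Sequence[SVCall],
    truth: Sequence[TruthDeletion],
    support_range: Iterable[int] = range(4, 11),
    require_sample: Optional[str] = None,
    width: int = 200,
) -> List[RocPoint]:
    """TP/FP counts over a minimum-support sweep.

    ``calls`` should be deletion-class with exclusions already applied.  A
    kept call is a true positive iff both of its probes intersect both
    probes of some truth deletion; TP counts *distinct* truth deletions
    detected, FP counts kept calls matching none.  Overlapping truth
    entries violate the truth-set contract and raise.
    """
    _check_truth_nonoverlapping(truth)
    matches = _match_calls(calls, truth, width)
    points = []
    for ms in support_range:
        kept = filter_calls(list(calls), ms, require_sample)
        tp_truth = set()
        fp = 0
        for c in kept:
            hit = matches[c.call_id]
            if hit:
                tp_truth.update(hit)
            else:
                fp += 1
        points.append(RocPoint(min_support=ms, true_positives=len(tp_truth), false_positives=fp))
    return points


# ---------------------------------------------------------------------------
# I/O helpers

def read_truth_bed(path) -> List[TruthDeletion]:
    """Truth deletions from BED (chrom, start, end[, id])."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise EvaluationError(f"{path}:{lineno}: need >= 3 BED fields")
            name = f[3] if len(f) > 3 else f"truth_{lineno}"
            out.append(TruthDeletion(chrom=f[0], start=int(f[1]), end=int(f[2]), id=name))
    return out


def read_bed_regions(path) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_roc_tsv(points: Sequence[RocPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("min_support\ttrue_positives\tfalse_positives\n")
        for p in points:
            fh.write(f"{p.min_support}\t{p.true_positives}\t{p.false_positives}\n")
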