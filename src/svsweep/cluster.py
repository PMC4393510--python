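"""Sweep-line greedy clustering of discordant pairs into breakpoint calls.

Each discordant pair, under its own library's fragment-size cutoff ``W``,
permits a 2-D *breakpoint rectangle*: the product of the candidate-position
intervals for breakpoint 1 and breakpoint 2.  For an end mapped ``[s, e)``
on '+', the breakpoint must lie right of the mapped bases but within
fragment reach: ``[e, s + W)``; on '−', the mirror ``[e − W, s)``.  Pairs
from *different* libraries or samples corroborate the same variant when
their rectangles intersect on both sides — per-library cutoffs absorb
insert-size variability across the cohort.

Because the stream is sorted by leftmost coordinate, a single sweep
suffices: a cluster whose side-1 footprint lies entirely left of the
incoming pair's side-1 interval can never gain another member and is
closed.  An incoming pair joins the compatible open cluster with the
largest worst-side overlap (ties go to the oldest cluster), else seeds a
new one.  Clusters that accumulate more members than ``cluster_cap`` mark
loci of aberrant read depth — typically reference-assembly artifacts — and
are dropped entirely (logged, never emitted as calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

from .extract import ReadPair, RoutingKey
from .profiles import LibraryProfile

__all__ = [
    "ClusterError",
    "BreakpointRectangle",
    "Cluster",
    "SVCall",
    "breakpoint_rectangle",
    "rectangles_compatible",
    "sweep_cluster",
    "finalize_call",
    "cluster_partition",
    "default_cluster_cap",
]

OPEN = "open"
CLOSED = "closed"
DROPPED_DEPTH = "dropped_depth"


class ClusterError(RuntimeError):
    pass


@dataclass(frozen=True)
class BreakpointRectangle:
    """Candidate-breakpoint region permitted by one discordant pair."""

    lo1: int
    hi1: int
    lo2: int
    hi2: int
    owner: ReadPair

    def __post_init__(self) -> None:
        if self.lo1 >= self.hi1 or self.lo2 >= self.hi2:
            raise ClusterError(
                f"degenerate breakpoint rectangle for read {self.owner.read_id}: "
                f"[{self.lo1},{self.hi1}) x [{self.lo2},{self.hi2})"
            )


def _end_interval(start: int, end: int, strand: str, w: int) -> Tuple[int, int]:
    if strand == "+":
        return end, start + w
    return end - w, start


def breakpoint_rectangle(pair: ReadPair, profile: LibraryProfile) -> BreakpointRectangle:
    """The 2-D breakpoint region a canonicalized pair permits under its
    library's slop ``W = max_concordant_span``.

    Raises :class:`ClusterError` when ``W`` does not exceed an end's mapped
    length (degenerate profile — the interval would be empty).
    """
    w = profile.max_concordant_span
    lo1, hi1 = _end_interval(pair.start1, pair.end1, pair.strand1, w)
    lo2, hi2 = _end_interval(pair.start2, pair.end2, pair.strand2, w)
    return BreakpointRectangle(lo1, hi1, lo2, hi2, pair)


def rectangles_compatible(a: BreakpointRectangle, b: BreakpointRectangle) -> bool:
    """True iff the two rectangles overlap on side 1 AND side 2."""
    return (
        min(a.hi1, b.hi1) > max(a.lo1, b.lo1)
        and min(a.hi2, b.hi2) > max(a.lo2, b.lo2)
    )


@dataclass
class Cluster:
    """A growing (then closed) set of mutually compatible rectangles."""

    members: List[BreakpointRectangle] = field(default_factory=list)
    running1: Tuple[int, int] = (0, 0)  # intersection of members' side-1 intervals
    running2: Tuple[int, int] = (0, 0)
    footprint_hi1: int = 0  # max hi1 over members: sweep-closure bound
    state: str = OPEN
    seq: int = 0  # creation order, for oldest-first tie-breaking

    def _overlaps(self, r: BreakpointRectangle) -> Optional[Tuple[int, int]]:
        o1 = min(self.running1[1], r.hi1) - max(self.running1[0], r.lo1)
        if o1 <= 0:
            return None
        o2 = min(self.running2[1], r.hi2) - max(self.running2[0], r.lo2)
        if o2 <= 0:
            return None
        return o1, o2

    def _add(self, r: BreakpointRectangle, cap: int) -> None:
        self.members.append(r)
        self.running1 = (max(self.running1[0], r.lo1), min(self.running1[1], r.hi1))
        self.running2 = (max(self.running2[0], r.lo2), min(self.running2[1], r.hi2))
        self.footprint_hi1 = max(self.footprint_hi1, r.hi1)
        if self.state == OPEN and len(self.members) >= cap:
            self.state = DROPPED_DEPTH

    @property
    def dropped(self) -> bool:
        return self.state == DROPPED_DEPTH


def sweep_cluster(
    pairs: Iterable[ReadPair],
    profiles: Mapping[Tuple[str, str], LibraryProfile],
    cluster_cap: int,
    on_drop=None,
) -> Iterator[Cluster]:
    """Sweep a sorted partition stream and yield finished clusters.

    ``pairs`` must be sorted by the partition sort key (start1 first);
    a decreasing start1 raises :class:`ClusterError`.  A cluster reaching
    ``cluster_cap`` members is marked ``dropped_depth`` (``on_drop`` is
    invoked once with it); it stays in the sweep and keeps absorbing
    compatible pairs — so the saturated locus cannot reseed fresh clusters —
    but is never emitted as a call.  Yielded clusters carry state ``closed``
    or ``dropped_depth``; every input pair belongs to exactly one of them.
    """
    if cluster_cap < 1:
        raise ClusterError(f"cluster_cap must be >= 1, got {cluster_cap}")
    open_clusters: List[Cluster] = []
    last_start1 = None
    seq = 0

    for pair in pairs:
        if last_start1 is not None and pair.start1 < last_start1:
            raise ClusterError(
                f"input stream not sorted: start1 decreased at read {pair.read_id}"
            )
        last_start1 = pair.start1
        prof = profiles.get((pair.sample_id, pair.library_id))
        if prof is None:
            raise ClusterError(
                f"no profile for {pair.sample_id}/{pair.library_id} (read {pair.read_id})"
            )
        rect = breakpoint_rectangle(pair, prof)

        # (1) sweep closure: clusters entirely left of this pair's side-1
        # interval can never gain members
        still_open: List[Cluster] = []
        for cl in open_clusters:
            if cl.footprint_hi1 <= rect.lo1:
                if cl.state == OPEN:
                    cl.state = CLOSED
                yield cl
            else:
                still_open.append(cl)
        open_clusters = still_open

        # (2) best compatible open cluster: max worst-side overlap, oldest wins ties
        best = None
        best_key = None
        for cl in open_clusters:
            ov = cl._overlaps(rect)
            if ov is None:
                continue
            key = (-min(ov), cl.seq)
            if best_key is None or key < best_key:
                best, best_key = cl, key
        if best is not None:
            was_dropped = best.dropped
            best._add(rect, cluster_cap)
            if best.dropped and not was_dropped and on_drop is not None:
                on_drop(best)
            continue

        # (3) seed a new cluster
        cl = Cluster(
            members=[rect],
            running1=(rect.lo1, rect.hi1),
            running2=(rect.lo2, rect.hi2),
            footprint_hi1=rect.hi1,
            seq=seq,
        )
        seq += 1
        if cluster_cap == 1:
            cl.state = DROPPED_DEPTH
            if on_drop is not None:
                on_drop(cl)
        open_clusters.append(cl)

    for cl in open_clusters:
        if cl.state == OPEN:
            cl.state = CLOSED
        yield cl


@dataclass(frozen=True)
class SVCall:
    """A finalized breakpoint call with per-sample support.

    ``(start1, end1)`` / ``(start2, end2)`` are the final running
    intersections of the member rectangles — the tightest region every
    supporting pair agrees on.  Outer footprints (min mapped start / max
    mapped end per side) are kept as metadata and excluded from equality.
    """

    call_id: str
    sv_class: str
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    strand1: str
    strand2: str
    support_by_sample: Dict[str, int]
    total_support: int
    footprint1: Optional[Tuple[int, int]] = field(default=None, compare=False)
    footprint2: Optional[Tuple[int, int]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.total_support != sum(self.support_by_sample.values()):
            raise ClusterError(
                f"{self.call_id}: total_support != sum of per-sample support"
            )


def finalize_call(cluster: Cluster, key: RoutingKey, call_id: str) -> SVCall:
    """Turn a closed cluster into an :class:`SVCall`.

    Raises :class:`ClusterError` for depth-dropped clusters (the caller
    must skip them).
    """
    if cluster.dropped:
        raise ClusterError("cannot finalize a depth-dropped cluster")
    if not cluster.members:
        raise ClusterError("cannot finalize an empty cluster")
    support: Dict[str, int] = {}
    for r in cluster.members:
        support[r.owner.sample_id] = support.get(r.owner.sample_id, 0) + 1
    return SVCall(
        call_id=call_id,
        sv_class=key.sv_class,
        chrom1=key.chrom1,
        start1=cluster.running1[0],
        end1=cluster.running1[1],
        chrom2=key.chrom2,
        start2=cluster.running2[0],
        end2=cluster.running2[1],
        strand1=key.strand1,
        strand2=key.strand2,
        support_by_sample=support,
        total_support=len(cluster.members),
        footprint1=(
            min(r.owner.start1 for r in cluster.members),
            max(r.owner.end1 for r in cluster.members),
        ),
        footprint2=(
            min(r.owner.start2 for r in cluster.members),
            max(r.owner.end2 for r in cluster.members),
        ),
    )


def cluster_partition(
    pairs: Iterable[ReadPair],
    key: RoutingKey,
    profiles: Mapping[Tuple[str, str], LibraryProfile],
    cluster_cap: int,
    call_prefix: str = "call",
    start_index: int = 0,
) -> Tuple[List[SVCall], List[Cluster]]:
    """Cluster one sorted partition; returns (calls, drop_log)."""
    calls: List[SVCall] = []
    dropped: List[Cluster] = []
    i = start_index
    for cl in sweep_cluster(pairs, profiles, cluster_cap):
        if cl.dropped:
            dropped.append(cl)
            continue
        calls.append(finalize_call(cl, key, f"{call_prefix}_{i}"))
        i += 1
    return calls, dropped


def default_cluster_cap(mean_depths: Iterable[float]) -> int:
    """Depth-informed cap on cluster size: ``max(100, round(10 × Σ depth))``.

    Loci attracting more discordant pairs than ~10× the cohort's aggregate
    mean depth reflect collapsed or poorly assembled reference sequence.
    """
    total = sum(mean_depths)
    return max(100, int(round(10 * total)))
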