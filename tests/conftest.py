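"""Shared fixtures and builders for the test suite.

Everything here constructs data programmatically: read pairs with
prescribed breakpoint rectangles, small hand-written SAM files, and
randomized partitions of well-separated clusters for oracle comparisons.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from svsweep.cluster import breakpoint_rectangle
from svsweep.extract import ReadPair, RoutingKey
from svsweep.extsort import sort_key
from svsweep.profiles import LibraryProfile

READ_LEN = 50


def make_profile(
    w: int = 325,
    sample_id: str = "S1",
    library_id: str = "L1",
    median: float = 300,
    mad: float = 5,
    k_mad: float = 5,
) -> LibraryProfile:
    return LibraryProfile(
        sample_id=sample_id,
        library_id=library_id,
        median_span=min(median, w),
        mad_span=mad,
        k_mad=k_mad,
        max_concordant_span=w,
        n_observations=1000,
    )


def make_pair(
    chrom1="chr1",
    start1=100,
    end1=150,
    strand1="+",
    chrom2="chr1",
    start2=600,
    end2=650,
    strand2="-",
    sample_id="S1",
    library_id="L1",
    read_id="r1",
    mapq1=60,
    mapq2=60,
) -> ReadPair:
    return ReadPair(
        chrom1, start1, end1, strand1, chrom2, start2, end2, strand2,
        sample_id, library_id, read_id, mapq1, mapq2,
    )


def pair_for_rects(
    lo1: int,
    lo2: int,
    w: int,
    read_id: str,
    sample_id: str = "S1",
    library_id: str = "L1",
    chrom: str = "chr1",
) -> ReadPair:
    """A deletion-signature (+,−) pair whose breakpoint rectangle is
    exactly [lo1, lo1+w−rl) × [lo2, lo2+w−rl) under cutoff ``w``."""
    rl = READ_LEN
    # '+' end mapped [s1, e1): rectangle side 1 = [e1, s1+w)
    e1 = lo1
    s1 = e1 - rl
    # '-' end mapped [s2, e2): rectangle side 2 = [e2-w, s2)
    e2 = lo2 + w
    s2 = e2 - rl
    return make_pair(
        chrom1=chrom, start1=s1, end1=e1, strand1="+",
        chrom2=chrom, start2=s2, end2=e2, strand2="-",
        sample_id=sample_id, library_id=library_id, read_id=read_id,
    )


def separated_cluster_partition(
    rng: np.random.Generator,
    profiles: Dict[Tuple[str, str], LibraryProfile],
    max_pairs: int = 50,
    max_clusters: int = 6,
) -> Tuple[List[ReadPair], List[List[str]]]:
    """A random sorted deletion partition whose true clusters are separated
    by more than 2·max(W) on side 1.

    Every member of a cluster's rectangle contains that cluster's common
    breakpoint point, so the cluster is a clique; separation makes the
    cliques the connected components.  Returns (sorted pairs, list of true
    member read-id groups).
    """
    keys = sorted(profiles)
    max_w = max(p.max_concordant_span for p in profiles.values())
    n_clusters = int(rng.integers(1, max_clusters + 1))
    pairs: List[ReadPair] = []
    groups: List[List[str]] = []
    budget = max_pairs
    for ci in range(n_clusters):
        b1 = 10_000 + ci * (3 * max_w)
        b2 = 200_000 + int(rng.integers(0, 50_000))
        k = int(rng.integers(1, min(8, budget) + 1))
        budget -= k
        group = []
        for m in range(k):
            sid, lib = keys[int(rng.integers(len(keys)))]
            w = profiles[(sid, lib)].max_concordant_span
            width = w - READ_LEN
            lo1 = b1 - int(rng.integers(0, width))
            lo2 = b2 - int(rng.integers(0, width))
            rid = f"c{ci}m{m}"
            pairs.append(pair_for_rects(lo1, lo2, w, rid, sample_id=sid, library_id=lib))
            group.append(rid)
        groups.append(group)
        if budget <= 0:
            break
    pairs.sort(key=sort_key)
    return pairs, groups


def brute_force_clusters(
    pairs: Sequence[ReadPair], profiles: Dict[Tuple[str, str], LibraryProfile]
) -> List[frozenset]:
    """Independent oracle: maximal mutually-compatible sets, enumerated as
    maximal cliques of the pairwise rectangle-compatibility graph."""
    import networkx as nx

    from svsweep.cluster import rectangles_compatible

    rects = [breakpoint_rectangle(p, profiles[(p.sample_id, p.library_id)]) for p in pairs]
    g = nx.Graph()
    g.add_nodes_from(p.read_id for p in pairs)
    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            if rectangles_compatible(rects[i], rects[j]):
                g.add_edge(pairs[i].read_id, pairs[j].read_id)
    return [frozenset(c) for c in nx.find_cliques(g)]


SAM_HEADER = (
    "@HD\tVN:1.6\tSO:unsorted\n"
    "@SQ\tSN:chr1\tLN:1000000\n"
    "@SQ\tSN:chr2\tLN:1000000\n"
    "@RG\tID:L1\tSM:S1\tLB:L1\n"
)


def sam_record(
    qname: str,
    flag: int,
    chrom: str,
    pos0: int,
    mapq: int = 60,
    cigar: str = "50M",
    rnext: str = "=",
    pnext0: int = 0,
    rg: str = "L1",
) -> str:
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t"
        f"{rnext}\t{pnext0 + 1}\t0\t*\t*\tRG:Z:{rg}\n"
    )


@pytest.fixture
def default_profiles() -> Dict[Tuple[str, str], LibraryProfile]:
    return {
        ("S1", "L1"): make_profile(w=325, sample_id="S1", library_id="L1"),
        ("S2", "L2"): make_profile(w=340, sample_id="S2", library_id="L2", mad=5, k_mad=8),
    }
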