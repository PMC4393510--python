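"""End-to-end discovery workflow: profile → extract → sort → sweep → calls.

Glues the per-stage modules together for the common case of a sample sheet
of SAM/BAM files.  Each stage is independently usable and spills typed TSV
intermediates to a work directory, so the pipeline here is deliberately
thin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import extsort
from .cluster import Cluster, SVCall, cluster_partition, default_cluster_cap
from .extract import (
    FilterReport,
    PairFilters,
    ReadPair,
    canonicalize_pair,
    chromosome_order,
    partition_discordants,
    read_alignment_pairs,
)
from .profiles import LibraryProfile, estimate_library_profile

__all__ = [
    "SampleEntry",
    "read_sample_sheet",
    "profile_samples",
    "run_discovery",
    "DiscoveryResult",
]


@dataclass(frozen=True)
class SampleEntry:
    """One sample-sheet row: id, tumor/normal role, pairing and file path."""

    sample_id: str
    role: str  # tumor | normal | none
    pair_id: str
    path: str
    depth: Optional[float] = None


def read_sample_sheet(path) -> List[SampleEntry]:
    """TSV with header: sample_id, role, pair_id, path[, depth]."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for req in ("sample_id", "role", "pair_id", "path"):
            if req not in cols:
                raise ValueError(f"sample sheet {path} lacks column {req!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            depth = float(f[cols["depth"]]) if "depth" in cols and f[cols["depth"]] else None
            entries.append(
                SampleEntry(
                    sample_id=f[cols["sample_id"]],
                    role=f[cols["role"]],
                    pair_id=f[cols["pair_id"]],
                    path=f[cols["path"]],
                    depth=depth,
                )
            )
    return entries


def profile_samples(
    entries: Sequence[SampleEntry],
    k_mad: float = 8.0,
    n_profile: int = 1_000_000,
    min_observations: int = 1000,
    filters: PairFilters = PairFilters(),
) -> Dict[Tuple[str, str], LibraryProfile]:
    """Estimate a fragment-size profile per (sample, library).

    Spans are outer distances of the first ``n_profile`` properly oriented
    (+,−) same-chromosome pairs per sample, computed from mapped
    coordinates (never the stored template-length field).  Median/MAD are
    robust to the discordant minority in that stream.
    """
    profiles: Dict[Tuple[str, str], LibraryProfile] = {}
    import pysam

    for entry in entries:
        with pysam.AlignmentFile(str(entry.path), check_sq=False) as af:
            rank = chromosome_order(af.header)
        spans: Dict[str, List[int]] = {}
        n_seen = 0
        for raw in read_alignment_pairs(entry.path, entry.sample_id, filters):
            pair = canonicalize_pair(raw, rank)
            if pair.chrom1 != pair.chrom2 or (pair.strand1, pair.strand2) != ("+", "-"):
                continue
            spans.setdefault(pair.library_id, []).append(pair.span)
            n_seen += 1
            if n_seen >= n_profile:
                break
        for lib, vals in spans.items():
            profiles[(entry.sample_id, lib)] = estimate_library_profile(
                vals, k_mad, entry.sample_id, lib, min_observations=min_observations
            )
    return profiles


@dataclass
class DiscoveryResult:
    calls: List[SVCall]
    profiles: Dict[Tuple[str, str], LibraryProfile]
    reports: Dict[str, FilterReport]
    dropped: List[Cluster]
    sample_order: List[str]


def run_discovery(
    entries: Sequence[SampleEntry],
    workdir,
    k_mad: float = 8.0,
    filters: PairFilters = PairFilters(),
    memory_records: int = 500_000,
    cluster_cap: Optional[int] = None,
    n_profile: int = 1_000_000,
    min_observations: int = 1000,
    profiles: Optional[Mapping[Tuple[str, str], LibraryProfile]] = None,
    workers: int = 1,
) -> DiscoveryResult:
    """Run the whole joint-calling workflow over a cohort.

    ``cluster_cap`` defaults to the depth-informed
    :func:`~svsweep.cluster.default_cluster_cap` using the sample sheet's
    depth column (100 when depths are absent).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if profiles is None:
        profiles = profile_samples(
            entries, k_mad=k_mad, n_profile=n_profile,
            min_observations=min_observations, filters=filters,
        )
    if cluster_cap is None:
        depths = [e.depth for e in entries if e.depth is not None]
        cluster_cap = default_cluster_cap(depths) if depths else 100

    part = partition_discordants(entries, profiles, filters, workdir, workers=workers)
    calls: List[SVCall] = []
    dropped: List[Cluster] = []
    rank = part.chrom_rank
    keys = sorted(
        part.spill_paths,
        key=lambda k: (rank[k.chrom1], rank[k.chrom2], k.strand1, k.strand2),
    )
    idx = 0
    for key in keys:
        sorted_path = extsort.external_sort(
            part.spill_paths[key], memory_records, workdir / "sorted"
        )
        from .extract import iter_pairs_tsv

        key_calls, key_dropped = cluster_partition(
            iter_pairs_tsv(sorted_path), key, profiles, cluster_cap, start_index=idx
        )
        idx += len(key_calls)
        calls.extend(key_calls)
        dropped.extend(key_dropped)
    return DiscoveryResult(
        calls=calls,
        profiles=dict(profiles),
        reports=part.reports,
        dropped=dropped,
        sample_order=[e.sample_id for e in entries],
    )
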