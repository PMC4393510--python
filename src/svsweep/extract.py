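"""Discordant read-pair extraction and routing-key partitioning.

Reads SAM/BAM per sample, mates records by read name, applies quality
filters, canonicalizes each pair (lower end first under the header's
chromosome order), classifies it against its library's fragment-size profile
and spills discordant pairs to one file per routing key
``(chrom1, chrom2, strand1, strand2)``.  Each routing key isolates exactly
the alignments that could support one rearrangement class at one
chromosome (pair), so downstream sorting and clustering can run per key,
in parallel, with bitwise-identical output regardless of scheduling.

Spill files are a versioned tab-separated dialect (one pair per line) — the
unit of hand-off between the extract, sort and cluster stages.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pysam

from .profiles import CONCORDANT, DISCORDANT, EXCLUDED, LibraryProfile, classify_alignment_pair

__all__ = [
    "ExtractionError",
    "ReadPair",
    "RoutingKey",
    "PairFilters",
    "FilterReport",
    "DELETION",
    "TANDEM_DUPLICATION",
    "INVERSION",
    "TRANSLOCATION",
    "chromosome_order",
    "read_alignment_pairs",
    "canonicalize_pair",
    "routing_key",
    "partition_discordants",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "iter_pairs_tsv",
]

PAIRS_TSV_MAGIC = "#svsweep-pairs\tv1"

DELETION = "deletion"
TANDEM_DUPLICATION = "tandem_duplication"
INVERSION = "inversion"
TRANSLOCATION = "translocation"


class ExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReadPair:
    """A two-ended mapping with provenance.  Coordinates are 0-based
    half-open mapped intervals; after canonicalization end 1 is the lower
    end under (chromosome-order, start)."""

    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str
    sample_id: str
    library_id: str
    read_id: str
    mapq1: int
    mapq2: int

    @property
    def span(self) -> int:
        """Outer span: rightmost mapped end minus leftmost mapped start.
        Meaningful for canonicalized same-chromosome pairs."""
        return self.end2 - self.start1


@dataclass(frozen=True)
class RoutingKey:
    chrom1: str
    chrom2: str
    strand1: str
    strand2: str

    @property
    def sv_class(self) -> str:
        if self.chrom1 != self.chrom2:
            return TRANSLOCATION
        return {
            ("+", "-"): DELETION,
            ("-", "+"): TANDEM_DUPLICATION,
            ("+", "+"): INVERSION,
            ("-", "-"): INVERSION,
        }[(self.strand1, self.strand2)]

    def filename(self) -> str:
        s = {"+": "p", "-": "m"}
        return f"{self.chrom1}__{self.chrom2}__{s[self.strand1]}{s[self.strand2]}.tsv"


@dataclass(frozen=True)
class PairFilters:
    min_mapq: int = 20
    drop_duplicates: bool = True
    drop_secondary_supplementary: bool = True


@dataclass
class FilterReport:
    """Record- and pair-level accounting for one sample's extraction."""

    records_total: int = 0
    unmapped_dropped: int = 0
    secondary_dropped: int = 0
    duplicate_dropped: int = 0
    mapq_dropped: int = 0
    unmated: int = 0
    pairs_emitted: int = 0
    concordant: int = 0
    discordant: int = 0
    excluded: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def chromosome_order(header: "pysam.AlignmentHeader") -> Dict[str, int]:
    """Chromosome → rank, in the order declared by the SAM header."""
    names = list(header.references)
    if not names:
        raise ExtractionError("alignment header declares no reference sequences")
    return {name: i for i, name in enumerate(names)}


def _library_of(aln: "pysam.AlignedSegment", rg_to_lib: Mapping[str, str]) -> str:
    try:
        rg = aln.get_tag("RG")
    except KeyError:
        return ""
    return rg_to_lib.get(rg, str(rg))


def _rg_library_map(header) -> Dict[str, str]:
    out = {}
    for rg in header.to_dict().get("RG", []):
        out[rg["ID"]] = rg.get("LB", rg["ID"])
    return out


def read_alignment_pairs(
    path,
    sample_id: str,
    filters: PairFilters = PairFilters(),
    report: Optional[FilterReport] = None,
) -> Iterator[ReadPair]:
    """Stream mated pairs from a SAM/BAM file, applying record-level filters.

    Yields one (uncanonicalized) :class:`ReadPair` per read name whose two
    primary ends both survive the filters.  Dropped records and reads whose
    mate is never seen are counted in ``report``; they are not errors.
    """
    if report is None:
        report = FilterReport()
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        if not af.references:
            raise ExtractionError(f"{path}: missing or headerless alignment file")
        rg_to_lib = _rg_library_map(af.header)
        pending: Dict[str, "pysam.AlignedSegment"] = {}
        for aln in af:
            report.records_total += 1
            if filters.drop_secondary_supplementary and (aln.is_secondary or aln.is_supplementary):
                report.secondary_dropped += 1
                continue
            if aln.is_unmapped or aln.mate_is_unmapped or aln.reference_name is None:
                report.unmapped_dropped += 1
                continue
            if filters.drop_duplicates and aln.is_duplicate:
                report.duplicate_dropped += 1
                continue
            if aln.mapping_quality < filters.min_mapq:
                report.mapq_dropped += 1
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            report.pairs_emitted += 1
            yield ReadPair(
                chrom1=mate.reference_name,
                start1=mate.reference_start,
                end1=mate.reference_end,
                strand1="-" if mate.is_reverse else "+",
                chrom2=aln.reference_name,
                start2=aln.reference_start,
                end2=aln.reference_end,
                strand2="-" if aln.is_reverse else "+",
                sample_id=sample_id,
                library_id=_library_of(aln, rg_to_lib),
                read_id=aln.query_name,
                mapq1=mate.mapping_quality,
                mapq2=aln.mapping_quality,
            )
        report.unmated += len(pending)


def canonicalize_pair(pair: ReadPair, chrom_rank: Mapping[str, int]) -> ReadPair:
    """Order the two ends by (chromosome rank, start); strands travel with
    their ends.  Idempotent."""
    key1 = (chrom_rank[pair.chrom1], pair.start1)
    key2 = (chrom_rank[pair.chrom2], pair.start2)
    if key1 <= key2:
        return pair
    return replace(
        pair,
        chrom1=pair.chrom2,
        start1=pair.start2,
        end1=pair.end2,
        strand1=pair.strand2,
        chrom2=pair.chrom1,
        start2=pair.start1,
        end2=pair.end1,
        strand2=pair.strand1,
        mapq1=pair.mapq2,
        mapq2=pair.mapq1,
    )


def routing_key(pair: ReadPair) -> RoutingKey:
    """Routing key of a canonicalized pair — the partition in which it could
    support a rearrangement."""
    return RoutingKey(pair.chrom1, pair.chrom2, pair.strand1, pair.strand2)


# ---------------------------------------------------------------------------
# spill-file TSV dialect (v1)

_TSV_FIELDS = [
    "chrom1", "start1", "end1", "strand1",
    "chrom2", "start2", "end2", "strand2",
    "sample_id", "library_id", "read_id", "mapq1", "mapq2",
]


def _pair_line(p: ReadPair) -> str:
    return (
        f"{p.chrom1}\t{p.start1}\t{p.end1}\t{p.strand1}\t"
        f"{p.chrom2}\t{p.start2}\t{p.end2}\t{p.strand2}\t"
        f"{p.sample_id}\t{p.library_id}\t{p.read_id}\t{p.mapq1}\t{p.mapq2}\n"
    )


def _parse_line(line: str) -> ReadPair:
    f = line.rstrip("\n").split("\t")
    return ReadPair(
        chrom1=f[0], start1=int(f[1]), end1=int(f[2]), strand1=f[3],
        chrom2=f[4], start2=int(f[5]), end2=int(f[6]), strand2=f[7],
        sample_id=f[8], library_id=f[9], read_id=f[10],
        mapq1=int(f[11]), mapq2=int(f[12]),
    )


def write_pairs_tsv(pairs: Iterable[ReadPair], path) -> None:
    with open(path, "w") as fh:
        fh.write(PAIRS_TSV_MAGIC + "\n")
        for p in pairs:
            fh.write(_pair_line(p))


def iter_pairs_tsv(path) -> Iterator[ReadPair]:
    with open(path) as fh:
        first = fh.readline()
        if first.rstrip("\n") != PAIRS_TSV_MAGIC:
            raise ExtractionError(f"{path}: not a svsweep pairs TSV (bad magic)")
        for line in fh:
            yield _parse_line(line)


def read_pairs_tsv(path) -> List[ReadPair]:
    return list(iter_pairs_tsv(path))


# ---------------------------------------------------------------------------
# partitioning

@dataclass
class PartitionResult:
    spill_paths: Dict[RoutingKey, Path]
    reports: Dict[str, FilterReport]
    chrom_rank: Dict[str, int]


def _extract_sample(
    entry,
    profiles: Mapping[Tuple[str, str], LibraryProfile],
    filters: PairFilters,
    chrom_rank: Mapping[str, int],
    sample_dir: Path,
) -> Tuple[str, FilterReport, Dict[RoutingKey, Path]]:
    report = FilterReport()
    handles: Dict[RoutingKey, object] = {}
    paths: Dict[RoutingKey, Path] = {}
    try:
        for raw in read_alignment_pairs(entry.path, entry.sample_id, filters, report):
            pair = canonicalize_pair(raw, chrom_rank)
            prof = profiles.get((pair.sample_id, pair.library_id))
            if prof is None:
                raise ExtractionError(
                    f"no library profile for read group/library "
                    f"{pair.sample_id}/{pair.library_id or '<untagged>'} "
                    f"(read {pair.read_id})"
                )
            label = classify_alignment_pair(pair, prof)
            if label == CONCORDANT:
                report.concordant += 1
            elif label == EXCLUDED:
                report.excluded += 1
            else:
                report.discordant += 1
                key = routing_key(pair)
                fh = handles.get(key)
                if fh is None:
                    path = sample_dir / key.filename()
                    fh = open(path, "w")
                    fh.write(PAIRS_TSV_MAGIC + "\n")
                    handles[key] = fh
                    paths[key] = path
                fh.write(_pair_line(pair))
    finally:
        for fh in handles.values():
            fh.close()
    return entry.sample_id, report, paths


def partition_discordants(
    entries: Sequence,
    profiles: Mapping[Tuple[str, str], LibraryProfile],
    filters: PairFilters,
    workdir,
    workers: int = 1,
) -> PartitionResult:
    """Extract discordant pairs from every sample and spill them into one
    TSV per routing key under ``workdir/partitions``.

    Samples may be processed concurrently (``workers``); each sample writes
    private per-key files which are then concatenated in sample-sheet order,
    so output is bitwise independent of the degree of concurrency.
    ``entries`` are objects with ``sample_id`` and ``path`` attributes.
    """
    workdir = Path(workdir)
    spill_root = workdir / "spill"
    part_dir = workdir / "partitions"
    spill_root.mkdir(parents=True, exist_ok=True)
    part_dir.mkdir(parents=True, exist_ok=True)

    chrom_rank: Optional[Dict[str, int]] = None
    for entry in entries:
        with pysam.AlignmentFile(os.fspath(entry.path), check_sq=False) as af:
            order = chromosome_order(af.header)
        if chrom_rank is None:
            chrom_rank = order
        elif order != chrom_rank:
            raise ExtractionError(
                f"sample {entry.sample_id}: chromosome order differs from the "
                "first sample's header; cohort headers must agree"
            )
    if chrom_rank is None:
        return PartitionResult({}, {}, {})

    jobs = []
    for entry in entries:
        sdir = spill_root / entry.sample_id
        sdir.mkdir(parents=True, exist_ok=True)
        jobs.append((entry, sdir))

    results = []
    if workers <= 1:
        for entry, sdir in jobs:
            results.append(_extract_sample(entry, profiles, filters, chrom_rank, sdir))
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futs = [
                pool.submit(_extract_sample, entry, profiles, filters, chrom_rank, sdir)
                for entry, sdir in jobs
            ]
            results = [f.result() for f in futs]

    reports = {sid: rep for sid, rep, _ in results}
    merged: Dict[RoutingKey, Path] = {}
    all_keys: List[RoutingKey] = []
    seen = set()
    for _, _, paths in results:
        for key in paths:
            if key not in seen:
                seen.add(key)
                all_keys.append(key)
    # deterministic key order: chromosome rank then strands
    all_keys.sort(key=lambda k: (chrom_rank[k.chrom1], chrom_rank[k.chrom2], k.strand1, k.strand2))

    for key in all_keys:
        out_path = part_dir / key.filename()
        with open(out_path, "w") as out:
            out.write(PAIRS_TSV_MAGIC + "\n")
            for _, _, paths in results:  # results are in sample-sheet order
                p = paths.get(key)
                if p is None:
                    continue
                with open(p) as fh:
                    fh.readline()  # magic
                    for line in fh:
                        out.write(line)
        merged[key] = out_path
    return PartitionResult(merged, reports, dict(chrom_rank))
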