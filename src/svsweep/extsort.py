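"""Memory-bounded external sorting of routing-key partitions.

Each partition is sorted by the pair's leftmost coordinate before the sweep.
To keep peak memory independent of cohort size, a partition is read in
chunks of at most ``memory_budget`` records, each chunk sorted in memory and
spilled to a run file, and the runs are combined with a k-way merge
(``heapq.merge``).  The sort key is the full tuple
``(start1, end1, chrom2, start2, sample_id, read_id)`` — a total order, so
the merged stream is bit-reproducible for any memory budget.
"""

from __future__ import annotations

import heapq
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple

from .extract import PAIRS_TSV_MAGIC, ReadPair, _pair_line, iter_pairs_tsv, write_pairs_tsv

__all__ = ["SortOrderError", "sort_key", "sort_partition", "kway_merge", "external_sort"]


class SortOrderError(RuntimeError):
    """A run file violated its sortedness contract."""


def sort_key(p: ReadPair) -> Tuple[int, int, str, int, str, str]:
    return (p.start1, p.end1, p.chrom2, p.start2, p.sample_id, p.read_id)


def sort_partition(spill_path, memory_budget: int, run_dir) -> List[Path]:
    """Split one partition into internally sorted run files.

    At most ``memory_budget`` records are resident at a time.  Returns the
    run paths in creation order; the concatenation of all runs is a
    permutation of the input.
    """
    if memory_budget < 1:
        raise ValueError(f"memory_budget must be >= 1, got {memory_budget}")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(spill_path).stem
    runs: List[Path] = []
    chunk: List[ReadPair] = []

    def flush() -> None:
        if not chunk:
            return
        chunk.sort(key=sort_key)
        path = run_dir / f"{stem}.run{len(runs)}.tsv"
        write_pairs_tsv(chunk, path)
        runs.append(path)
        chunk.clear()

    for pair in iter_pairs_tsv(spill_path):
        chunk.append(pair)
        if len(chunk) >= memory_budget:
            flush()
    flush()
    return runs


def _checked_run(path) -> Iterator[ReadPair]:
    prev = None
    for pair in iter_pairs_tsv(path):
        key = sort_key(pair)
        if prev is not None and key < prev:
            raise SortOrderError(f"run file {path} is not sorted (adjacent inversion)")
        prev = key
        yield pair


def kway_merge(run_paths: Sequence) -> Iterator[ReadPair]:
    """Merge sorted runs into one globally sorted stream.

    Each run is verified while streaming; an adjacent inversion raises
    :class:`SortOrderError` naming the offending run.  True duplicate
    records are preserved (multiset conservation).
    """
    streams = [_checked_run(p) for p in run_paths]
    return heapq.merge(*streams, key=sort_key)


def external_sort(spill_path, memory_budget: int, workdir, out_path=None) -> Path:
    """sort_partition + kway_merge, writing the sorted partition to disk."""
    workdir = Path(workdir)
    runs = sort_partition(spill_path, memory_budget, workdir / "runs")
    if out_path is None:
        out_path = workdir / (Path(spill_path).stem + ".sorted.tsv")
    with open(out_path, "w") as fh:
        fh.write(PAIRS_TSV_MAGIC + "\n")
        for pair in kway_merge(runs):
            fh.write(_pair_line(pair))
    for r in runs:
        r.unlink()
    return Path(out_path)
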