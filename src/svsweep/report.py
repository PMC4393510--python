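"""Support filtering and BEDPE serialization of finalized calls.

BEDPE columns (0-based half-open):
``chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2
svclass total_support support_by_sample``
where ``name`` is the call id, ``score`` the total support, and the last
column encodes per-sample support as ``"s1:3;s2:1"`` in sample-sheet order.
``read_bedpe(write_bedpe(calls)) == calls`` on the serialized data model.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

from .cluster import SVCall

__all__ = ["ReportError", "filter_calls", "write_bedpe", "read_bedpe"]

_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
    "strand1\tstrand2\tsvclass\ttotal_support\tsupport_by_sample"
)


class ReportError(ValueError):
    pass


def filter_calls(
    calls: Sequence[SVCall],
    min_support: int,
    require_sample: Optional[str] = None,
    known_samples: Optional[Sequence[str]] = None,
) -> List[SVCall]:
    """Keep calls with ``total_support >= min_support`` and, if
    ``require_sample`` is given, at least one supporting pair from that
    sample.  Monotone in ``min_support``.
    """
    if min_support < 1:
        raise ReportError(f"min_support must be >= 1, got {min_support}")
    if require_sample is not None:
        universe = (
            set(known_samples)
            if known_samples is not None
            else {s for c in calls for s in c.support_by_sample}
        )
        if calls and require_sample not in universe:
            raise ReportError(f"unknown require_sample {require_sample!r}")
    out = []
    for c in calls:
        if c.total_support < min_support:
            continue
        if require_sample is not None and c.support_by_sample.get(require_sample, 0) < 1:
            continue
        out.append(c)
    return out


def _support_str(call: SVCall, sample_order: Optional[Sequence[str]]) -> str:
    if sample_order is None:
        order = sorted(call.support_by_sample)
    else:
        order = [s for s in sample_order if s in call.support_by_sample]
        extra = [s for s in call.support_by_sample if s not in set(sample_order)]
        order += sorted(extra)
    return ";".join(f"{s}:{call.support_by_sample[s]}" for s in order)


def write_bedpe(calls: Iterable[SVCall], path, sample_order: Optional[Sequence[str]] = None) -> None:
    """Write calls as BEDPE; an empty call set yields a header-comment-only
    file.  ``sample_order`` (normally sample-sheet order) fixes the order of
    the per-sample support field."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom1}\t{c.start1}\t{c.end1}\t{c.chrom2}\t{c.start2}\t{c.end2}\t"
                f"{c.call_id}\t{c.total_support}\t{c.strand1}\t{c.strand2}\t"
                f"{c.sv_class}\t{c.total_support}\t{_support_str(c, sample_order)}\n"
            )


def read_bedpe(path) -> List[SVCall]:
    """Read calls back from BEDPE; malformed lines raise
    :class:`ReportError` with the line number."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 13:
                raise ReportError(f"{path}:{lineno}: expected 13 BEDPE fields, got {len(f)}")
            try:
                support = {}
                if f[12]:
                    for tok in f[12].split(";"):
                        s, n = tok.rsplit(":", 1)
                        support[s] = int(n)
                calls.append(
                    SVCall(
                        call_id=f[6],
                        sv_class=f[10],
                        chrom1=f[0],
                        start1=int(f[1]),
                        end1=int(f[2]),
                        chrom2=f[3],
                        start2=int(f[4]),
                        end2=int(f[5]),
                        strand1=f[8],
                        strand2=f[9],
                        support_by_sample=support,
                        total_support=int(f[11]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ReportError(f"{path}:{lineno}: malformed BEDPE line: {exc}") from exc
    return calls
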