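"""Per-library fragment-size statistics and the discordance cutoff.

Paired-end libraries differ — within and between samples — in the median and
dispersion of their fragment (insert) sizes.  A read pair is only evidence for
a structural variant if its mapped geometry is inconsistent with *its own*
library's concordant fragment model, so every library gets a profile: the
median outer span, the median absolute deviation (MAD) of the span, and a
cutoff ``median + k·MAD`` beyond which a properly oriented (+,−) pair is
called discordant.

The MAD here is deliberately *unscaled* (no 1.4826 normal-consistency
factor): the discordance multiplier ``k`` is quoted directly in MAD units,
conventionally 5 (sensitive) or 8 (specific).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

__all__ = [
    "CONCORDANT",
    "DISCORDANT",
    "EXCLUDED",
    "ProfileError",
    "LibraryProfile",
    "median_and_mad",
    "estimate_library_profile",
    "classify_alignment_pair",
    "write_profiles",
    "read_profiles",
]

CONCORDANT = "concordant"
DISCORDANT = "discordant"
EXCLUDED = "excluded"


class ProfileError(ValueError):
    """Raised for empty span streams, underpopulated or degenerate profiles."""


def _lower_median(sorted_vals: list) -> float:
    # lower-median convention: for even n take the smaller of the two
    # middle elements, so results are integral for integral input
    return sorted_vals[(len(sorted_vals) - 1) // 2]


def median_and_mad(values: Iterable[float]) -> Tuple[float, float]:
    """Median and unscaled median absolute deviation of ``values``.

    Uses the lower-median convention for even-length input (deterministic and
    integer-preserving).  Raises :class:`ProfileError` on empty input.

    >>> median_and_mad([290, 295, 300, 305, 310])
    (300, 5)
    """
    vals = sorted(values)
    if not vals:
        raise ProfileError("no fragment-span observations: cannot estimate a profile")
    med = _lower_median(vals)
    devs = sorted(abs(v - med) for v in vals)
    return med, _lower_median(devs)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class LibraryProfile:
    """Fragment-size model for one (sample, library).

    ``max_concordant_span = round(median_span + k_mad * mad_span)`` is the
    largest outer span a properly oriented pair may have and still be
    considered concordant; it doubles as the positional slop ``W`` used when
    screening pairs for a common breakpoint.
    """

    sample_id: str
    library_id: str
    median_span: float
    mad_span: float
    k_mad: float
    max_concordant_span: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.k_mad <= 0:
            raise ProfileError(f"k_mad must be positive, got {self.k_mad}")
        if self.mad_span < 0 or self.median_span < 0:
            raise ProfileError("median/MAD must be non-negative")
        if self.max_concordant_span < self.median_span:
            raise ProfileError("max_concordant_span below median_span")

    @property
    def min_concordant_span(self) -> float:
        """Lower span bound; undersized (+,−) pairs below it are excluded."""
        return max(0.0, self.median_span - self.k_mad * self.mad_span)


def estimate_library_profile(
    spans: Iterable[int],
    k_mad: float,
    sample_id: str,
    library_id: str,
    min_observations: int = 1000,
) -> LibraryProfile:
    """Fit a :class:`LibraryProfile` from outer-span observations.

    ``spans`` must come from properly oriented (+,−) same-chromosome pairs.
    Raises :class:`ProfileError` naming the library when fewer than
    ``min_observations`` spans are supplied.
    """
    vals = list(spans)
    if len(vals) < min_observations:
        raise ProfileError(
            f"library {sample_id}/{library_id}: {len(vals)} span observations "
            f"< required {min_observations}"
        )
    med, mad = median_and_mad(vals)
    return LibraryProfile(
        sample_id=sample_id,
        library_id=library_id,
        median_span=med,
        mad_span=mad,
        k_mad=k_mad,
        max_concordant_span=_round_half_up(med + k_mad * mad),
        n_observations=len(vals),
    )


def classify_alignment_pair(pair, profile: LibraryProfile) -> str:
    """Label a canonicalized mapped pair concordant / discordant / excluded.

    Discordant: interchromosomal, or non-(+,−) orientation after coordinate
    ordering, or (+,−) with outer span above the library cutoff.  Undersized
    (+,−) pairs (span below ``median − k·MAD``) are *excluded* — they signal
    insertions, which this caller does not model.  Everything else is
    concordant.
    """
    if pair.chrom1 != pair.chrom2:
        return DISCORDANT
    if (pair.strand1, pair.strand2) != ("+", "-"):
        return DISCORDANT
    span = pair.end2 - pair.start1
    if span > profile.max_concordant_span:
        return DISCORDANT
    if span < profile.min_concordant_span:
        return EXCLUDED
    return CONCORDANT


_PROFILE_COLUMNS = [
    "sample_id",
    "library_id",
    "median",
    "mad",
    "k_mad",
    "max_concordant_span",
    "n",
]


def write_profiles(profiles: Iterable[LibraryProfile], path) -> None:
    """Serialize profiles to a TSV (columns: sample_id, library_id, median,
    mad, k_mad, max_concordant_span, n)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for p in profiles:
            fh.write(
                f"{p.sample_id}\t{p.library_id}\t{p.median_span:g}\t{p.mad_span:g}"
                f"\t{p.k_mad:g}\t{p.max_concordant_span}\t{p.n_observations}\n"
            )


def read_profiles(path) -> Mapping[Tuple[str, str], LibraryProfile]:
    """Read a profiles TSV back into a {(sample_id, library_id): profile} map."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PROFILE_COLUMNS:
            raise ProfileError(f"unexpected profile TSV header in {path}")
        for line in fh:
            s, lib, med, mad, k, mx, n = line.rstrip("\n").split("\t")
            prof = LibraryProfile(
                sample_id=s,
                library_id=lib,
                median_span=float(med),
                mad_span=float(mad),
                k_mad=float(k),
                max_concordant_span=int(mx),
                n_observations=int(n),
            )
            out[(s, lib)] = prof
    return out
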