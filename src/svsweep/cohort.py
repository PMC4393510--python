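"""Cohort analytics: germline/private classification, somatic FDR, and
sample clustering by shared variants.

Joint calling across a tumor-normal cohort reports, for every breakpoint,
the supporting read-pair count in every sample.  Thresholding those counts
gives a breakpoints × samples *presence matrix* from which the cohort
analyses follow:

* **germline** — present in at least one normal genome;
* **private** — present in exactly one of the cohort's samples;
* **tumor_private** — private to a tumor: the somatic candidates;
* **normal_private** — private to a normal: biologically implausible as
  somatic events, so (assuming tumor and normal data are comparably error
  prone) their count estimates the number of false somatic candidates.

The somatic false discovery rate is then
``FDR = 100 · #normal_private / #tumor_private``.  Labels are sets, not
exclusive: a normal-private breakpoint is also germline under the
≥1-normal rule.

``fdr_vs_n`` measures how the pairwise-only FDR shrinks as N additional
tumor-normal pairs join the screen — the central benefit of joint calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .cluster import SVCall
from .extract import DELETION, TANDEM_DUPLICATION

__all__ = [
    "CohortError",
    "SamplePairing",
    "presence_matrix",
    "classify_breakpoints",
    "somatic_fdr",
    "fdr_vs_n",
    "sample_clustering",
    "germline_cnv_matrix",
    "GERMLINE",
    "PRIVATE",
    "TUMOR_PRIVATE",
    "NORMAL_PRIVATE",
]

GERMLINE = "germline"
PRIVATE = "private"
TUMOR_PRIVATE = "tumor_private"
NORMAL_PRIVATE = "normal_private"


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class SamplePairing:
    """Tumor-normal pairing of the cohort's samples."""

    pairs: Tuple[Tuple[str, str], ...]  # (tumor_id, normal_id)
    unpaired: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for t, n in self.pairs:
            for s in (t, n):
                if s in seen:
                    raise CohortError(f"sample {s} appears twice in the pairing")
                seen.add(s)
        for s in self.unpaired:
            if s in seen:
                raise CohortError(f"sample {s} appears twice in the pairing")
            seen.add(s)

    @property
    def tumors(self) -> FrozenSet[str]:
        return frozenset(t for t, _ in self.pairs)

    @property
    def normals(self) -> FrozenSet[str]:
        return frozenset(n for _, n in self.pairs)

    @classmethod
    def from_entries(cls, entries: Sequence) -> "SamplePairing":
        """Build from sample-sheet entries (attrs: sample_id, role, pair_id)."""
        by_pair: Dict[str, Dict[str, str]] = {}
        unpaired: List[str] = []
        for e in entries:
            if e.pair_id:
                by_pair.setdefault(e.pair_id, {})[e.role] = e.sample_id
            else:
                unpaired.append(e.sample_id)
        pairs = []
        for pid, members in by_pair.items():
            if "tumor" in members and "normal" in members:
                pairs.append((members["tumor"], members["normal"]))
            else:
                unpaired.extend(members.values())
        return cls(pairs=tuple(pairs), unpaired=tuple(unpaired))


def presence_matrix(
    calls: Sequence[SVCall],
    sample_ids: Sequence[str],
    min_pairs: int = 1,
) -> pd.DataFrame:
    """Boolean breakpoints × samples matrix: present iff the sample
    contributed at least ``min_pairs`` supporting read pairs."""
    data = np.zeros((len(calls), len(sample_ids)), dtype=bool)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, c in enumerate(calls):
        for s, n in c.support_by_sample.items():
            if s in col and n >= min_pairs:
                data[i, col[s]] = True
    return pd.DataFrame(data, index=[c.call_id for c in calls], columns=list(sample_ids))


def classify_breakpoints(
    matrix: pd.DataFrame, pairing: SamplePairing
) -> Dict[str, FrozenSet[str]]:
    """Label every breakpoint with the subset of
    {germline, private, tumor_private, normal_private} it satisfies.

    Labels are non-exclusive sets; a call present in no sample at all is an
    error (it cannot belong to a call set).
    """
    missing = (pairing.tumors | pairing.normals) - set(matrix.columns)
    if missing:
        raise CohortError(f"presence matrix lacks samples: {sorted(missing)}")
    normals = sorted(pairing.normals)
    tumors = sorted(pairing.tumors)
    vals = matrix.to_numpy()
    n_present = vals.sum(axis=1)
    in_normal = matrix[normals].to_numpy().any(axis=1) if normals else np.zeros(len(matrix), bool)
    in_tumor = matrix[tumors].to_numpy().any(axis=1) if tumors else np.zeros(len(matrix), bool)
    labels: Dict[str, FrozenSet[str]] = {}
    for i, call_id in enumerate(matrix.index):
        if n_present[i] == 0:
            raise CohortError(f"call {call_id} is present in no sample")
        s = set()
        if in_normal[i]:
            s.add(GERMLINE)
        if n_present[i] == 1:
            s.add(PRIVATE)
            if in_tumor[i]:
                s.add(TUMOR_PRIVATE)
            if in_normal[i]:
                s.add(NORMAL_PRIVATE)
        labels[call_id] = frozenset(s)
    return labels


def somatic_fdr(labels: Mapping[str, FrozenSet[str]]) -> float:
    """Somatic FDR in percent: ``100 × #normal_private / #tumor_private``.

    Rests on the assumption that variants private to a single normal genome
    are false, and that false somatic calls arise at similar absolute rates
    in tumor and normal data.  Raises :class:`CohortError` when there are no
    tumor-private calls (the rate is undefined).
    """
    n_norm = sum(1 for s in labels.values() if NORMAL_PRIVATE in s)
    n_tum = sum(1 for s in labels.values() if TUMOR_PRIVATE in s)
    if n_tum == 0:
        raise CohortError("somatic FDR undefined: no tumor-private calls")
    return 100.0 * n_norm / n_tum


def fdr_vs_n(
    matrix: pd.DataFrame,
    pairing: SamplePairing,
    n_values: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Somatic FDR as a function of N additional screening pairs.

    For each focal pair, a breakpoint present in the focal normal but not
    the focal tumor is a *false somatic* candidate; it survives as a false
    somatic call only if it is also absent from every sample of N other
    pairs drawn uniformly without replacement.  The denominator is the
    analogous tumor-side count (present in the focal tumor only, absent
    from the screen).  Returns a DataFrame with columns ``n`` and
    ``mean_fdr`` (percent), averaged over ``replicates`` seeded draws.
    At N = 0 this reduces to the pairwise-only estimator.
    """
    pairs = list(pairing.pairs)
    if not pairs:
        raise CohortError("no tumor-normal pairs in the pairing")
    for n in n_values:
        if n >= len(pairs):
            raise CohortError(f"N={n} >= available pairs ({len(pairs)})")
    cols = {s: j for j, s in enumerate(matrix.columns)}
    vals = matrix.to_numpy()
    t_idx = np.array([cols[t] for t, _ in pairs])
    n_idx = np.array([cols[n] for _, n in pairs])
    rng = np.random.default_rng(seed)

    rows = []
    for n_extra in n_values:
        fdrs = []
        for _ in range(replicates):
            false_somatic = 0
            true_side = 0
            for i in range(len(pairs)):
                others = np.delete(np.arange(len(pairs)), i)
                chosen = rng.choice(others, size=n_extra, replace=False) if n_extra else np.array([], int)
                screen_cols = np.concatenate([t_idx[chosen], n_idx[chosen]]).astype(int)
                in_screen = vals[:, screen_cols].any(axis=1) if len(screen_cols) else np.zeros(len(vals), bool)
                cand_norm = vals[:, n_idx[i]] & ~vals[:, t_idx[i]] & ~in_screen
                cand_tum = vals[:, t_idx[i]] & ~vals[:, n_idx[i]] & ~in_screen
                false_somatic += int(cand_norm.sum())
                true_side += int(cand_tum.sum())
            fdrs.append(100.0 * false_somatic / true_side if true_side else 0.0)
        rows.append({"n": n_extra, "mean_fdr": float(np.mean(fdrs))})
    return pd.DataFrame(rows)


def germline_cnv_matrix(
    calls: Sequence[SVCall],
    matrix: pd.DataFrame,
    labels: Mapping[str, FrozenSet[str]],
    max_span: int = 1_000_000,
) -> pd.DataFrame:
    """Restrict a presence matrix to germline deletion/tandem-duplication
    calls whose implied event span (start2 − end1, same chromosome) is at
    most ``max_span`` — the copy-number variants suitable for relatedness
    clustering."""
    keep = []
    for c in calls:
        if c.sv_class not in (DELETION, TANDEM_DUPLICATION):
            continue
        if c.chrom1 != c.chrom2:
            continue
        if c.start2 - c.end1 > max_span:
            continue
        if GERMLINE not in labels.get(c.call_id, frozenset()):
            continue
        keep.append(c.call_id)
    return matrix.loc[keep]


def _jaccard_distances(vals: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between the columns of a boolean matrix.
    A pair of columns with empty union gets distance 1."""
    x = vals.astype(np.float64)
    inter = x.T @ x
    sums = x.sum(axis=0)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def _newick(node, names: Sequence[str]) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    bl_l = node.dist - node.get_left().dist
    bl_r = node.dist - node.get_right().dist
    return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"


def sample_clustering(
    matrix: pd.DataFrame,
) -> Tuple[pd.DataFrame, str]:
    """Average-linkage hierarchical clustering of samples by Jaccard
    distance over presence columns.

    Returns the pairwise distance matrix (DataFrame) and the dendrogram as
    a Newick string.  A sample with an all-absent column is at distance 1
    from everything; it is kept, with a warning.
    """
    if matrix.shape[1] < 2:
        raise CohortError("need at least 2 samples to cluster")
    if matrix.shape[0] < 1:
        raise CohortError("need at least 1 call to cluster samples")
    vals = matrix.to_numpy(dtype=bool)
    empty = [s for s, v in zip(matrix.columns, vals.sum(axis=0)) if v == 0]
    if empty:
        warnings.warn(f"samples with no present calls (distance 1 to all): {empty}")
    dist = _jaccard_distances(vals)
    names = list(matrix.columns)
    dist_df = pd.DataFrame(dist, index=names, columns=names)
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dist, checks=False), method="average")
    tree = to_tree(z)
    return dist_df, _newick(tree, names) + ";"
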