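"""Synthetic multi-sample paired-end cohorts with planted SVs.

The discovery method consumes *mappings*, not bases, so the simulator works
directly in reference coordinates: for every sample haplotype it builds a
donor genome as an ordered list of reference segments (deletions remove a
segment, tandem duplications repeat one, inversions flip one, balanced
translocations rejoin chromosome arms), samples fragments uniformly along
the donor with per-library Normal(median, 1.4826·MAD) lengths, and maps
each fragment's two read ends back through the segment map.  Fragments
contained in one segment emit concordant (+,−) pairs; fragments spanning a
junction emit exactly the rearrangement-class signature a real aligner
would report (deletions: inflated (+,−) span; tandem duplications: everted
(−,+) pairs; inversions: (+,+)/(−,−); translocations: interchromosomal
pairs).  Reads that would straddle a junction (split reads) are dropped.

Germline SVs are genotyped per *individual*: a tumor and its matched
normal share the genotype.  Somatic SVs are private to one tumor.  The
scaling σ = 1.4826·MAD makes the realized span MAD match the configured
MAD, so profile estimation is directly checkable against the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .extract import DELETION, INVERSION, TANDEM_DUPLICATION, TRANSLOCATION

__all__ = [
    "SimulationError",
    "LibrarySpec",
    "SampleSpec",
    "SimConfig",
    "PlantedSV",
    "plant_svs",
    "simulate_sample_pairs",
    "write_sam",
    "simulate_cohort",
    "write_truth",
    "read_truth",
    "presence_from_genotypes",
    "SimOutput",
]

MAD_TO_SIGMA = 1.4826


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    median: int
    mad: int
    depth: float  # mean sequence coverage contributed by this library


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    libraries: Tuple[LibrarySpec, ...]
    role: str = "none"  # tumor | normal | none
    pair_id: str = ""

    @property
    def depth(self) -> float:
        return sum(l.depth for l in self.libraries)


@dataclass(frozen=True)
class SimConfig:
    chrom_lengths: Dict[str, int]
    samples: Tuple[SampleSpec, ...]
    sv_counts: Dict[str, int]  # class -> count
    size_range: Tuple[int, int] = (1000, 50000)
    germline_af: float = 1.0  # per-individual carrier probability
    hom_fraction: float = 0.5  # P(hom | carrier); het otherwise
    somatic_fraction: float = 0.0  # fraction of each class planted as somatic
    noise_rate: float = 0.0  # random discordant pairs per true fragment
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise SimulationError("chromosome lengths must be positive")
        for s in self.samples:
            if s.depth <= 0:
                raise SimulationError(f"sample {s.sample_id}: depth must be positive")
        if self.size_range[0] > self.size_range[1] or self.size_range[0] < 1:
            raise SimulationError("invalid SV size range")


@dataclass(frozen=True)
class PlantedSV:
    sv_id: str
    sv_class: str
    chrom: str
    start: int
    end: int  # for translocation: end == start; partner is (chrom2, pos2)
    genotypes: Dict[str, str]  # sample_id -> het|hom
    origin: str = "germline"  # germline | somatic:<tumor_id>
    chrom2: Optional[str] = None
    pos2: Optional[int] = None


def _individuals(samples: Sequence[SampleSpec]) -> List[List[SampleSpec]]:
    by_pair: Dict[str, List[SampleSpec]] = {}
    singles: List[List[SampleSpec]] = []
    for s in samples:
        if s.pair_id:
            by_pair.setdefault(s.pair_id, []).append(s)
        else:
            singles.append([s])
    return list(by_pair.values()) + singles


def _max_fragment(config: SimConfig) -> int:
    return max(
        int(lib.median + 8 * MAD_TO_SIGMA * lib.mad)
        for s in config.samples
        for lib in s.libraries
    )


def plant_svs(config: SimConfig, rng: Optional[np.random.Generator] = None) -> List[PlantedSV]:
    """Place non-overlapping SVs (rejection sampling) and genotype them.

    Germline SVs are carried per individual with probability
    ``germline_af`` (hom with probability ``hom_fraction``); every germline
    SV has at least one carrier.  ``somatic_fraction`` of each class is
    instead assigned het to a single random tumor.  Deterministic under the
    config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    margin = 2 * _max_fragment(config)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom: str, lo: int, hi: int) -> bool:
        return all(hi + margin <= a or b + margin <= lo for a, b in occupied[chrom])

    def place_interval(size: int) -> Tuple[str, int]:
        for _ in range(2000):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            clen = config.chrom_lengths[chrom]
            if clen < size + 2 * margin + 2:
                continue
            start = int(rng.integers(margin, clen - size - margin))
            if free(chrom, start, start + size):
                occupied[chrom].append((start, start + size))
                return chrom, start
        raise SimulationError(
            "could not place a non-overlapping SV after 2000 attempts; "
            "reduce sv_counts or sizes, or enlarge the genome"
        )

    individuals = _individuals(config.samples)
    tumors = [s.sample_id for s in config.samples if s.role == "tumor"]

    planted: List[PlantedSV] = []
    idx = 0
    for sv_class in sorted(config.sv_counts):
        count = config.sv_counts[sv_class]
        n_somatic = int(round(config.somatic_fraction * count))
        if n_somatic > 0 and not tumors:
            raise SimulationError("somatic SVs requested but no tumor samples configured")
        somatic_flags = np.zeros(count, dtype=bool)
        if n_somatic:
            somatic_flags[rng.choice(count, size=n_somatic, replace=False)] = True
        for j in range(count):
            size = int(rng.integers(config.size_range[0], config.size_range[1] + 1))
            if sv_class == TRANSLOCATION:
                if len(chroms) < 2:
                    raise SimulationError("translocations require at least 2 chromosomes")
                chrom_a, pos_a = place_interval(1)
                for _ in range(2000):
                    chrom_b, pos_b = place_interval(1)
                    if chrom_b != chrom_a:
                        break
                    occupied[chrom_b].pop()  # same chromosome: retry
                else:
                    raise SimulationError("could not place translocation partner")
                chrom, start, end = chrom_a, pos_a, pos_a
                chrom2, pos2 = chrom_b, pos_b
            else:
                chrom, start = place_interval(size)
                end = start + size
                chrom2 = pos2 = None

            if somatic_flags[j]:
                tumor = tumors[int(rng.integers(len(tumors)))]
                genotypes = {tumor: "het"}
                origin = f"somatic:{tumor}"
            else:
                origin = "germline"
                genotypes = {}
                while not genotypes:
                    for ind in individuals:
                        if rng.random() < config.germline_af:
                            gt = "hom" if rng.random() < config.hom_fraction else "het"
                            for s in ind:
                                genotypes[s.sample_id] = gt
            planted.append(
                PlantedSV(
                    sv_id=f"sv_{idx}",
                    sv_class=sv_class,
                    chrom=chrom,
                    start=start,
                    end=end,
                    genotypes=genotypes,
                    origin=origin,
                    chrom2=chrom2,
                    pos2=pos2,
                )
            )
            idx += 1
    return planted


# ---------------------------------------------------------------------------
# donor genome construction

@dataclass(frozen=True)
class _Segment:
    ref_chrom: str
    ref_start: int
    ref_end: int
    orient: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _chrom_segments(chrom: str, length: int, svs: List[PlantedSV]) -> List[_Segment]:
    segs: List[_Segment] = []
    cursor = 0
    for sv in sorted(svs, key=lambda s: s.start):
        if sv.start > cursor:
            segs.append(_Segment(chrom, cursor, sv.start, "+"))
        if sv.sv_class == DELETION:
            pass
        elif sv.sv_class == TANDEM_DUPLICATION:
            segs.append(_Segment(chrom, sv.start, sv.end, "+"))
            segs.append(_Segment(chrom, sv.start, sv.end, "+"))
        elif sv.sv_class == INVERSION:
            segs.append(_Segment(chrom, sv.start, sv.end, "-"))
        else:
            raise SimulationError(f"unexpected intra-chromosomal class {sv.sv_class}")
        cursor = sv.end
    if cursor < length:
        segs.append(_Segment(chrom, cursor, length, "+"))
    return segs


def _split_at(segs: List[_Segment], pos: int) -> Tuple[List[_Segment], List[_Segment]]:
    prefix: List[_Segment] = []
    suffix: List[_Segment] = []
    for i, s in enumerate(segs):
        if s.orient == "+" and s.ref_start <= pos < s.ref_end:
            if pos > s.ref_start:
                prefix.append(_Segment(s.ref_chrom, s.ref_start, pos, "+"))
            if pos < s.ref_end:
                suffix.append(_Segment(s.ref_chrom, pos, s.ref_end, "+"))
            suffix.extend(segs[i + 1:])
            return prefix, suffix
        prefix.append(s)
    raise SimulationError(f"translocation breakpoint {pos} not inside a forward segment")


def _haplotype_genome(
    sample: SampleSpec, planted: Sequence[PlantedSV], config: SimConfig, hap: int
) -> Dict[str, List[_Segment]]:
    carried = [
        sv
        for sv in planted
        if sv.genotypes.get(sample.sample_id) == "hom"
        or (sv.genotypes.get(sample.sample_id) == "het" and hap == 0)
    ]
    intra: Dict[str, List[PlantedSV]] = {}
    tlocs: List[PlantedSV] = []
    for sv in carried:
        if sv.sv_class == TRANSLOCATION:
            tlocs.append(sv)
        else:
            intra.setdefault(sv.chrom, []).append(sv)
    genome = {
        chrom: _chrom_segments(chrom, length, intra.get(chrom, []))
        for chrom, length in config.chrom_lengths.items()
    }
    for sv in tlocs:
        a, b = sv.chrom, sv.chrom2
        pre_a, suf_a = _split_at(genome[a], sv.start)
        pre_b, suf_b = _split_at(genome[b], sv.pos2)
        genome[a] = pre_a + suf_b  # derivative A
        genome[b] = pre_b + suf_a  # derivative B
    return genome


# ---------------------------------------------------------------------------
# fragment simulation

PairRecord = Tuple[str, str, int, str, str, int, str, str]
# (qname, chrom1, pos1, strand1, chrom2, pos2, strand2, library_id)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _map_reads_on_chrom(
    segs: List[_Segment],
    ds: np.ndarray,
    L: np.ndarray,
    rl: int,
) -> Tuple[np.ndarray, list, np.ndarray, np.ndarray, list, np.ndarray, np.ndarray]:
    """Map fragments (donor start ds, length L) on one donor chromosome.

    Returns (keep mask, chromA, posA, strandA(+1/-1), chromB, posB, strandB)
    with junction-straddling reads dropped via the mask.
    """
    seg_dstart = np.cumsum([0] + [s.length for s in segs])[:-1]
    seg_len = np.array([s.length for s in segs])
    seg_ref_start = np.array([s.ref_start for s in segs])
    seg_ref_end = np.array([s.ref_end for s in segs])
    seg_fwd = np.array([s.orient == "+" for s in segs])
    seg_chrom = [s.ref_chrom for s in segs]

    def locate(pos: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        i = np.searchsorted(seg_dstart, pos, side="right") - 1
        ok = pos + rl <= seg_dstart[i] + seg_len[i]
        return i, ok

    pa = ds
    pb = ds + L - rl
    ia, oka = locate(pa)
    ib, okb = locate(pb)
    keep = oka & okb

    def ref_pos(i: np.ndarray, pos: np.ndarray) -> np.ndarray:
        off = pos - seg_dstart[i]
        fwd = seg_fwd[i]
        return np.where(fwd, seg_ref_start[i] + off, seg_ref_end[i] - off - rl)

    pos_a = ref_pos(ia, pa)
    pos_b = ref_pos(ib, pb)
    strand_a = np.where(seg_fwd[ia], 1, -1)  # read A is donor-forward
    strand_b = np.where(seg_fwd[ib], -1, 1)  # read B is donor-reverse
    chrom_a = [seg_chrom[i] for i in ia]
    chrom_b = [seg_chrom[i] for i in ib]
    return keep, chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b


def simulate_sample_pairs(
    sample: SampleSpec,
    planted: Sequence[PlantedSV],
    config: SimConfig,
    rng: np.random.Generator,
) -> List[PairRecord]:
    """All read-pair records for one sample, across its libraries.

    Het carriers route each fragment to a haplotype with probability 1/2.
    ``noise_rate`` adds uniformly random discordant pairs per library.
    """
    rl = config.read_length
    total_ref = sum(config.chrom_lengths.values())
    genomes = [_haplotype_genome(sample, planted, config, hap) for hap in (0, 1)]
    chroms = list(config.chrom_lengths)
    clens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)

    records: List[PairRecord] = []
    frag_no = 0
    for lib in sample.libraries:
        n_frags = int(round(lib.depth * total_ref / (2 * rl)))
        sigma = MAD_TO_SIGMA * lib.mad
        haps = rng.integers(0, 2, n_frags)
        for hap in (0, 1):
            n_h = int((haps == hap).sum())
            if n_h == 0:
                continue
            genome = genomes[hap]
            names = list(genome)
            dlens = np.array([sum(s.length for s in genome[c]) for c in names], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(dlens)])
            g = rng.random(n_h) * cum[-1]
            ci = np.searchsorted(cum, g, side="right") - 1
            ds = (g - cum[ci]).astype(np.int64)
            L = rng.normal(lib.median, sigma, n_h)
            L = np.maximum(np.rint(L), 2 * rl).astype(np.int64)
            fits = ds + L <= dlens[ci]
            for j, name in enumerate(names):
                mask = fits & (ci == j)
                if not mask.any():
                    continue
                keep, ca, pa, sa, cb, pb, sb = _map_reads_on_chrom(
                    genome[name], ds[mask], L[mask], rl
                )
                idx = np.nonzero(keep)[0]
                for t in idx:
                    records.append(
                        (
                            f"{sample.sample_id}.{lib.library_id}.f{frag_no + t}",
                            ca[t],
                            int(pa[t]),
                            "+" if sa[t] > 0 else "-",
                            cb[t],
                            int(pb[t]),
                            "+" if sb[t] > 0 else "-",
                            lib.library_id,
                        )
                    )
                frag_no += int(mask.sum())
        # uniformly random discordant noise pairs
        n_noise = int(round(config.noise_rate * n_frags))
        for k in range(n_noise):
            c1 = chroms[int(rng.choice(len(chroms), p=clens / clens.sum()))]
            c2 = chroms[int(rng.choice(len(chroms), p=clens / clens.sum()))]
            p1 = int(rng.integers(0, config.chrom_lengths[c1] - rl))
            p2 = int(rng.integers(0, config.chrom_lengths[c2] - rl))
            s1 = "+" if rng.random() < 0.5 else "-"
            s2 = "+" if rng.random() < 0.5 else "-"
            records.append(
                (f"{sample.sample_id}.{lib.library_id}.noise{k}", c1, p1, s1, c2, p2, s2, lib.library_id)
            )
    return records


def write_sam(records: Sequence[PairRecord], sample: SampleSpec, config: SimConfig, path) -> None:
    """Write pair records as an unsorted SAM file with @SQ/@RG headers."""
    rl = config.read_length
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in config.chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for lib in sample.libraries:
        lines.append(f"@RG\tID:{lib.library_id}\tSM:{sample.sample_id}\tLB:{lib.library_id}")
    cigar = f"{rl}M"
    for qname, c1, p1, s1, c2, p2, s2, lib in records:
        rev1 = 0x10 if s1 == "-" else 0
        rev2 = 0x10 if s2 == "-" else 0
        mrev1 = 0x20 if s2 == "-" else 0
        mrev2 = 0x20 if s1 == "-" else 0
        rn1 = "=" if c2 == c1 else c2
        rn2 = "=" if c1 == c2 else c1
        lines.append(
            f"{qname}\t{0x1 | 0x40 | rev1 | mrev1}\t{c1}\t{p1 + 1}\t60\t{cigar}\t"
            f"{rn1}\t{p2 + 1}\t0\t*\t*\tRG:Z:{lib}"
        )
        lines.append(
            f"{qname}\t{0x1 | 0x80 | rev2 | mrev2}\t{c2}\t{p2 + 1}\t60\t{cigar}\t"
            f"{rn2}\t{p1 + 1}\t0\t*\t*\tRG:Z:{lib}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth files, sample sheet, cohort driver

def write_truth(planted: Sequence[PlantedSV], bed_path, bedpe_path, genotypes_path) -> None:
    """Truth deletions as BED, all SV breakpoints as BEDPE, and the
    per-sample genotype table as TSV.  ``read_truth`` inverts
    (bedpe, genotypes)."""
    with open(bed_path, "w") as fh:
        for sv in planted:
            if sv.sv_class == DELETION:
                fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_id}\n")
    with open(bedpe_path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tsvclass\torigin\n")
        for sv in planted:
            if sv.sv_class == TRANSLOCATION:
                c2, p2 = sv.chrom2, sv.pos2
            else:
                c2, p2 = sv.chrom, sv.end
            fh.write(
                f"{sv.chrom}\t{sv.start}\t{sv.start + 1}\t{c2}\t{p2}\t{p2 + 1}\t"
                f"{sv.sv_id}\t{sv.sv_class}\t{sv.origin}\n"
            )
    with open(genotypes_path, "w") as fh:
        fh.write("sv_id\tsample_id\tgenotype\n")
        for sv in planted:
            for s, gt in sv.genotypes.items():
                fh.write(f"{sv.sv_id}\t{s}\t{gt}\n")


def read_truth(bedpe_path, genotypes_path) -> List[PlantedSV]:
    genos: Dict[str, Dict[str, str]] = {}
    with open(genotypes_path) as fh:
        fh.readline()
        for line in fh:
            sv_id, s, gt = line.rstrip("\n").split("\t")
            genos.setdefault(sv_id, {})[s] = gt
    out = []
    with open(bedpe_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c1, s1, _e1, c2, s2, _e2, sv_id, cls, origin = line.rstrip("\n").split("\t")
            if cls == TRANSLOCATION:
                out.append(
                    PlantedSV(sv_id, cls, c1, int(s1), int(s1), genos.get(sv_id, {}), origin, c2, int(s2))
                )
            else:
                out.append(PlantedSV(sv_id, cls, c1, int(s1), int(s2), genos.get(sv_id, {}), origin))
    return out


def presence_from_genotypes(
    planted: Sequence[PlantedSV],
    sample_ids: Sequence[str],
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Genotype table → boolean presence matrix, with a per-(call, sample)
    detection-dropout probability emulating missed detection at finite
    depth.  Variants left with no present sample (undetected cohort-wide)
    are removed, mirroring a call set."""
    if rng is None:
        rng = np.random.default_rng(0)
    data = np.zeros((len(planted), len(sample_ids)), dtype=bool)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, sv in enumerate(planted):
        for s in sv.genotypes:
            if s in col:
                data[i, col[s]] = True
    if dropout > 0:
        drop = rng.random(data.shape) < dropout
        data &= ~drop
    df = pd.DataFrame(data, index=[sv.sv_id for sv in planted], columns=list(sample_ids))
    return df[df.any(axis=1)]


@dataclass
class SimOutput:
    planted: List[PlantedSV]
    sample_sheet: Path
    sam_paths: Dict[str, Path]
    truth_bed: Path
    truth_bedpe: Path
    genotypes: Path


def simulate_cohort(config: SimConfig, outdir) -> SimOutput:
    """Generate the full cohort: one SAM per sample, a sample sheet
    (sample_id, role, pair_id, path, depth) and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    plant_seed, *sample_seeds = seed_seq.spawn(1 + len(config.samples))
    planted = plant_svs(config, np.random.default_rng(plant_seed))

    sam_paths: Dict[str, Path] = {}
    for sample, sseed in zip(config.samples, sample_seeds):
        rng = np.random.default_rng(sseed)
        records = simulate_sample_pairs(sample, planted, config, rng)
        path = outdir / f"{sample.sample_id}.sam"
        write_sam(records, sample, config, path)
        sam_paths[sample.sample_id] = path

    sheet = outdir / "sample_sheet.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\trole\tpair_id\tpath\tdepth\n")
        for s in config.samples:
            fh.write(f"{s.sample_id}\t{s.role}\t{s.pair_id}\t{sam_paths[s.sample_id]}\t{s.depth:g}\n")

    truth_bed = outdir / "truth.bed"
    truth_bedpe = outdir / "truth.bedpe"
    genotypes = outdir / "genotypes.tsv"
    write_truth(planted, truth_bed, truth_bedpe, genotypes)
    return SimOutput(planted, sheet, sam_paths, truth_bed, truth_bedpe, genotypes)
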