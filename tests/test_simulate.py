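"""Synthetic cohort generator: planting, signatures, truth, recovery."""

import numpy as np
import pytest

from svsweep.extract import (
    DELETION,
    PairFilters,
    canonicalize_pair,
    read_alignment_pairs,
)
from svsweep.pipeline import profile_samples, read_sample_sheet
from svsweep.profiles import DISCORDANT, classify_alignment_pair, estimate_library_profile
from svsweep.simulate import (
    LibrarySpec,
    PlantedSV,
    SampleSpec,
    SimConfig,
    SimulationError,
    plant_svs,
    presence_from_genotypes,
    read_truth,
    simulate_cohort,
    simulate_sample_pairs,
    write_truth,
)


def _config(**kw):
    defaults = dict(
        chrom_lengths={"chr1": 500_000},
        samples=(
            SampleSpec("N1", (LibrarySpec("L1", 300, 15, 5.0),), role="normal", pair_id="p1"),
            SampleSpec("T1", (LibrarySpec("L2", 400, 30, 5.0),), role="tumor", pair_id="p1"),
        ),
        sv_counts={"deletion": 5},
        size_range=(2000, 10_000),
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_planting_is_deterministic_under_seed():
    cfg = _config(chrom_lengths={"chr1": 10_000_000}, sv_counts={"deletion": 10})
    a = plant_svs(cfg)
    b = plant_svs(cfg)
    assert [(s.chrom, s.start, s.end) for s in a] == [(s.chrom, s.start, s.end) for s in b]
    assert len(a) == 10


def test_planted_intervals_disjoint():
    cfg = _config(chrom_lengths={"chr1": 3_000_000}, sv_counts={"deletion": 10, "inversion": 5})
    svs = sorted(plant_svs(cfg), key=lambda s: (s.chrom, s.start))
    for x, y in zip(svs, svs[1:]):
        assert x.chrom != y.chrom or x.end <= y.start


def test_zero_somatic_fraction_puts_every_sv_in_a_normal():
    cfg = _config(somatic_fraction=0.0, germline_af=0.6, chrom_lengths={"chr1": 2_000_000})
    svs = plant_svs(cfg)
    for sv in svs:
        assert sv.origin == "germline"
        assert "N1" in sv.genotypes  # individual-level genotype covers the normal


def test_full_allele_frequency_means_everyone_carries():
    cfg = _config(germline_af=1.0, chrom_lengths={"chr1": 2_000_000})
    for sv in plant_svs(cfg):
        assert set(sv.genotypes) == {"N1", "T1"}


def test_somatic_svs_private_to_one_tumor():
    cfg = _config(somatic_fraction=1.0, chrom_lengths={"chr1": 2_000_000})
    for sv in plant_svs(cfg):
        assert sv.origin == "somatic:T1"
        assert sv.genotypes == {"T1": "het"}


def test_hom_deletion_fragments_have_inflated_deletion_signature():
    sample = SampleSpec("S1", (LibrarySpec("L1", 300, 15, 10.0),))
    cfg = _config(samples=(sample,), chrom_lengths={"chr1": 300_000}, sv_counts={})
    del_sv = PlantedSV("sv_0", DELETION, "chr1", 100_000, 120_000, {"S1": "hom"})
    rng = np.random.default_rng(5)
    records = simulate_sample_pairs(sample, [del_sv], cfg, rng)
    max_frag = 300 + 8 * 1.4826 * 15
    straddlers = []
    for _q, c1, p1, s1, c2, p2, s2, _lib in records:
        lo, hi = min(p1, p2), max(p1, p2)
        span = hi + cfg.read_length - lo
        if span > max_frag:
            straddlers.append((lo, hi, span, (s1, s2) if p1 <= p2 else (s2, s1)))
    assert straddlers, "expected fragments spanning the deletion"
    del_len = 20_000
    for lo, hi, span, strands in straddlers:
        assert strands == ("+", "-")
        assert lo < 100_000 <= 120_000 <= hi  # brackets the junction in reference space
        # span = sampled fragment length + deleted length
        assert del_len + 2 * cfg.read_length <= span <= del_len + max_frag
    # no coverage inside a homozygous deletion
    for _q, c1, p1, s1, c2, p2, s2, _lib in records:
        for p in (p1, p2):
            assert not (100_000 <= p < 120_000 - cfg.read_length)


def test_no_svs_no_noise_yields_under_one_percent_discordant(tmp_path):
    cfg = _config(sv_counts={}, noise_rate=0.0)
    out = simulate_cohort(cfg, tmp_path)
    entries = read_sample_sheet(out.sample_sheet)
    profiles = profile_samples(entries, k_mad=8.0, min_observations=100)
    for entry in entries:
        labels = []
        rank = {"chr1": 0}
        for raw in read_alignment_pairs(entry.path, entry.sample_id, PairFilters()):
            pair = canonicalize_pair(raw, rank)
            prof = profiles[(pair.sample_id, pair.library_id)]
            labels.append(classify_alignment_pair(pair, prof))
        assert labels
        assert labels.count(DISCORDANT) / len(labels) < 0.01


def test_profiles_recover_configured_library_parameters(tmp_path):
    # ~10,000 fragments per library: depth 4 on 500 kb with 100 bp reads
    samples = (
        SampleSpec(
            "S1",
            (
                LibrarySpec("A", 300, 15, 4.0),
                LibrarySpec("B", 400, 30, 4.0),
                LibrarySpec("C", 500, 50, 4.0),
            ),
        ),
    )
    cfg = _config(samples=samples, sv_counts={}, seed=11)
    out = simulate_cohort(cfg, tmp_path)
    entries = read_sample_sheet(out.sample_sheet)
    profiles = profile_samples(entries, k_mad=8.0, min_observations=1000)
    for lib in samples[0].libraries:
        prof = profiles[("S1", lib.library_id)]
        assert prof.n_observations >= 1000
        assert abs(prof.median_span - lib.median) / lib.median < 0.02
        assert abs(prof.mad_span - lib.mad) / lib.mad < 0.10


def test_truth_files_round_trip(tmp_path):
    cfg = _config(
        chrom_lengths={"chr1": 3_000_000, "chr2": 2_000_000},
        sv_counts={"deletion": 4, "inversion": 2, "tandem_duplication": 2, "translocation": 2},
    )
    planted = plant_svs(cfg)
    bed, bedpe, geno = tmp_path / "t.bed", tmp_path / "t.bedpe", tmp_path / "g.tsv"
    write_truth(planted, bed, bedpe, geno)
    assert read_truth(bedpe, geno) == planted
    n_del_rows = sum(1 for l in bed.read_text().splitlines() if l.strip())
    assert n_del_rows == 4


def test_empty_plant_writes_empty_truth(tmp_path):
    bed, bedpe, geno = tmp_path / "t.bed", tmp_path / "t.bedpe", tmp_path / "g.tsv"
    write_truth([], bed, bedpe, geno)
    assert bed.read_text() == ""
    assert read_truth(bedpe, geno) == []


def test_presence_from_genotypes_dropout():
    svs = [
        PlantedSV("sv_0", DELETION, "chr1", 0, 10, {"A": "het", "B": "hom"}),
        PlantedSV("sv_1", DELETION, "chr1", 20, 30, {"B": "het"}),
    ]
    m = presence_from_genotypes(svs, ["A", "B"], dropout=0.0)
    assert m.loc["sv_0"].tolist() == [True, True]
    assert m.loc["sv_1"].tolist() == [False, True]
    # full dropout removes every row (nothing detected anywhere)
    m2 = presence_from_genotypes(svs, ["A", "B"], dropout=1.0, rng=np.random.default_rng(0))
    assert len(m2) == 0


def test_impossible_placement_raises():
    cfg = _config(chrom_lengths={"chr1": 30_000}, sv_counts={"deletion": 50})
    with pytest.raises(SimulationError, match="non-overlapping"):
        plant_svs(cfg)
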