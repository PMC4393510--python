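"""Pair reading and filtering, canonicalization, routing, partitioning."""

import filecmp

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import SAM_HEADER, make_pair, make_profile, sam_record
from svsweep.extract import (
    DELETION,
    INVERSION,
    TANDEM_DUPLICATION,
    TRANSLOCATION,
    FilterReport,
    PairFilters,
    canonicalize_pair,
    partition_discordants,
    read_alignment_pairs,
    read_pairs_tsv,
    routing_key,
    write_pairs_tsv,
)
from svsweep.pipeline import SampleEntry

RANK = {"chr1": 0, "chr2": 1, "chr5": 2}

FLAG_PAIRED_R1 = 0x1 | 0x40
FLAG_PAIRED_R2 = 0x1 | 0x80 | 0x10  # mate on reverse strand


def _write_sam(path, body):
    path.write_text(SAM_HEADER + body)


def test_clean_pair_is_emitted(tmp_path):
    sam = tmp_path / "a.sam"
    _write_sam(
        sam,
        sam_record("q1", FLAG_PAIRED_R1, "chr1", 100, pnext0=400)
        + sam_record("q1", FLAG_PAIRED_R2, "chr1", 400, pnext0=100),
    )
    report = FilterReport()
    pairs = list(read_alignment_pairs(sam, "S1", PairFilters(min_mapq=20), report))
    assert len(pairs) == 1
    assert report.pairs_emitted == 1
    p = pairs[0]
    assert (p.start1, p.end1, p.start2, p.end2) == (100, 150, 400, 450)
    assert p.library_id == "L1"


def test_low_mapq_end_drops_pair_and_is_counted(tmp_path):
    sam = tmp_path / "a.sam"
    _write_sam(
        sam,
        sam_record("q1", FLAG_PAIRED_R1, "chr1", 100, mapq=0, pnext0=400)
        + sam_record("q1", FLAG_PAIRED_R2, "chr1", 400, pnext0=100),
    )
    report = FilterReport()
    pairs = list(read_alignment_pairs(sam, "S1", PairFilters(min_mapq=20), report))
    assert pairs == []
    assert report.mapq_dropped == 1
    assert report.unmated == 1


def test_secondary_record_ignored_primary_pair_kept(tmp_path):
    sam = tmp_path / "a.sam"
    _write_sam(
        sam,
        sam_record("q1", FLAG_PAIRED_R1, "chr1", 100, pnext0=400)
        + sam_record("q1", FLAG_PAIRED_R2 | 0x100, "chr2", 5000, pnext0=100)
        + sam_record("q1", FLAG_PAIRED_R2, "chr1", 400, pnext0=100),
    )
    report = FilterReport()
    pairs = list(read_alignment_pairs(sam, "S1", PairFilters(), report))
    assert len(pairs) == 1
    assert report.secondary_dropped == 1


@pytest.mark.parametrize(
    "kwargs,expect",
    [
        # reorder by chromosome: chr2 end listed first
        (
            dict(chrom1="chr2", start1=100, end1=150, strand1="+",
                 chrom2="chr1", start2=50, end2=100, strand2="-"),
            ("chr1", 50, "-"),
        ),
        # reorder by coordinate on the same chromosome
        (
            dict(chrom1="chr1", start1=500, end1=550, strand1="-",
                 chrom2="chr1", start2=100, end2=150, strand2="+"),
            ("chr1", 100, "+"),
        ),
    ],
)
def test_canonicalize_orders_ends(kwargs, expect):
    pair = canonicalize_pair(make_pair(**kwargs), RANK)
    assert (pair.chrom1, pair.start1, pair.strand1) == expect


@given(
    chrom1=st.sampled_from(["chr1", "chr2"]),
    chrom2=st.sampled_from(["chr1", "chr2"]),
    start1=st.integers(0, 10_000),
    start2=st.integers(0, 10_000),
    strand1=st.sampled_from("+-"),
    strand2=st.sampled_from("+-"),
)
@settings(max_examples=100, deadline=None)
def test_canonicalize_is_idempotent_and_ordered(chrom1, chrom2, start1, start2, strand1, strand2):
    pair = make_pair(
        chrom1=chrom1, start1=start1, end1=start1 + 50, strand1=strand1,
        chrom2=chrom2, start2=start2, end2=start2 + 50, strand2=strand2,
    )
    canon = canonicalize_pair(pair, RANK)
    assert canonicalize_pair(canon, RANK) == canon
    assert (RANK[canon.chrom1], canon.start1) <= (RANK[canon.chrom2], canon.start2)


@pytest.mark.parametrize(
    "kwargs,sv_class",
    [
        (dict(strand1="+", strand2="-"), DELETION),
        (dict(strand1="-", strand2="+"), TANDEM_DUPLICATION),
        (dict(strand1="+", strand2="+"), INVERSION),
        (dict(strand1="-", strand2="-"), INVERSION),
        (dict(chrom2="chr5", strand1="+", strand2="+"), TRANSLOCATION),
    ],
)
def test_routing_key_class(kwargs, sv_class):
    assert routing_key(make_pair(**kwargs)).sv_class == sv_class


def test_pairs_tsv_round_trip(tmp_path):
    pairs = [make_pair(read_id=f"r{i}", start1=i * 10, end1=i * 10 + 50) for i in range(5)]
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(pairs, path)
    assert read_pairs_tsv(path) == pairs


def _cohort(tmp_path, bodies):
    entries = []
    for sample_id, body in bodies.items():
        sam = tmp_path / f"{sample_id}.sam"
        header = SAM_HEADER.replace("SM:S1", f"SM:{sample_id}")
        sam.write_text(header + body)
        entries.append(SampleEntry(sample_id, "none", "", str(sam)))
    return entries


def _deletion_signature_records(n, chrom="chr1", offset=0):
    # span 5000 >> cutoff: discordant (+,-)
    body = ""
    for i in range(n):
        p1 = offset + i * 10
        p2 = p1 + 5000
        body += sam_record(f"d{i}", FLAG_PAIRED_R1, chrom, p1, pnext0=p2)
        body += sam_record(f"d{i}", FLAG_PAIRED_R2, chrom, p2, pnext0=p1)
    return body


def test_partition_single_key_two_samples(tmp_path):
    entries = _cohort(
        tmp_path,
        {"A": _deletion_signature_records(10), "B": _deletion_signature_records(10)},
    )
    profiles = {
        ("A", "L1"): make_profile(w=325, sample_id="A"),
        ("B", "L1"): make_profile(w=325, sample_id="B"),
    }
    res = partition_discordants(entries, profiles, PairFilters(), tmp_path / "w")
    assert len(res.spill_paths) == 1
    (key,) = res.spill_paths
    assert key.sv_class == DELETION
    records = read_pairs_tsv(res.spill_paths[key])
    assert len(records) == 20
    assert {r.sample_id for r in records} == {"A", "B"}


def test_partition_splits_classes_and_conserves_counts(tmp_path):
    # one deletion-signature pair + one inversion-signature pair + one concordant
    body = (
        sam_record("del1", FLAG_PAIRED_R1, "chr1", 100, pnext0=5100)
        + sam_record("del1", FLAG_PAIRED_R2, "chr1", 5100, pnext0=100)
        + sam_record("inv1", FLAG_PAIRED_R1, "chr1", 200, pnext0=5200)
        + sam_record("inv1", 0x1 | 0x80, "chr1", 5200, pnext0=200)  # both forward
        + sam_record("ok1", FLAG_PAIRED_R1, "chr1", 300, pnext0=550)
        + sam_record("ok1", FLAG_PAIRED_R2, "chr1", 550, pnext0=300)
    )
    entries = _cohort(tmp_path, {"A": body})
    profiles = {("A", "L1"): make_profile(w=325, sample_id="A")}
    res = partition_discordants(entries, profiles, PairFilters(), tmp_path / "w")
    assert len(res.spill_paths) == 2
    assert {k.sv_class for k in res.spill_paths} == {DELETION, INVERSION}
    rep = res.reports["A"]
    assert rep.pairs_emitted == rep.concordant + rep.discordant + rep.excluded == 3
    assert rep.discordant == 2 and rep.concordant == 1


def test_partition_empty_input(tmp_path):
    entries = _cohort(tmp_path, {"A": ""})
    res = partition_discordants(entries, {("A", "L1"): make_profile(sample_id="A")},
                                PairFilters(), tmp_path / "w")
    assert res.spill_paths == {}
    assert res.reports["A"].pairs_emitted == 0


def test_partition_output_independent_of_worker_count(tmp_path):
    bodies = {
        s: _deletion_signature_records(8, offset=i * 1000)
        for i, s in enumerate(["A", "B", "C"])
    }
    profiles = {(s, "L1"): make_profile(sample_id=s) for s in bodies}
    (tmp_path / "one").mkdir()
    (tmp_path / "two").mkdir()
    e1 = _cohort(tmp_path / "one", bodies)
    e2 = _cohort(tmp_path / "two", bodies)
    r1 = partition_discordants(e1, profiles, PairFilters(), tmp_path / "w1", workers=1)
    r2 = partition_discordants(e2, profiles, PairFilters(), tmp_path / "w2", workers=3)
    assert set(r1.spill_paths) == set(r2.spill_paths)
    for key in r1.spill_paths:
        assert filecmp.cmp(r1.spill_paths[key], r2.spill_paths[key], shallow=False)
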