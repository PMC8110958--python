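import pytest

from mirsnp.annotation import (
    classify_all,
    classify_snp,
    compartment_summary,
    dedupe_by_site,
    substitution_spectrum,
)
from mirsnp.models import GenomicInterval, MirnaAnnotation, Variant, VariantClass


def _snp(chrom, pos0, ref, alt):
    return Variant(chrom, pos0, ref, alt, VariantClass.SNP)


@pytest.fixture
def plus_ann():
    return MirnaAnnotation(
        "mir-p",
        GenomicInterval("chr1", 100, 180, "+"),
        matures=[("miR-p-5p", GenomicInterval("chr1", 110, 132, "+"))],
    )


@pytest.fixture
def minus_ann():
    return MirnaAnnotation(
        "mir-m",
        GenomicInterval("chr1", 100, 180, "-"),
        matures=[("miR-m-3p", GenomicInterval("chr1", 150, 172, "-"))],
    )


@pytest.mark.parametrize(
    "pos0,compartment,mpos",
    [
        (110, "mature_nonseed", 1),
        (111, "seed", 2),
        (112, "seed", 3),
        (117, "seed", 8),
        (118, "mature_nonseed", 9),
        (131, "mature_nonseed", 22),
        (109, "precursor_nonmature", None),
        (132, "precursor_nonmature", None),
    ],
)
def test_plus_strand_compartments(plus_ann, pos0, compartment, mpos):
    (call,) = classify_snp(_snp("chr1", pos0, "C", "T"), plus_ann)
    assert call.compartment == compartment
    assert call.mature_position == mpos
    assert call.substitution == "C>T"  # plus strand: sense == VCF


def test_outside_precursor_returns_nothing(plus_ann):
    assert classify_snp(_snp("chr1", 99, "C", "T"), plus_ann) == []
    assert classify_snp(_snp("chr2", 120, "C", "T"), plus_ann) == []


def test_minus_strand_full_position_map(minus_ann):
    """On the minus strand, mature position 1 is the genomically rightmost base."""
    for g in range(150, 172):
        (call,) = classify_snp(_snp("chr1", g, "C", "T"), minus_ann)
        expected = 172 - g  # hand-built map: genomic end -> position 1
        assert call.mature_position == expected
        assert call.compartment == ("seed" if 2 <= expected <= 8 else "mature_nonseed")


def test_minus_strand_sense_alleles_and_transition(minus_ann):
    (call,) = classify_snp(_snp("chr1", 170, "C", "T"), minus_ann)
    assert call.mature_position == 2
    assert call.compartment == "seed"
    assert (call.sense_ref, call.sense_alt) == ("G", "A")
    assert call.is_transition


def test_vcf_ref_convention_keeps_source_alleles(minus_ann):
    (call,) = classify_snp(_snp("chr1", 170, "C", "T"), minus_ann,
                           strand_convention="vcf_ref")
    assert call.substitution == "C>T"
    assert call.is_transition  # Ts/Tv is strand-invariant


def test_overlapping_matures_flagged_ambiguous():
    ann = MirnaAnnotation(
        "mir-o",
        GenomicInterval("chr1", 100, 180, "+"),
        matures=[
            ("miR-o-5p", GenomicInterval("chr1", 110, 132, "+")),
            ("miR-o-5p.2", GenomicInterval("chr1", 120, 142, "+")),
        ],
    )
    calls = classify_snp(_snp("chr1", 125, "A", "G"), ann)
    assert len(calls) == 2
    assert all(c.ambiguous for c in calls)


def test_spectrum_ts_tv_fractions(plus_ann):
    calls = [classify_snp(_snp("chr1", p, r, a), plus_ann)[0]
             for p, r, a in [(112, "C", "T"), (113, "G", "A"), (114, "C", "G")]]
    spec = substitution_spectrum(calls)
    assert spec["transitions"] == 2 and spec["transversions"] == 1
    assert spec["transition_pct"] == 66.7
    assert sum(spec["counts"].values()) == 3
    single = substitution_spectrum(calls[:1])
    assert [v for v in single["counts"].values() if v] == [1]


def test_spectrum_empty_scope_is_explicit_zero(plus_ann):
    (call,) = classify_snp(_snp("chr1", 105, "C", "T"), plus_ann)  # not in mature
    spec = substitution_spectrum([call], scope="mature_only")
    assert spec["total"] == 0 and spec["transition_pct"] == 0.0


def test_compartment_summary_percentages(plus_ann):
    (call,) = classify_snp(_snp("chr1", 112, "C", "T"), plus_ann)
    summary = compartment_summary([call], n_annotated_precursors=10)
    assert summary["seed_pct"] == 100.0
    assert summary["mature_nonseed_pct"] == 0.0
    assert summary["unique_precursor_pct"] == 10.0


def test_partition_and_recovery_on_cohort(small_cohort):
    """Classification recovers every planted compartment; counts partition."""
    from mirsnp.io import FilterSpec, read_vcf

    variants = read_vcf(small_cohort.paths["vcf"], FilterSpec())
    calls = classify_all([v for v in variants if v.is_snp], small_cohort.annotations)
    unique = dedupe_by_site(calls)
    truth = small_cohort.truth_snps.set_index(["chrom", "vcf_pos"])
    assert len(unique) == len(truth)
    for c in unique:
        row = truth.loc[(c.variant.chrom, c.variant.vcf_pos)]
        assert c.compartment == row["compartment"]
        assert c.precursor_id == row["precursor_id"]
        assert c.substitution == f"{row['sense_ref']}>{row['sense_alt']}"
        assert c.is_transition == bool(row["is_transition"])
    counts = compartment_summary(calls)
    assert (
        counts["seed_count"] + counts["mature_nonseed_count"]
        + counts["precursor_nonmature_count"]
        == counts["total_snps"]
    )


@pytest.mark.parametrize("frac_minus", [0.0, 1.0])
def test_strand_invariance_of_ts_tv(frac_minus):
    """Planted Ts/Tv totals are recovered on all-plus and all-minus cohorts."""
    import os
    import tempfile
    from dataclasses import replace

    from conftest import small_config
    from mirsnp.io import FilterSpec, read_vcf
    from mirsnp.simulate import _write_vcf, make_cohort

    cfg = replace(small_config(seed=9), frac_minus_strand=frac_minus)
    res = make_cohort(cfg)

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "v.vcf")
        _write_vcf(path, res.records, res.chrom_seqs, cfg.n_samples)
        variants = read_vcf(path, FilterSpec())
    calls = dedupe_by_site(classify_all([v for v in variants if v.is_snp],
                                        res.annotations))
    spec = substitution_spectrum(calls)
    assert spec["transitions"] == sum(cfg.n_transitions)
    assert spec["total"] == cfg.n_total_snps
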