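import numpy as np
import pytest

from oracles import enumerate_structures

from mirsnp.annotation import classify_snp
from mirsnp.fold import (
    DDG_EPSILON,
    ReferenceMismatchError,
    apply_snp_to_hairpin,
    cohort_ddg_summary,
    ddg_analysis,
    fold_mfe,
)
from mirsnp.fold.nearest_neighbor import EnergyParams, evaluate_structure
from mirsnp.fold.pairs import dotbracket_to_pairs, pairs_to_dotbracket
from mirsnp.fold import vienna
from mirsnp.models import GenomicInterval, MirnaAnnotation, Variant, VariantClass
from mirsnp.simulate import make_hairpin

PARAMS = EnergyParams.default()


def test_nussinov_triplet_hairpin():
    res = fold_mfe("GGGAAAUCCC", engine="nussinov")
    assert res.mfe == -3.0
    assert len(res.pairs) == 3
    best = max(len(s) for s in enumerate_structures("GGGAAAUCCC"))
    assert best == 3


def test_all_a_sequence_has_no_pairs():
    for engine in ("nussinov", "loop_energy"):
        res = fold_mfe("A" * 12, engine=engine)
        assert res.structure == "." * 12
        assert res.mfe == 0.0


def test_invalid_input_rejected():
    with pytest.raises(ValueError):
        fold_mfe("ACGTACGTAC")  # DNA alphabet
    with pytest.raises(ValueError):
        fold_mfe("ACGUA")  # too short
    with pytest.raises(ValueError):
        fold_mfe("ACGUACGUACGU", engine="zuker2000")


@pytest.mark.parametrize("case", range(40))
def test_dp_engines_match_exhaustive_enumeration(case):
    """Both DPs find the enumerated optimum and their structure achieves it."""
    rng = np.random.default_rng(1000 + case)
    n = int(rng.integers(10, 17))
    seq = "".join(rng.choice(list("ACGU"), size=n))
    structs = enumerate_structures(seq)
    nus = fold_mfe(seq, engine="nussinov")
    assert -nus.mfe == max(len(s) for s in structs)
    loop = fold_mfe(seq, engine="loop_energy")
    best = min(evaluate_structure(seq, s, PARAMS) for s in structs)
    assert loop.mfe == pytest.approx(best, abs=1e-9)
    assert evaluate_structure(seq, loop.pairs, PARAMS) == pytest.approx(loop.mfe)


def test_folding_is_deterministic():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGU"), size=40))
    for engine in ("nussinov", "loop_energy"):
        a = fold_mfe(seq, engine=engine)
        b = fold_mfe(seq, engine=engine)
        assert (a.structure, a.mfe) == (b.structure, b.mfe)


def test_dotbracket_round_trip():
    pairs = frozenset({(0, 9), (1, 8), (3, 7)})
    s = pairs_to_dotbracket(10, pairs)
    assert dotbracket_to_pairs(s) == pairs


@pytest.fixture
def plus_ann_with_hairpin():
    hairpin = "GGCGCCGUAAACAUACGGCGCC"  # 22 nt stem-loop
    return MirnaAnnotation(
        "mir-h",
        GenomicInterval("chr1", 100, 122, "+"),
        matures=[("miR-h-5p", GenomicInterval("chr1", 100, 110, "+"))],
        hairpin_seq=hairpin,
    )


def test_apply_snp_plus_strand(plus_ann_with_hairpin):
    ann = plus_ann_with_hairpin
    v = Variant("chr1", 106, "G", "A", VariantClass.SNP)
    (call,) = classify_snp(v, ann)
    alt = apply_snp_to_hairpin(ann, call)
    assert alt[6] == "A" and ann.hairpin_seq[6] == "G"
    assert sum(a != b for a, b in zip(alt, ann.hairpin_seq)) == 1


def test_apply_snp_minus_strand_maps_to_sense():
    # minus-strand precursor: genome holds revcomp of the hairpin
    hairpin = "GGCGCCGUAAACAUACGGCGCC"
    ann = MirnaAnnotation(
        "mir-m", GenomicInterval("chr1", 100, 122, "-"), hairpin_seq=hairpin
    )
    # hairpin offset 6 (G) sits at genomic position end-1-6 = 115; VCF C>T
    v = Variant("chr1", 115, "C", "T", VariantClass.SNP)
    (call,) = classify_snp(v, ann)
    assert (call.sense_ref, call.sense_alt) == ("G", "A")
    alt = apply_snp_to_hairpin(ann, call)
    assert alt[6] == "A"


def test_apply_snp_reference_mismatch_guard(plus_ann_with_hairpin):
    ann = plus_ann_with_hairpin
    v = Variant("chr1", 106, "C", "T", VariantClass.SNP)  # hairpin has G there
    (call,) = classify_snp(v, ann)
    with pytest.raises(ReferenceMismatchError):
        apply_snp_to_hairpin(ann, call)


def _ddg_fixture(hairpin, pos0_offset, ref, alt, strand="+"):
    n = len(hairpin)
    ann = MirnaAnnotation(
        "mir-x", GenomicInterval("chr1", 100, 100 + n, strand), hairpin_seq=hairpin
    )
    v = Variant("chr1", 100 + pos0_offset, ref, alt, VariantClass.SNP)
    (call,) = classify_snp(v, ann)
    return ann, call


def test_ddg_antisymmetry_under_allele_swap():
    hairpin = make_hairpin(12, 5, np.random.default_rng(4))
    ref = hairpin[3].replace("U", "T")
    alt = "A" if ref != "A" else "G"
    ann, call = _ddg_fixture(hairpin, 3, ref, alt)
    fwd = ddg_analysis(ann, call, engine="loop_energy")
    alt_hairpin = apply_snp_to_hairpin(ann, call)
    ann_rev, call_rev = _ddg_fixture(alt_hairpin, 3, alt, ref)
    rev = ddg_analysis(ann_rev, call_rev, engine="loop_energy")
    assert rev.ddg == pytest.approx(-fwd.ddg, abs=1e-9)


def test_stem_disrupting_snp_destabilizes_and_changes_structure():
    # perfect 10-bp stem; break a central G-C pair to G-A
    hairpin = "GGCGGCGCGCAAAAGCGCGCCGCC"
    ann, call = _ddg_fixture(hairpin, 17, "C", "A")  # breaks the G6-C17 pair
    rec = ddg_analysis(ann, call, engine="loop_energy")
    assert rec.ddg > 0
    assert rec.direction == "increase"
    assert rec.structure_changed


def test_structure_change_with_marginal_energy_change():
    """A SNP can rearrange the structure while |ΔΔG| is only 0.1 kcal/mol."""
    hairpin = "GUUUGUGCAGUAAAAACUGUUGUACAAAC"
    ann, call = _ddg_fixture(hairpin, 11, "A", "C")
    rec = ddg_analysis(ann, call, engine="loop_energy")
    assert rec.structure_changed
    assert rec.direction != "none"
    assert abs(rec.ddg) == pytest.approx(0.1, abs=1e-9)


def test_zero_change_snp_is_direction_none():
    # SNP in a hairpin loop of unpaired A's: structure and energy unchanged
    hairpin = "GGCGCGCGCAAAAAGCGCGCGCC"
    ann, call = _ddg_fixture(hairpin, 11, "A", "U")
    rec = ddg_analysis(ann, call, engine="loop_energy")
    assert rec.direction == "none"
    assert not rec.structure_changed


def test_cohort_summary_arithmetic():
    class R:
        def __init__(self, ddg, changed=False):
            self.ddg_val = ddg
            self.structure_changed = changed

        @property
        def ddg(self):
            return self.ddg_val

        @property
        def abs_ddg(self):
            return abs(self.ddg_val)

        @property
        def direction(self):
            if self.ddg_val >= DDG_EPSILON:
                return "increase"
            if self.ddg_val <= -DDG_EPSILON:
                return "decrease"
            return "none"

    s = cohort_ddg_summary([R(1.0), R(-2.0), R(0.0)])
    assert (s["n_nonzero"], s["n_increase"], s["n_decrease"]) == (2, 1, 1)
    assert s["mean_abs_ddg"] == 1.5
    empty = cohort_ddg_summary([R(0.0), R(0.0)])
    assert empty["n_nonzero"] == 0 and not empty["mean_abs_ddg_defined"]


def test_make_hairpin_folds_back_to_its_stem():
    rng = np.random.default_rng(7)
    seq = make_hairpin(10, 4, rng)
    assert len(seq) == 24
    res = fold_mfe(seq, engine="loop_energy")
    assert len(res.pairs) >= 8


def test_random_hairpins_fold_to_single_terminal_loop():
    import re

    rng = np.random.default_rng(8)
    for _ in range(20):
        seq = make_hairpin(int(rng.integers(8, 15)), int(rng.integers(3, 8)), rng)
        res = fold_mfe(seq, engine="loop_energy")
        assert len(re.findall(r"\(\.*\)", res.structure)) == 1


def test_external_engine_contract():
    assert vienna.available()
    res = fold_mfe("GGGCGCAAAAGCGCCC", engine="external")
    assert res.mfe < 0
    assert len(res.structure) == 16
    again = fold_mfe("GGGCGCAAAAGCGCCC", engine="external")
    assert (res.structure, res.mfe) == (again.structure, again.mfe)
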