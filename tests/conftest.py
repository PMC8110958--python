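import pytest

from mirsnp.simulate import SimConfig, make_cohort


def small_config(seed: int = 5) -> SimConfig:
    """Scaled-down cohort: fast enough for per-module tests."""
    return SimConfig(
        seed=seed,
        n_precursors=40,
        n_seed_snps=2,
        n_mature_nonseed_snps=5,
        n_precursor_nonmature_snps=10,
        n_unique_snp_precursors=12,
        n_transitions=(2, 3, 8),
        n_samples=12,
        n_premirna_indels=3,
        n_fail_dp=2,
        n_offtarget_snps=6,
        n_utr_genes=150,
        target_plan=((8, 4, 6), (5, 3, 7)),
        n_go_terms=20,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_cohort")
    return make_cohort(small_config(), outdir=outdir)


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """Full study-scale cohort: 381 precursors, 73 SNPs, 23 samples."""
    outdir = tmp_path_factory.mktemp("study_cohort")
    return make_cohort(SimConfig(seed=101), outdir=outdir)
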