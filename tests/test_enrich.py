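import numpy as np
import pandas as pd
import pytest

from oracles import hypergeom_upper_tail

from mirsnp.enrich import compare_enrichment, hypergeom_enrich, read_go_annotation


def _universe(n):
    return {f"g{i}" for i in range(n)}


def test_exact_tail_small_case():
    # N=20, K=5, n=5, k=5: C(5,5)C(15,0)/C(20,5) = 1/15504
    universe = _universe(20)
    targets = {f"g{i}" for i in range(5)}
    annotation = {"T": set(targets)}
    df = hypergeom_enrich(targets, annotation, universe)
    assert df.loc[0, "p_value"] == pytest.approx(1 / 15504, rel=1e-12)


def test_zero_overlap_gives_p_one():
    universe = _universe(20)
    df = hypergeom_enrich({"g0", "g1"}, {"T": {"g10", "g11"}}, universe)
    assert df.loc[0, "k"] == 0
    assert df.loc[0, "p_value"] == 1.0


def test_tail_matches_combinatorial_summation():
    """scipy path agrees with explicit summation for many (N,K,n,k)."""
    rng = np.random.default_rng(21)
    for _ in range(50):
        N = int(rng.integers(10, 51))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = _universe(N)
        targets = set(rng.choice(sorted(universe), size=n, replace=False))
        term = set(rng.choice(sorted(universe), size=K, replace=False))
        df = hypergeom_enrich(targets, {"T": term}, universe)
        k = len(term & targets)
        assert df.loc[0, "k"] == k
        assert df.loc[0, "p_value"] == pytest.approx(
            hypergeom_upper_tail(k, N, K, n), rel=1e-10
        )


def test_bh_fdr_monotone_and_above_p():
    rng = np.random.default_rng(22)
    N = 100
    universe = _universe(N)
    targets = set(rng.choice(sorted(universe), size=20, replace=False))
    annotation = {
        f"T{i}": set(rng.choice(sorted(universe), size=int(rng.integers(5, 40)),
                                replace=False))
        for i in range(25)
    }
    df = hypergeom_enrich(targets, annotation, universe)
    assert (df["fdr"].values >= df["p_value"].values - 1e-12).all()
    assert (np.diff(df["fdr"].values) >= -1e-12).all()  # sorted by p


def test_null_type_one_error_calibration():
    """Under random target draws, P(p <= 0.05) sits near the nominal level."""
    rng = np.random.default_rng(23)
    N, n, reps = 2000, 200, 1000
    universe = sorted(_universe(N))
    hits = 0
    for _ in range(reps):
        targets = set(rng.choice(universe, size=n, replace=False))
        K = int(rng.integers(100, 600))
        term = set(rng.choice(universe, size=K, replace=False))
        df = hypergeom_enrich(targets, {"T": term}, set(universe))
        hits += df.loc[0, "p_value"] <= 0.05
    rate = hits / reps
    ci = 3 * np.sqrt(0.05 * 0.95 / reps)  # the discrete test is conservative
    assert rate <= 0.05 + ci
    assert rate >= 0.05 - ci


def test_targets_outside_universe_rejected():
    with pytest.raises(ValueError):
        hypergeom_enrich({"zz"}, {"T": {"g0"}}, _universe(5))


def test_term_without_universe_genes_skipped():
    df = hypergeom_enrich({"g0"}, {"T": {"outside"}}, _universe(5))
    assert df.empty


def test_compare_identical_targets_all_both():
    universe = _universe(30)
    targets = {f"g{i}" for i in range(6)}
    annotation = {"T1": set(targets), "T2": {f"g{i}" for i in range(10, 20)}}
    df = hypergeom_enrich(targets, annotation, universe)
    comp = compare_enrichment(df, df, alpha=0.05)
    assert (comp["status"] == "both").all()
    assert (comp["k_ref"] == comp["k_alt"]).all()


def test_compare_subset_monotonicity_of_k():
    universe = _universe(40)
    ref = {f"g{i}" for i in range(12)}
    alt = {f"g{i}" for i in range(6)}  # alt subset of ref
    annotation = {f"T{i}": {f"g{j}" for j in range(i, i + 15)} for i in range(5)}
    rows_ref = hypergeom_enrich(ref, annotation, universe)
    rows_alt = hypergeom_enrich(alt, annotation, universe)
    comp = compare_enrichment(rows_ref, rows_alt, alpha=1.0)
    assert (comp["k_alt"] <= comp["k_ref"]).all()


def test_mismatched_universes_error():
    a = hypergeom_enrich({"g0"}, {"T": {"g0", "g1"}}, _universe(10))
    b = hypergeom_enrich({"g0"}, {"T": {"g0", "g1"}}, _universe(20))
    with pytest.raises(ValueError, match="universe"):
        compare_enrichment(a, b)


def test_planted_enrichment_recovered_on_cohort(small_cohort):
    """Planted terms reach significance on the correct side of the comparison."""
    go = small_cohort.go_annotation
    universe = set(small_cohort.utrs)
    truth = small_cohort.truth_go
    for mid, ref_seed, alt_seed in small_cohort.seed_specs:
        tt = small_cohort.truth_targets
        sub = tt[tt.mirna_id == mid]
        ref_targets = set(sub[sub.role.isin(["ref_only", "common"])].gene)
        alt_targets = set(sub[sub.role.isin(["alt_only", "common"])].gene)
        rows_ref = hypergeom_enrich(ref_targets, go, universe)
        rows_alt = hypergeom_enrich(alt_targets, go, universe)
        comp = compare_enrichment(rows_ref, rows_alt, alpha=0.05)
        planted = truth[truth.mirna_id == mid].set_index("term")["enriched_in"]
        status = comp.set_index("term_id")["status"]
        t_ref = planted[planted == "reference"].index[0]
        t_alt = planted[planted == "snp_altered"].index[0]
        assert status[t_ref] in ("ref_only", "both")
        assert status[t_alt] == "alt_only"


def test_read_go_annotation(tmp_path):
    p = tmp_path / "go.tsv"
    p.write_text("g1\tGO:1\ng2\tGO:1\ng1\tGO:2\n")
    ann = read_go_annotation(p)
    assert ann == {"GO:1": {"g1", "g2"}, "GO:2": {"g1"}}
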