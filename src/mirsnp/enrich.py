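"""Hypergeometric GO-term over-representation with BH FDR correction.

For a target set of size n drawn from a universe of N genes, of which K are
annotated to a term and k of the targets are, the enrichment p-value is the
upper hypergeometric tail P(X >= k). Benjamini–Hochberg step-up FDR is
applied across all tested terms. Only over-representation is tested.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr",
]


def read_go_annotation(path) -> dict[str, set]:
    """Read a two-column (gene, term) TSV into a term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    ann: dict[str, set] = {}
    for gene, term in zip(df["gene"], df["term"]):
        ann.setdefault(term, set()).add(gene)
    return ann


def hypergeom_enrich(
    targets: Iterable[str],
    annotation: dict,
    universe: Iterable[str],
    term_names: Optional[dict] = None,
) -> pd.DataFrame:
    """Test every annotated term for over-representation in the target set.

    Returns rows sorted by p-value. Terms with no annotated universe gene are
    skipped; an empty target set yields an empty frame.
    """
    universe = frozenset(universe)
    targets = frozenset(targets)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    term_names = term_names or {}
    N, n = len(universe), len(targets)
    rows = []
    for term, genes in annotation.items():
        term_genes = frozenset(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & targets)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((term, term_names.get(term, term), k, K, n, N, min(p, 1.0)))
    if not rows or n == 0:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def compare_enrichment(
    rows_ref: pd.DataFrame,
    rows_alt: pd.DataFrame,
    alpha: float = 0.05,
    by: str = "fdr",
) -> pd.DataFrame:
    """Per-term comparison of two enrichment runs at a significance cut.

    ``by`` selects the thresholded column (``fdr`` default, or ``p_value``).
    Both runs must share the annotation universe. Status is ``both``,
    ``ref_only`` or ``alt_only``; k columns give the per-run overlap counts.
    """
    if by not in ("fdr", "p_value"):
        raise ValueError("'by' must be 'fdr' or 'p_value'")
    if len(rows_ref) and len(rows_alt):
        if rows_ref["N"].iat[0] != rows_alt["N"].iat[0]:
            raise ValueError("enrichment runs used different universes")
    sig_ref = rows_ref[rows_ref[by] <= alpha] if len(rows_ref) else rows_ref
    sig_alt = rows_alt[rows_alt[by] <= alpha] if len(rows_alt) else rows_alt
    ref_terms = set(sig_ref["term_id"]) if len(sig_ref) else set()
    alt_terms = set(sig_alt["term_id"]) if len(sig_alt) else set()
    k_ref = dict(zip(rows_ref.get("term_id", []), rows_ref.get("k", [])))
    k_alt = dict(zip(rows_alt.get("term_id", []), rows_alt.get("k", [])))
    rows = []
    for term in sorted(ref_terms | alt_terms):
        status = (
            "both" if term in ref_terms and term in alt_terms
            else "ref_only" if term in ref_terms
            else "alt_only"
        )
        rows.append((term, status, k_ref.get(term, 0), k_alt.get(term, 0)))
    return pd.DataFrame(rows, columns=["term_id", "status", "k_ref", "k_alt"])
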