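"""Hypergeometric term enrichment with Benjamini-Hochberg FDR correction."""
from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationTable", "hypergeometric_enrichment", "bh_adjust", "read_annotation_tsv"]


class AnnotationTable:
    """Term -> gene-set mapping over a fixed gene universe.

    Every annotated gene must belong to the universe; overlapping terms are
    allowed.
    """

    def __init__(self, terms: dict[str, set[str]], universe: set[str]):
        self.universe = set(universe)
        self.terms = {t: set(g) for t, g in terms.items()}
        stray = sorted(set().union(*self.terms.values()) - self.universe) if self.terms else []
        if stray:
            raise ValueError(f"annotated genes outside the universe: {stray[:10]}")

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, universe: set[str]) -> "AnnotationTable":
        """Build from a two-column (gene_id, term) frame."""
        terms: dict[str, set[str]] = {}
        for gene, term in pairs.itertuples(index=False):
            terms.setdefault(str(term), set()).add(str(gene))
        return cls(terms, universe)


def read_annotation_tsv(path, universe: set[str]) -> AnnotationTable:
    pairs = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return AnnotationTable.from_pairs(pairs.iloc[:, :2], universe)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: set[str],
    annotations: AnnotationTable,
    test_empty_terms: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term in a query gene set.

    For a term with K annotated genes in a universe of N, and a query of n
    genes hitting k of them, the raw P is P(X >= k) for X hypergeometric.
    BH adjustment runs across all tested terms; terms with zero query overlap
    are included by default (they affect the BH denominator).
    """
    query = set(query)
    outside = sorted(query - annotations.universe)
    if outside:
        raise ValueError(f"query genes outside the universe: {outside[:10]}")
    N = len(annotations.universe)
    n = len(query)
    rows = {}
    for term, genes in annotations.terms.items():
        k = len(query & genes)
        if k == 0 and not test_empty_terms:
            continue
        K = len(genes)
        rows[term] = {
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "pvalue": float(stats.hypergeom.sf(k - 1, N, K, n)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if not out.empty:
        out["pvalue"] = out["pvalue"].clip(0.0, 1.0)
        out["p_adjusted"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values("pvalue", kind="mergesort")
        out.index.name = "term"
    return out
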