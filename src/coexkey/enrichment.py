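"""Term over-representation by the one-sided Fisher (hypergeometric) test with
Benjamini-Hochberg correction.

The test asks, per annotation term, whether a query gene set overlaps the
term's gene set more than expected under sampling without replacement from
the background universe: p = P(X >= k) for X ~ Hypergeom(N, K, n).  The
background is the analysis universe (for this pipeline: the post-filter gene
list), not the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "fisher_enrichment",
    "benjamini_hochberg",
    "read_annotation_pairs",
    "read_gmt",
]


@dataclass
class AnnotationMap:
    """term -> gene set over a background universe, with term namespaces."""

    terms: dict[str, set]
    universe: set
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for term, genes in self.terms.items():
            outside = set(genes) - self.universe
            if outside:
                warnings.warn(
                    f"term {term!r}: {len(outside)} annotated genes outside the "
                    "universe were dropped",
                    stacklevel=2,
                )
            cleaned[term] = set(genes) & self.universe
        self.terms = cleaned


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order and capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Per-term overlap counts, hypergeometric p and BH q."""

    table: pd.DataFrame  # term, k, K, n, N, odds_ratio, p, q, significant
    q_cut: float = 0.05


def fisher_enrichment(
    query, annotation: AnnotationMap, q_cut: float = 0.05
) -> EnrichmentResult:
    """One-sided over-representation test of ``query`` against every term.

    Query genes outside the universe are dropped with a warning.  Rows are
    sorted by q then p; terms with K < 2 or zero overlap are reported but
    never flagged significant.
    """
    query = set(query)
    outside = query - annotation.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= annotation.universe
    columns = ["term", "k", "K", "n", "N", "odds_ratio", "p", "q", "significant"]
    if not query or not annotation.terms:
        return EnrichmentResult(table=pd.DataFrame(columns=columns), q_cut=q_cut)
    big_n = len(annotation.universe)
    n = len(query)
    rows = []
    for term, genes in annotation.terms.items():
        big_k = len(genes)
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        a, b = k, n - k
        c, d = big_k - k, big_n - big_k - (n - k)
        odds = np.inf if b * c == 0 and a * d > 0 else (
            0.0 if a * d == 0 else (a * d) / (b * c)
        )
        rows.append((term, k, big_k, n, big_n, odds, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=columns[:7])
    table["q"] = benjamini_hochberg(table["p"])
    table["significant"] = (table["q"] < q_cut) & (table["K"] >= 2) & (table["k"] >= 1)
    table = table.sort_values(["q", "p", "term"]).reset_index(drop=True)
    return EnrichmentResult(table=table, q_cut=q_cut)


def read_annotation_pairs(path, universe) -> AnnotationMap:
    """Two-column TSV (gene, term) -> AnnotationMap over ``universe``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    terms: dict[str, set] = {}
    for gene, term in zip(df["gene"], df["term"]):
        terms.setdefault(str(term), set()).add(str(gene))
    return AnnotationMap(terms=terms, universe=set(universe))


def read_gmt(path, universe) -> AnnotationMap:
    """GMT file (term <tab> description <tab> gene...) -> AnnotationMap."""
    terms: dict[str, set] = {}
    namespaces: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        terms[parts[0]] = set(parts[2:])
        namespaces[parts[0]] = parts[1]
    return AnnotationMap(terms=terms, universe=set(universe), namespaces=namespaces)
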