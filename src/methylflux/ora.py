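"""Hypergeometric over-representation analysis (ORA) of gene lists.

For a query of n genes drawn from a universe of N genes and a term annotating
K of them, the overlap k is tested against the upper tail of
Hypergeometric(N, K, n); p-values across terms are Benjamini-Hochberg
adjusted. The universe should be the set of expressed/tested genes, not the
genome.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

logger = logging.getLogger("methylflux")


def hypergeom_ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: Mapping[str, set[str]],
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of a gene list against each term.

    Query genes outside the universe are dropped (with a logged count), and
    each term is intersected with the universe before testing. Terms whose
    in-universe size falls outside [min_term_size, max_term_size] are not
    tested. Results are sorted by padj, then p, then term.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    dropped = query - universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query &= universe
    if not query:
        raise ValueError("no query genes remain inside the universe")

    N, n = len(universe), len(query)
    rows = []
    for term, genes in collection.items():
        term_genes = genes & universe
        K = len(term_genes)
        if not (min_term_size <= K <= max_term_size):
            continue
        k = len(term_genes & query)
        # P(X >= k) under Hypergeometric(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term": term,
                "k_hit": k,
                "n_hits": n,
                "K_term": K,
                "N": N,
                "p": p,
                "fold_enrichment": fold,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "k_hit", "n_hits", "K_term", "N", "p", "fold_enrichment"]
    )
    if not out.empty:
        out["padj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
        out["padj"] = out["padj"].clip(upper=1.0)
        out = out.sort_values(
            ["padj", "p", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
    return out[["term", "k_hit", "n_hits", "K_term", "N", "p", "padj", "fold_enrichment"]]
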