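"""Hypergeometric over-representation analysis (ORA).

Given a query gene set, a collection of annotated gene sets (GMT) and a gene
universe, each collection set is tested for over-representation of query
genes with the upper-tail hypergeometric probability P(X >= k), where k is
the query/set overlap ("counts"), K the set size in the universe, n the
query size in the universe and N the universe size.  BH correction is
applied across the sets of one collection.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .rac import bh_adjust
from .signatures import GeneSignature


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) drawing n from N with K marked."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overrepresentation(
    query: GeneSignature,
    collection: Sequence[GeneSignature],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One EnrichmentRow per collection set, BH-corrected, sorted by p.

    Query and collection genes outside the universe are dropped; the number
    of dropped query genes is recorded in the frame attrs.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query.genes) & uni
    dropped = len(query.genes) - len(q)
    if not q:
        raise ValueError("query does not intersect the universe")
    N, n = len(uni), len(q)
    rows = []
    for sig in collection:
        members = set(sig.genes) & uni
        K = len(members)
        k = len(q & members)
        p = hypergeometric_test(k, K, n, N) if K else 1.0
        rows.append(dict(collection_set=sig.name, k=k, K=K, n=n, N=N, p=p))
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"])
    df = df.sort_values(["p", "collection_set"], kind="mergesort").reset_index(drop=True)
    df.attrs["query_genes_dropped"] = dropped
    return df
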