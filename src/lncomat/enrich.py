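"""Hypergeometric gene-set enrichment with Benjamini-Hochberg correction.

Over-representation of a query gene list (e.g. the down-regulated mRNAs of a
contrast, or the relevant genes of an lncRNA set) in each set of a GMT
collection is scored with the upper-tail hypergeometric probability
P(X >= k) for X ~ Hypergeom(N, K, n), where N is the universe size, K the
set size within the universe, n the query size and k the observed overlap.
Plain upper-tail probabilities are used (no EASE-style n-1 deflation); BH
q-values are computed over all tested sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .formats import ContractError, GeneSetCollection


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ContractError(
            f"invalid hypergeometric bounds N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(min(1.0, st.hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving w.r.t. input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_list(
    query: list[str] | set[str],
    universe: list[str] | set[str],
    sets: GeneSetCollection,
    direction: str = "mixed",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Test every gene set for over-representation of ``query`` in ``universe``.

    Sets are intersected with the universe before counting; sets with no
    member in the universe are dropped (and reported via the ``excluded``
    attribute on the returned frame). Every retained set is tested and enters
    the BH correction; rows with overlap below ``min_overlap`` are then
    hidden. Result is sorted by p, then set name.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        raise ContractError(f"query genes outside universe: {sorted(stray)}")
    if direction not in ("up", "down", "mixed"):
        raise ContractError(f"unknown direction tag {direction!r}")
    N, n = len(universe), len(query)
    rows, excluded = [], []
    for name in sets.names():
        members = set(sets.members(name)) & universe
        if not members:
            excluded.append(name)
            continue
        K = len(members)
        k = len(members & query)
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper(N, K, n, k), "direction": direction})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p",
                                         "direction"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result[result["k"] >= min_overlap]
        result = result.sort_values(["p", "set"], kind="mergesort")
        result = result.reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    result.attrs["excluded"] = excluded
    return result
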