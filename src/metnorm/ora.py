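"""Over-representation analysis of a gene list against a GMT collection.

A one-sided hypergeometric tail test per set: with a background universe
of N genes of which K belong to the set, a query of n genes showing x
members of the set has

    p = sum_{k=x}^{min(n, K)} C(K, k) C(N-K, n-k) / C(N, n)

p-values are Benjamini-Hochberg adjusted across all tested sets.  By
default the universe is restricted to genes annotated in the collection
(the intersection of the supplied universe with the union of set
members), mirroring how curated-pathway ORA services define their
background; pass ``restrict_universe=False`` to use the raw universe.
Sets overlapping the query in fewer than one gene are excluded from the
test (and from the adjustment denominator m) unless
``include_zero_overlap`` is set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import GeneSet

__all__ = ["benjamini_hochberg", "hypergeometric_overrep"]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeometric_overrep(
    query,
    collection: dict[str, GeneSet],
    universe,
    min_set_size: int = 3,
    restrict_universe: bool = True,
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Parameters
    ----------
    query
        Gene symbols of interest; members outside the universe are
        dropped with a warning.
    collection
        Mapping set_name -> :class:`GeneSet`.
    universe
        Background gene symbols.
    min_set_size
        Sets with fewer in-universe members are skipped.

    Returns a DataFrame with columns set_name, description,
    set_size_in_universe, overlap, p_value, q_value, neg_log10_q, sorted
    by descending neg_log10_q, ties by ascending p then set name.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("universe is empty")
    universe_set = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in universe_set]
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
        query = [g for g in query if g in universe_set]
    if len(query) > len(universe_set):
        raise ValidationError("query larger than universe")
    if restrict_universe:
        annotated = set().union(*(s.members for s in collection.values())) if collection else set()
        universe_set = universe_set & annotated
        query = [g for g in query if g in universe_set]

    N = len(universe_set)
    n = len(query)
    query_set = set(query)
    rows = []
    for name, s in collection.items():
        members = s.members & universe_set
        K = len(members)
        if K < min_set_size:
            continue
        x = len(query_set & members)
        if x < 1 and not include_zero_overlap:
            continue
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if N else 1.0
        rows.append(
            {
                "set_name": name,
                "description": s.description,
                "set_size_in_universe": K,
                "overlap": x,
                "p_value": min(1.0, max(p, 0.0)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "description",
            "set_size_in_universe",
            "overlap",
            "p_value",
        ],
    )
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        result["neg_log10_q"] = pd.Series(dtype=float)
        return result
    result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    with np.errstate(divide="ignore"):
        result["neg_log10_q"] = -np.log10(result["q_value"])
    result = result.sort_values(
        by=["neg_log10_q", "p_value", "set_name"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return result
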