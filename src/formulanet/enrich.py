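"""Hypergeometric gene-set over-representation and cumulative-curve AUCC.

For a query of n annotated genes and a term annotating M of the N genes in
the collection universe, the over-representation p-value is the
hypergeometric upper tail

    P = 1 - sum_{i<k} C(M,i) C(N-M, n-i) / C(N,n),

BH-adjusted over all tested terms; terms with adjusted P < alpha
(default 0.01) are called significant. The common-term cumulative curve
reports, for each N in 1..n_max, the percentage of a query's top-N terms
that are also significant for a comparison set; its trapezoidal integral
(AUCC) ranks comparison sets by association strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AnnotationCollection:
    """Flat term -> gene-set mapping with its annotation universe."""

    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, genes)
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        universe = self.universe
        if not universe:
            universe = frozenset()
            for _, genes in self.terms.values():
                universe |= genes
        object.__setattr__(self, "universe", frozenset(universe))
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")

    @classmethod
    def from_gmt(cls, terms: dict[str, tuple[str, frozenset[str]]]) -> "AnnotationCollection":
        return cls(terms=dict(terms))

    def __len__(self) -> int:
        return len(self.terms)


def hypergeom_tail(N: int, M: int, n: int, k: int) -> float:
    """P(overlap >= k) drawing n genes from N with M marked."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N; got N={N}, M={M}, n={n}")
    if not 0 <= k <= min(M, n):
        raise ValueError(f"require 0 <= k <= min(M, n); got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def enrich(
    query, collection: AnnotationCollection, alpha: float = 0.01
) -> pd.DataFrame:
    """Test every term overlapping the query; BH-adjust; sort by adjusted p.

    Terms with zero overlap are not tested (they cannot reach significance
    and would only dilute the BH correction). Output columns: term_id,
    name, N, M, n, k, pvalue, adj_pvalue, significant.
    """
    query = frozenset(str(g).upper() for g in query)
    q = query & collection.universe
    if not q:
        raise ValueError("query has no genes in the annotation universe")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for term_id in sorted(collection.terms):
        name, genes = collection.terms[term_id]
        k = len(q & genes)
        if k == 0:
            continue
        M = len(genes)
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "N": N,
                "M": M,
                "n": n,
                "k": k,
                "pvalue": hypergeom_tail(N, M, n, k),
            }
        )
    if not rows:
        raise ValueError("no term overlaps the query")
    df = pd.DataFrame(rows)
    df["adj_pvalue"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["adj_pvalue"] < alpha
    return (
        df.sort_values(["adj_pvalue", "term_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def significant_terms(rows: pd.DataFrame) -> frozenset[str]:
    return frozenset(rows.loc[rows["significant"], "term_id"])


def common_term_curve(
    formula_rows: pd.DataFrame, disease_significant, n_max: int = 30
) -> np.ndarray:
    """p(N) = 100 * |top-N formula terms ∩ disease-significant terms| / N.

    ``formula_rows`` must already be sorted ascending by adjusted p-value
    (as :func:`enrich` returns them). If fewer than ``n_max`` rows are
    available the curve is truncated.
    """
    terms = formula_rows["term_id"].tolist()
    if n_max > len(terms):
        n_max = len(terms)
    disease_significant = frozenset(disease_significant)
    hits = 0
    curve = np.empty(n_max)
    for i in range(n_max):
        if terms[i] in disease_significant:
            hits += 1
        curve[i] = 100.0 * hits / (i + 1)
    return curve


def aucc(percentages) -> float:
    """Trapezoidal area under a cumulative curve sampled at N = 1, 2, ..."""
    p = np.asarray(percentages, dtype=float)
    if p.size < 2:
        raise ValueError("AUCC needs a curve of length >= 2")
    return float(np.trapezoid(p))


def aucc_ranking(
    formula_rows: pd.DataFrame,
    disease_rows: dict[str, pd.DataFrame],
    n_max: int = 30,
) -> pd.DataFrame:
    """AUCC of the common-term curve per comparison set, sorted descending."""
    out = []
    for label, rows in disease_rows.items():
        curve = common_term_curve(formula_rows, significant_terms(rows), n_max=n_max)
        out.append({"set": label, "aucc": aucc(curve), "n_points": len(curve)})
    return (
        pd.DataFrame(out)
        .sort_values(["aucc", "set"], ascending=[False, True])
        .reset_index(drop=True)
    )
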