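"""Binomial over-representation scoring of compound-target profiles.

A target hit by k of the formula's n compounds is tested against the null
that compound-target links fall uniformly, with per-pair hit probability
g/n where g is the mean number of compounds per target in the profile.
The tail probability P(X >= k) under Binomial(n, g/n), adjusted for
multiple testing (Benjamini-Hochberg), gates the gene score

    GS = -log10(P_adj) / rank(P_adj)     if P_adj <= alpha, else 0,

and a compound's score CS is the mean GS over its targets. Genes with
GS > 0 are the formula's core targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class InteractionTable:
    """Bipartite compound-target edge table with profile-level constants.

    ``n`` is the number of distinct compounds; ``g`` the average number of
    compounds per target (rows / distinct genes).
    """

    frame: pd.DataFrame  # columns: compound_id, gene[, herb]

    def __post_init__(self):
        df = self.frame
        if df.duplicated(subset=["compound_id", "gene"]).any():
            raise ValueError("duplicate (compound, gene) rows in interaction table")

    @property
    def n(self) -> int:
        return self.frame["compound_id"].nunique()

    @property
    def g(self) -> float:
        if self.frame.empty:
            return 0.0
        return len(self.frame) / self.frame["gene"].nunique()

    def restrict_to_herb(self, herb: str) -> "InteractionTable":
        if "herb" not in self.frame.columns:
            raise KeyError("interaction table has no herb column")
        mask = self.frame["herb"].fillna("").str.split(",").map(lambda hs: herb in hs)
        sub = self.frame[mask].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"unknown herb id {herb!r}")
        return InteractionTable(sub)

    def herbs(self) -> list[str]:
        if "herb" not in self.frame.columns:
            return []
        out: set[str] = set()
        for hs in self.frame["herb"].fillna(""):
            out.update(h for h in str(hs).split(",") if h)
        return sorted(out)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"require 0 <= p <= 1, got p={p}")
    if k == 0:
        return 1.0
    # survival function is P(X > k-1) = P(X >= k), numerically stable
    return float(stats.binom.sf(k - 1, n, p))


def score_targets(
    table: InteractionTable,
    alpha: float = 0.05,
    gs_pvalue: str = "adjusted",
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Score every gene in the profile; returns one row per gene.

    Columns: gene, k, pvalue, adj_pvalue, rank, gs. The significance gate
    and the GS numerator use the BH-adjusted p-value by default
    (``gs_pvalue="raw"`` switches both to the raw tail probability). Ranks
    are 1-based competition (min) ranks over ascending gating p-values.
    """
    if table.frame.empty:
        raise ValueError("empty interaction table")
    if gs_pvalue not in ("adjusted", "raw"):
        raise ValueError("gs_pvalue must be 'adjusted' or 'raw'")
    n = table.n
    p_null = table.g / n
    counts = table.frame.groupby("gene")["compound_id"].nunique().sort_index()
    pvals = np.array([binomial_tail(int(k), n, p_null) for k in counts])
    adj = multipletests(pvals, method="fdr_bh")[1]
    gate = adj if gs_pvalue == "adjusted" else pvals
    rank = pd.Series(gate).rank(method="min", ascending=True).astype(int).to_numpy()
    with np.errstate(divide="ignore"):
        numer = -np.log(np.maximum(gate, np.finfo(float).tiny)) / np.log(log_base)
    gs = np.where(gate <= alpha, numer / rank, 0.0)
    return pd.DataFrame(
        {
            "gene": counts.index,
            "k": counts.to_numpy(dtype=int),
            "pvalue": pvals,
            "adj_pvalue": adj,
            "rank": rank,
            "gs": gs,
        }
    ).reset_index(drop=True)


def score_compounds(table: InteractionTable, target_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-compound CS = mean GS over the compound's targets (zeros included)."""
    gs_map = dict(zip(target_scores["gene"], target_scores["gs"]))
    missing = set(table.frame["gene"]) - set(gs_map)
    if missing:
        raise KeyError(f"genes missing from target scores: {sorted(missing)[:5]}")
    rows = []
    for cid, sub in table.frame.groupby("compound_id"):
        genes = sub["gene"].unique()
        cs = float(np.mean([gs_map[g] for g in genes]))
        rows.append({"compound_id": cid, "n_targets": len(genes), "cs": cs})
    return (
        pd.DataFrame(rows)
        .sort_values(["cs", "compound_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def select_core_targets(target_scores: pd.DataFrame) -> frozenset[str]:
    """Genes with GS > 0 — the formula's core targets."""
    return frozenset(target_scores.loc[target_scores["gs"] > 0, "gene"])


def select_representative_compounds(
    compound_scores: pd.DataFrame, table: InteractionTable, core: frozenset[str] | set[str]
) -> list[str]:
    """Shortest CS-descending prefix of compounds whose targets cover ``core``.

    Ties in CS are broken lexicographically by compound id so the prefix is
    reproducible. Compounds inside the prefix that add no new coverage are
    kept: the selection is a ranked prefix, not a minimal set cover.
    """
    core = frozenset(core)
    if not core:
        return []
    ranked = compound_scores.sort_values(
        ["cs", "compound_id"], ascending=[False, True]
    )["compound_id"].tolist()
    targets_of = {
        cid: frozenset(sub["gene"]) for cid, sub in table.frame.groupby("compound_id")
    }
    covered: set[str] = set()
    for i, cid in enumerate(ranked, start=1):
        covered |= targets_of.get(cid, frozenset()) & core
        if covered >= core:
            return ranked[:i]
    raise ValueError(
        f"core targets not coverable from table; uncovered: {sorted(core - covered)}"
    )


def herb_core_targets(
    table: InteractionTable, herb: str, top_n: int = 30, alpha: float = 0.05
) -> frozenset[str]:
    """Top ``top_n`` GS-ranked targets of one herb's compound sub-profile.

    Only genes with GS > 0 qualify; ties in GS break by ascending gene
    symbol. Fewer than ``top_n`` qualifying genes returns just those.
    """
    sub = table.restrict_to_herb(herb)
    scores = score_targets(sub, alpha=alpha)
    pos = scores[scores["gs"] > 0].sort_values(
        ["gs", "gene"], ascending=[False, True]
    )
    return frozenset(pos["gene"].head(top_n))


def herb_ranked_targets(
    table: InteractionTable, herb: str, top_n: int = 30, alpha: float = 0.05
) -> list[str]:
    """Like :func:`herb_core_targets` but preserving the GS-descending order."""
    sub = table.restrict_to_herb(herb)
    scores = score_targets(sub, alpha=alpha)
    pos = scores[scores["gs"] > 0].sort_values(["gs", "gene"], ascending=[False, True])
    return pos["gene"].head(top_n).tolist()


def target_overlap(set_a, set_b) -> tuple[frozenset[str], int]:
    """Case-normalised intersection of two gene sets, with its size."""
    a = frozenset(str(g).upper() for g in set_a)
    b = frozenset(str(g).upper() for g in set_b)
    common = a & b
    return common, len(common)
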