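"""Readers and writers for the plain-text formats the pipeline exchanges.

All gene symbols are upper-cased on ingest so that identifiers coming from
different sources compare equal. Malformed lines raise with their line
number; silent data loss (dropped self-loops, duplicate edges) is counted
and logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ["mw", "alogp", "hba", "hbd", "psa", "rotb", "arom", "alerts"]


def _norm_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# interaction table (compound -> target)

def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a compound-target TSV with columns compound_id, gene[, herb].

    Returns a DataFrame with unique (compound_id, gene) rows; the optional
    ``herb`` column holds comma-separated herb ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["gene"] = df["gene"].map(_norm_gene)
    if "herb" not in df.columns:
        df["herb"] = ""
    before = len(df)
    df = df.drop_duplicates(subset=["compound_id", "gene"]).reset_index(drop=True)
    if len(df) < before:
        logger.info("read_interactions: dropped %d duplicate rows", before - len(df))
    return df


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI networks: TSV edge list and SIF

def read_ppi_edgelist(
    path: str | Path, score_threshold: float = 0.0
) -> nx.Graph:
    """Read an undirected PPI from a TSV edge list (gene_a, gene_b[, score]).

    Edges with score <= ``score_threshold`` are excluded when a score column
    is present, mirroring confidence filtering of HIPPIE-style resources
    (default drops only zero-scored rows). Self-loops and duplicate edges
    are dropped with counts logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need at least two columns")
    g = nx.Graph()
    n_self, n_dup, n_filtered = 0, 0, 0
    has_score = len(cols) >= 3
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a, b = _norm_gene(row[0]), _norm_gene(row[1])
        if not a or not b:
            raise ValueError(f"{path}:{i}: empty gene symbol")
        if has_score:
            score = float(row[2])
            if score <= score_threshold:
                n_filtered += 1
                continue
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b, **({"score": score} if has_score else {}))
    if n_self or n_dup or n_filtered:
        logger.info(
            "read_ppi_edgelist: dropped %d self-loops, %d duplicates, %d low-score",
            n_self, n_dup, n_filtered,
        )
    return g


def write_ppi_edgelist(g: nx.Graph, path: str | Path) -> None:
    rows = []
    for a, b, data in sorted(g.edges(data=True)):
        rows.append({"gene_a": a, "gene_b": b, "score": data.get("score", 1.0)})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_sif(path: str | Path) -> nx.Graph:
    """Read a simple-interaction-format file (node <TAB> type <TAB> node...)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                g.add_node(_norm_gene(parts[0]))
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed SIF line")
            src = _norm_gene(parts[0])
            for tgt in parts[2:]:
                tgt = _norm_gene(tgt)
                if src != tgt:
                    g.add_edge(src, tgt)
    return g


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(g.edges()):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for n in sorted(nx.isolates(g)):
            fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {term_id: (description, gene set)}."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, desc, >=1 gene")
            term, desc = parts[0], parts[1]
            genes = frozenset(_norm_gene(p) for p in parts[2:] if p.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (desc, genes)
    return terms


def write_gmt(terms: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, genes = terms[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene lists, partitions, descriptors, truth JSON

def read_gene_set(path: str | Path) -> frozenset[str]:
    """Read one gene symbol per line (blank lines and '#' comments skipped)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(_norm_gene(line))
    return frozenset(genes)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_partition_table(path: str | Path) -> pd.DataFrame:
    """Read a module membership TSV with columns module_id, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"module_id", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: need columns module_id, gene")
    if df.empty:
        raise ValueError(f"{path}: empty partition file")
    df["gene"] = df["gene"].map(_norm_gene)
    return df.drop_duplicates().reset_index(drop=True)


def write_partition_table(modules: Iterable[Iterable[str]], path: str | Path) -> None:
    rows = []
    for i, module in enumerate(modules, start=1):
        for gene in sorted(module):
            rows.append({"module_id": f"M{i}", "gene": gene})
    pd.DataFrame(rows, columns=["module_id", "gene"]).to_csv(path, sep="\t", index=False)


def read_descriptors(path: str | Path) -> pd.DataFrame:
    """Read a descriptor TSV (compound_id, herb, mw, alogp, hba, hbd, psa, rotb, arom, alerts)."""
    df = pd.read_csv(path, sep="\t")
    missing = ({"compound_id"} | set(DESCRIPTOR_COLUMNS)) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "herb" not in df.columns:
        df["herb"] = ""
    return df


def write_descriptors(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True, default=sorted)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
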