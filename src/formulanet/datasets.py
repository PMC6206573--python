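"""Bundled worked-example data.

Small published reference tables for the Ban-Xia-Xie-Xin-Tang (BXXXT)
seven-herb formula study that motivated this package: the 140-gene core
target list, the approved-drug target rows for its three indication
diseases (colitis, diabetes mellitus, gastric cancer), the printed
module-detector (Q, BHI) panel, and the 8-gene worked toy network used to
illustrate the CN/SPEN/NEN layer constructions.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from . import io


def _data_path(name: str):
    return resources.files("formulanet").joinpath(f"data/{name}")


def load_toy_ppi() -> nx.Graph:
    """The 8-gene illustrative network (A-H); A and B are the usual query."""
    with resources.as_file(_data_path("toy_ppi.sif")) as p:
        return io.read_sif(p)


def load_core_targets() -> frozenset[str]:
    """The 140 published core formula targets (gene symbols)."""
    with resources.as_file(_data_path("bxxxt_core_targets.txt")) as p:
        return io.read_gene_set(p)


def load_drug_target_table() -> pd.DataFrame:
    """Approved-drug target rows per disease (drug_id, drug, disease, targets)."""
    with resources.as_file(_data_path("bxxxt_drug_targets.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def drug_targets_by_disease() -> dict[str, frozenset[str]]:
    """Distinct drug-target gene symbols pooled per disease."""
    df = load_drug_target_table()
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        genes = {g.strip().upper() for g in str(row.targets).split(",")}
        out.setdefault(row.disease, set()).update(genes)
    return {k: frozenset(v) for k, v in out.items()}


def load_module_method_scores() -> pd.DataFrame:
    """Published per-detector module panel (method, modules, module_size, q, bhi)."""
    with resources.as_file(_data_path("module_method_scores.tsv")) as p:
        return pd.read_csv(p, sep="\t")
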