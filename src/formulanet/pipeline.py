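"""End-to-end orchestration: screen -> score -> layers -> enrichment ->
proximity -> modules -> herb roles, driven by one validated config.

Every stage writes its table under the output directory and logs its
counts (compounds filtered, queries dropped, pairs excluded) so silent
data loss is impossible; a run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem, enrich, io, layers, modules, proximity, targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    descriptors: str
    interactions: str
    ppi: str
    disease_genes: dict[str, str]  # label -> gene-list path
    gmt: str
    partitions: dict[str, str] = field(default_factory=dict)  # label -> partition TSV
    out_dir: str = "formulanet_out"
    qed_cutoff: float = 0.25
    alpha_targets: float = 0.05
    alpha_enrich: float = 0.01
    spen_max_len: int = 3
    gamma: float = 0.7
    tol: float = 1e-10
    n_perm: int = 2000
    herb_top_n: int = 30
    aucc_top_n: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 <= self.qed_cutoff <= 1.0:
            raise ValueError("qed_cutoff must lie in [0, 1]")
        for name in ("alpha_targets", "alpha_enrich"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.spen_max_len < 1 or self.n_perm < 1 or self.herb_top_n < 1:
            raise ValueError("spen_max_len, n_perm and herb_top_n must be positive")
        paths = [self.descriptors, self.interactions, self.ppi, self.gmt]
        paths += list(self.disease_genes.values()) + list(self.partitions.values())
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the machine-readable summary dict.

    Raises with the failing stage's name on any error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rwr_cfg = proximity.RWRConfig(gamma=config.gamma, tol=config.tol)
    summary: dict = {"parameters": dataclasses.asdict(config)}

    stage = "screen"
    try:
        desc = io.read_descriptors(config.descriptors)
        records = chem.records_from_frame(desc)
        params = chem.load_default_params()
        for r in records:
            chem.compute_qed(r, params)
        retained, rejected = chem.filter_druglike(records, cutoff=config.qed_cutoff)
        chem.qed_table(records).to_csv(out / "qed.tsv", sep="\t", index=False)
        retained_ids = {r.compound_id for r in retained}
        logger.info("screen: %d/%d compounds pass QED > %s", len(retained), len(records), config.qed_cutoff)
        summary["screen"] = {"n_compounds": len(records), "n_retained": len(retained)}

        stage = "score_targets"
        inter = io.read_interactions(config.interactions)
        inter = inter[inter["compound_id"].isin(retained_ids)].reset_index(drop=True)
        if inter.empty:
            raise ValueError("no interactions left after drug-likeness screening")
        table = targets.InteractionTable(inter)
        tscores = targets.score_targets(table, alpha=config.alpha_targets)
        cscores = targets.score_compounds(table, tscores)
        core = targets.select_core_targets(tscores)
        reps = targets.select_representative_compounds(cscores, table, core)
        tscores.to_csv(out / "target_scores.tsv", sep="\t", index=False)
        cscores.to_csv(out / "compound_scores.tsv", sep="\t", index=False)
        io.write_gene_set(core, out / "core_targets.txt")
        summary["targets"] = {
            "n_core": len(core),
            "n_representative": len(reps),
            "representative_compounds": reps,
        }

        stage = "layers"
        ppi = io.read_ppi_edgelist(config.ppi)
        disease_sets = {
            label: io.read_gene_set(path) for label, path in config.disease_genes.items()
        }
        layer_sets = {"formula": layers.build_layers(ppi, core, max_len=config.spen_max_len)}
        for label, genes in disease_sets.items():
            layer_sets[label] = layers.build_layers(ppi, genes, max_len=config.spen_max_len)
        layers.stats_panel(layer_sets).to_csv(out / "network_stats.tsv", sep="\t", index=False)
        sim_rows = []
        for label in disease_sets:
            for level in ("cn", "spen", "nen"):
                sim = layers.node_similarity(
                    getattr(layer_sets["formula"], level), getattr(layer_sets[label], level)
                )
                sim_rows.append({"disease": label, "level": level.upper(), "similarity": sim})
        sim_df = pd.DataFrame(sim_rows)
        sim_df.to_csv(out / "layer_similarity.tsv", sep="\t", index=False)
        for label, ls in layer_sets.items():
            io.write_sif(ls.spen, out / f"spen_{label}.sif")
        summary["layers"] = {
            "similarity": sim_rows,
            "dropped_queries": {k: sorted(v.dropped_queries) for k, v in layer_sets.items()},
        }

        stage = "enrichment"
        collection = enrich.AnnotationCollection.from_gmt(io.read_gmt(config.gmt))
        formula_rows = enrich.enrich(core, collection, alpha=config.alpha_enrich)
        formula_rows.to_csv(out / "enrichment_formula.tsv", sep="\t", index=False)
        disease_rows = {}
        for label, genes in disease_sets.items():
            rows = enrich.enrich(genes, collection, alpha=config.alpha_enrich)
            rows.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False)
            disease_rows[label] = rows
        aucc_df = enrich.aucc_ranking(formula_rows, disease_rows, n_max=config.aucc_top_n)
        aucc_df.to_csv(out / "enrichment_aucc.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "n_significant_formula": int(formula_rows["significant"].sum()),
            "aucc": aucc_df.to_dict(orient="records"),
        }

        stage = "proximity"
        prox_rows = []
        for i, (label, genes) in enumerate(sorted(disease_sets.items())):
            res = proximity.permutation_test(
                ppi, core, genes,
                n_perm=config.n_perm, seed=config.seed + i, config=rwr_cfg,
            )
            frame = res.summary()
            frame.insert(0, "disease", label)
            prox_rows.append(frame)
        prox_df = pd.concat(prox_rows, ignore_index=True)
        prox_df.to_csv(out / "proximity.tsv", sep="\t", index=False)
        summary["proximity"] = prox_df.to_dict(orient="records")

        stage = "modules"
        formula_spen = layer_sets["formula"].spen
        parts = {
            "greedy": modules.detect_modules_greedy(formula_spen),
            "density": modules.detect_modules_density(formula_spen),
        }
        for label, path in config.partitions.items():
            parts[label] = modules.load_partition(path, net=formula_spen)
        comparison = modules.compare_partitions(formula_spen, parts, collection)
        comparison.to_csv(out / "module_comparison.tsv", sep="\t", index=False)
        best = comparison.iloc[0]["method"]
        first_disease = sorted(disease_sets)[0]
        assoc = modules.module_disease_association(
            parts[best], disease_sets[first_disease], ppi, config=rwr_cfg
        )
        assoc.to_csv(out / "module_disease_association.tsv", sep="\t", index=False)
        io.write_partition_table(parts[best].modules, out / "best_partition.tsv")
        summary["modules"] = {
            "comparison": comparison.to_dict(orient="records"),
            "best": str(best),
        }

        stage = "herb_roles"
        herb_lists = {}
        for herb in table.herbs():
            ranked = targets.herb_ranked_targets(
                table, herb, top_n=config.herb_top_n, alpha=config.alpha_targets
            )
            if ranked:
                herb_lists[herb] = ranked
        if herb_lists:
            curves, ranking = proximity.herb_rwr_curves(
                herb_lists, disease_sets[first_disease], ppi, config=rwr_cfg
            )
            ranking.to_csv(out / "herb_ranking.tsv", sep="\t", index=False)
            curve_df = pd.DataFrame(
                [
                    {"herb": h, "n": i + 1, "cumulative_score": v}
                    for h, curve in curves.items()
                    for i, v in enumerate(curve)
                ]
            )
            curve_df.to_csv(out / "herb_curves.tsv", sep="\t", index=False)
            summary["herb_roles"] = ranking.to_dict(orient="records")
        else:
            summary["herb_roles"] = []
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def simulate_inputs(out_dir: str | Path, seed: int = 0, n_nodes: int = 500,
                    n_compounds: int = 200, n_core: int = 50, lift: float = 8.0,
                    n_modules: int = 5, module_size: int = 10) -> PipelineConfig:
    """Generate a complete synthetic input bundle and matching config.

    The compound-target universe is drawn from the PPI's genes so every
    stage connects; disease gene sets are planted near the core targets
    ('near') plus one uniform control ('random').
    """
    from . import synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ppi, ppi_truth = synthetic.gen_ppi(
        n_nodes, mean_degree=6.0, n_planted_modules=n_modules,
        module_size=module_size, seed=seed,
    )
    io.write_ppi_edgelist(ppi, out / "ppi.tsv")
    inter, target_truth = synthetic.gen_compound_targets(
        n_compounds, n_targets=n_nodes, n_core=n_core, lift=lift, seed=seed + 1
    )
    io.write_interactions(inter, out / "interactions.tsv")
    # descriptor compound ids C0001.. align with the interaction table ids
    desc, desc_truth = synthetic.gen_descriptors(n_compounds, druglike_fraction=0.8, seed=seed + 2)
    io.write_descriptors(desc, out / "descriptors.tsv")
    anchor = sorted(target_truth.planted_core_targets)
    near, _ = synthetic.gen_disease_genes(ppi, anchor, size=25, proximity_mode="near", seed=seed + 3)
    rand, _ = synthetic.gen_disease_genes(ppi, anchor, size=25, proximity_mode="random", seed=seed + 4)
    io.write_gene_set(near, out / "disease_near.txt")
    io.write_gene_set(rand, out / "disease_random.txt")
    ann = synthetic.gen_annotations(
        ppi_truth.planted_modules, n_noise_terms=20,
        universe=set(ppi.nodes), seed=seed + 5,
    )
    io.write_gmt(ann.terms, out / "annotations.gmt")
    io.write_truth(
        {
            "ppi": ppi_truth.to_dict(),
            "targets": target_truth.to_dict(),
            "descriptors": desc_truth.to_dict(),
        },
        out / "truth.json",
    )
    return PipelineConfig(
        descriptors=str(out / "descriptors.tsv"),
        interactions=str(out / "interactions.tsv"),
        ppi=str(out / "ppi.tsv"),
        disease_genes={"near": str(out / "disease_near.txt"), "random": str(out / "disease_random.txt")},
        gmt=str(out / "annotations.gmt"),
        out_dir=str(out / "results"),
        seed=seed,
    )
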