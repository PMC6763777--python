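"""End-to-end pipeline runner: simulate/load -> pathway activities ->
similarity network -> propagation -> significance -> evaluation.

Each stage writes its outputs in the standard text formats plus a manifest
(JSON: stage name, inputs, parameters, sha256 of outputs) so a run is fully
reproducible and any stage can be replaced by a precomputed artifact — in
particular, a run may start from an existing edge-list network and skip the
construction stages entirely.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import io_formats as io
from .drug_screen import filter_drugs
from .evaluation import loocv_auroc
from .network_propagation import RwrConfig, rwr
from .pathway_activity import (
    SsgseaConfig,
    build_mirna_pathways,
    pathway_activity_matrix,
    remove_redundant_pathways,
)
from .significance import permutation_pvalues
from .similarity_network import (
    drug_drug_similarity,
    merge_networks,
    pathway_drug_correlation,
    select_edges,
)
from .synthetic_data import SyntheticPanelConfig, generate_panel

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs, params, outputs) -> None:
    manifest = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def simulate_stage(cfg: SyntheticPanelConfig, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    mrna, mirna, sets, targets, acts, truth = generate_panel(cfg)
    paths = {
        "mrna": outdir / "mrna_expression.tsv",
        "mirna": outdir / "mirna_expression.tsv",
        "pathways": outdir / "pathways.gmt",
        "mirna_targets": outdir / "mirna_targets.tsv",
        "drug_activity": outdir / "drug_activity.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "seeds": outdir / "seeds.txt",
    }
    io.write_matrix(mrna, paths["mrna"], id_label="gene_id")
    io.write_matrix(mirna, paths["mirna"], id_label="mirna_id")
    io.write_gmt(sets, paths["pathways"])
    io.write_mirna_target_map(targets, paths["mirna_targets"])
    io.write_matrix(acts, paths["drug_activity"], id_label="drug_id")
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "module_of": truth.module_of,
                "signature_pathways": {
                    str(m): sorted(s) for m, s in truth.signature_pathways.items()
                },
                "seed_module": truth.seed_module,
                "tissue_of": truth.tissue_of,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    module_drugs = truth.module_drugs(truth.seed_module)
    paths["seeds"].write_text("\n".join(module_drugs[:3]) + "\n")
    _write_manifest(
        outdir, "simulate", {}, {"config": cfg.__dict__}, paths.values()
    )
    return paths


def build_network_stage(
    mrna_activity: io.ExpressionMatrix,
    mirna_activity: io.ExpressionMatrix | None,
    drugs: io.DrugActivityMatrix,
    r_min: float = 0.7,
    fdr_max: float = 0.05,
    top_frac: float = 0.0005,
    edge_rule: str = "union",
) -> io.DrugSimilarityNetwork:
    """Similarity networks per pathway level (mRNA, optionally miRNA),
    merged by edge union."""
    levels = [mrna_activity] + ([mirna_activity] if mirna_activity is not None else [])
    nets = []
    for activity in levels:
        pd_corr = pathway_drug_correlation(activity, drugs)
        dd = drug_drug_similarity(pd_corr)
        nets.append(select_edges(dd, r_min, fdr_max, top_frac, edge_rule))
    net = nets[0]
    for other in nets[1:]:
        net = merge_networks(net, other)
    return net


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; returns a summary dict.

    ``config`` keys (all optional unless noted):
      simulate: SyntheticPanelConfig fields — generate a synthetic panel
      inputs: paths for mrna/mirna expression, pathways GMT, mirna_targets,
              drug_activity, network (precomputed edge list), seeds (required)
      drug_filter: {enabled, min_observations}
      pathway: SsgseaConfig fields + {mirna_alpha, deredundancy_threshold}
      network: {r_min, fdr_max, top_frac, edge_rule}
      rwr: RwrConfig fields
      significance: {enabled, n_perm, rng_seed, p_estimator, null_model}
      evaluation: {enabled, negatives}
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    inputs = dict(config.get("inputs", {}))
    summary: dict = {"stages": []}

    def stage_done(name):
        summary["stages"].append(name)
        logger.info("stage %s done at %.1fs", name, time.time() - t0)

    if "simulate" in config:
        sim_cfg = SyntheticPanelConfig(**config["simulate"])
        paths = simulate_stage(sim_cfg, outdir)
        for key in ("mrna", "mirna", "pathways", "mirna_targets", "drug_activity"):
            inputs.setdefault(key, paths[key])
        inputs.setdefault("seeds", paths["seeds"])
        stage_done("simulate")

    if "seeds" not in inputs:
        raise ValueError("config must name a seed list (inputs.seeds)")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r}: {path} does not exist")

    rwr_cfg = RwrConfig(**config.get("rwr", {}))

    if "network" in inputs:
        net = io.read_edge_list(inputs["network"])
    else:
        for key in ("mrna", "pathways", "drug_activity"):
            if key not in inputs:
                raise ValueError(f"network construction requires inputs.{key}")
        drugs = io.read_drug_activity_matrix(inputs["drug_activity"])
        filt = config.get("drug_filter", {})
        if filt.get("enabled", False):
            drugs = filter_drugs(drugs, filt.get("min_observations", 4))
            io.write_matrix(drugs, outdir / "drug_activity_filtered.tsv",
                            id_label="drug_id")
            stage_done("filter-drugs")

        pw_cfg = config.get("pathway", {})
        ssgsea = SsgseaConfig(weight_exponent=pw_cfg.get("weight_exponent", 0.25))
        mrna = io.read_expression_matrix(inputs["mrna"])
        sets = io.read_gmt(inputs["pathways"])
        thresh = pw_cfg.get("deredundancy_threshold")
        if thresh is not None:
            sets = remove_redundant_pathways(sets, thresh)
        mrna_activity = pathway_activity_matrix(mrna, sets, ssgsea)
        io.write_matrix(mrna_activity, outdir / "mrna_pathway_activity.tsv",
                        id_label="pathway")

        mirna_activity = None
        if "mirna" in inputs and "mirna_targets" in inputs:
            mirna = io.read_expression_matrix(inputs["mirna"])
            targets = io.read_mirna_target_map(inputs["mirna_targets"])
            universe = set(mrna.feature_ids) & (
                set().union(*(sets[s] for s in sets))
                | set().union(*targets.values())
            )
            mirna_sets = build_mirna_pathways(
                targets, sets, universe, pw_cfg.get("mirna_alpha", 0.05)
            )
            if len(mirna_sets):
                io.write_gmt(mirna_sets, outdir / "mirna_pathways.gmt")
                mirna_activity = pathway_activity_matrix(mirna, mirna_sets, ssgsea)
                io.write_matrix(
                    mirna_activity, outdir / "mirna_pathway_activity.tsv",
                    id_label="pathway",
                )
        stage_done("pathway-activity")

        net_cfg = config.get("network", {})
        net = build_network_stage(
            mrna_activity,
            mirna_activity,
            drugs,
            r_min=net_cfg.get("r_min", 0.7),
            fdr_max=net_cfg.get("fdr_max", 0.05),
            top_frac=net_cfg.get("top_frac", 0.0005),
            edge_rule=net_cfg.get("edge_rule", "union"),
        )
        stage_done("build-network")
    net_path = outdir / "network.tsv"
    io.write_edge_list(net, net_path)

    seeds = io.read_seed_set(inputs["seeds"], net)
    sig_cfg = config.get("significance", {})
    if sig_cfg.get("enabled", True):
        table = permutation_pvalues(
            net,
            seeds,
            rwr_cfg,
            n_perm=sig_cfg.get("n_perm", 1000),
            rng_seed=sig_cfg.get("rng_seed", 0),
            p_estimator=sig_cfg.get("p_estimator", "literal"),
            null_model=sig_cfg.get("null_model", "rewire"),
        )
        stage_done("significance")
    else:
        table = rwr(net, seeds, rwr_cfg)
        stage_done("prioritize")
    ranked_path = outdir / "ranked.tsv"
    io.write_score_table(table, ranked_path)

    eval_cfg = config.get("evaluation", {})
    roc_path = None
    if eval_cfg.get("enabled", True) and len(seeds) >= 2:
        roc, _ = loocv_auroc(
            net, seeds, rwr_cfg, negatives=eval_cfg.get("negatives", "pooled")
        )
        roc_path = outdir / "roc.tsv"
        roc.to_frame().to_csv(roc_path, sep="\t", index=False)
        summary["auroc"] = roc.auroc
        stage_done("evaluate")

    outputs = [net_path, ranked_path] + ([roc_path] if roc_path else [])
    _write_manifest(
        outdir,
        "pipeline",
        inputs,
        {
            "rwr": rwr_cfg.__dict__,
            "network": config.get("network", {}),
            "significance": sig_cfg,
            "evaluation": eval_cfg,
        },
        outputs,
    )
    summary.update(
        {
            "network_nodes": net.n_nodes,
            "network_edges": net.n_edges,
            "n_seeds": len(seeds),
            "outputs": [str(p) for p in outputs],
        }
    )
    return summary
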