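"""Synthetic cell-line panels with planted drug-module structure.

The generator emulates a small NCI-60-like screen: samples (cell lines)
belong to tissues of origin; each pathway has a latent activity that is a
tissue-level baseline plus per-sample noise; member genes (and member
miRNAs) co-vary with their pathway's latent activity so single-sample
enrichment recovers it; and drugs in a planted functional module couple
their activity vectors to the module's signature pathways:

    a_d[s] = beta * sum_{P in signature(module(d))} z_P[s] + Normal(0, sigma)

Uncoupled (null) drugs are pure noise. Within-module drugs therefore share
pathway–drug correlation profiles, so the similarity-network construction
should place them in one neighbourhood and the walk should recover held-out
module members from seeded ones. All randomness flows from one rng_seed;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    DrugActivityMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)

TISSUES = ["BR", "CNS", "CO", "LC", "LE", "ME", "OV", "PR", "RE"]


@dataclass
class SyntheticPanelConfig:
    """Panel shape and planted-signal strength.

    n_samples=60 cell lines over n_tissues=9 tissues mirrors the NCI-60
    layout. beta (pathway_coupling_strength) scales how strongly a module
    drug's activity follows its signature pathways; noise_sd is the
    per-sample Gaussian noise on both pathway activities and drug
    activities. Defaults plant 4 modules of 5 drugs plus 20 null drugs
    over 30 pathways with beta=2, sigma=0.5.
    """

    n_samples: int = 60
    n_tissues: int = 9
    n_genes: int = 300
    n_mirnas: int = 60
    n_pathways: int = 30
    n_drugs: int = 40
    n_drug_modules: int = 4
    drugs_per_module: int = 5
    pathways_per_module: int = 2
    pathway_coupling_strength: float = 2.0  # beta
    noise_sd: float = 0.5                   # sigma
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.pathway_coupling_strength < 0:
            raise ValueError("pathway_coupling_strength must be nonnegative")
        if self.n_drug_modules * self.drugs_per_module > self.n_drugs:
            raise ValueError("modules do not fit into n_drugs")
        if self.n_drug_modules * self.pathways_per_module > self.n_pathways:
            raise ValueError("module signatures do not fit into n_pathways")
        if self.n_tissues > self.n_samples:
            raise ValueError("more tissues than samples")


@dataclass
class GroundTruth:
    """Planted structure: drug -> module, module -> signature pathways."""

    module_of: dict[str, int]
    signature_pathways: dict[int, frozenset[str]]
    seed_module: int = 0
    tissue_of: dict[str, str] = field(default_factory=dict)

    def module_drugs(self, module: int) -> list[str]:
        return sorted(d for d, m in self.module_of.items() if m == module)


def generate_panel(
    cfg: SyntheticPanelConfig,
) -> tuple[
    ExpressionMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    dict[str, frozenset[str]],
    DrugActivityMatrix,
    GroundTruth,
]:
    """Generate (mRNA, miRNA, pathway GMT sets, miRNA target map, drug
    activities, ground truth) for one synthetic panel."""
    rng = np.random.default_rng(cfg.rng_seed)
    samples = [f"CL{i:02d}" for i in range(cfg.n_samples)]
    tissue_names = (TISSUES * ((cfg.n_tissues // len(TISSUES)) + 1))[: cfg.n_tissues]
    tissue_of = {s: tissue_names[i % cfg.n_tissues] for i, s in enumerate(samples)}
    tissue_index = {s: i % cfg.n_tissues for i, s in enumerate(samples)}

    pathways = [f"PWY{i:02d}" for i in range(cfg.n_pathways)]
    # latent pathway activity: tissue baseline + per-sample noise
    baseline = rng.normal(0.0, 1.0, size=(cfg.n_pathways, cfg.n_tissues))
    z = np.empty((cfg.n_pathways, cfg.n_samples))
    for j, s in enumerate(samples):
        z[:, j] = baseline[:, tissue_index[s]]
    z += rng.normal(0.0, cfg.noise_sd, size=z.shape)

    # genes: a disjoint member block per pathway, remainder background noise
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    genes_per_pathway = max(3, cfg.n_genes // (2 * cfg.n_pathways))
    if genes_per_pathway * cfg.n_pathways > cfg.n_genes:
        raise ValueError("n_genes too small for the pathway membership blocks")
    sets: dict[str, frozenset[str]] = {}
    expr = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    for p_idx, pwy in enumerate(pathways):
        members = genes[p_idx * genes_per_pathway : (p_idx + 1) * genes_per_pathway]
        sets[pwy] = frozenset(members)
        block = slice(p_idx * genes_per_pathway, (p_idx + 1) * genes_per_pathway)
        expr[block] = z[p_idx] + rng.normal(
            0.0, cfg.noise_sd, size=(genes_per_pathway, cfg.n_samples)
        )
    gene_sets = GeneSetCollection(sets)

    # miRNAs cycle over pathways: expression follows the pathway latent and
    # targets are that pathway's member genes plus random background genes
    mirnas = [f"MIR{i:03d}" for i in range(cfg.n_mirnas)]
    mirna_expr = np.empty((cfg.n_mirnas, cfg.n_samples))
    target_map: dict[str, frozenset[str]] = {}
    background = genes[genes_per_pathway * cfg.n_pathways :]
    for m_idx, mir in enumerate(mirnas):
        p_idx = m_idx % cfg.n_pathways
        mirna_expr[m_idx] = z[p_idx] + rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
        extra = (
            rng.choice(background, size=min(3, len(background)), replace=False)
            if background
            else []
        )
        target_map[mir] = frozenset(sets[pathways[p_idx]]) | frozenset(extra)

    # drugs: module drugs couple to their signature pathways, rest are noise
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    acts = rng.normal(0.0, 1.0, size=(cfg.n_drugs, cfg.n_samples))
    module_of: dict[str, int] = {}
    signature: dict[int, frozenset[str]] = {}
    beta = cfg.pathway_coupling_strength
    for m in range(cfg.n_drug_modules):
        sig_idx = range(
            m * cfg.pathways_per_module, (m + 1) * cfg.pathways_per_module
        )
        signature[m] = frozenset(pathways[i] for i in sig_idx)
        sig_sum = z[list(sig_idx)].sum(axis=0)
        for k in range(cfg.drugs_per_module):
            d_idx = m * cfg.drugs_per_module + k
            module_of[drugs[d_idx]] = m
            acts[d_idx] = beta * sig_sum + rng.normal(
                0.0, cfg.noise_sd, cfg.n_samples
            )

    mrna = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    mirna = ExpressionMatrix(pd.DataFrame(mirna_expr, index=mirnas, columns=samples))
    activity = DrugActivityMatrix(pd.DataFrame(acts, index=drugs, columns=samples))
    truth = GroundTruth(
        module_of=module_of,
        signature_pathways=signature,
        seed_module=0,
        tissue_of=tissue_of,
    )
    return mrna, mirna, gene_sets, target_map, activity, truth
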