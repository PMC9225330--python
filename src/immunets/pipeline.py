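"""End-to-end orchestration of the network/biomarker pipeline.

``PipelineConfig`` carries every stage threshold with the protocol's
defaults (ANOVA q < 0.01; edge r > 0.9, q < 0.01; at most 2 networks per
gene; DE q < 0.05 at 2-fold with the (1, 25%) low-expression filter;
enrichment and survival screens at q < 0.05; GMM cardinality up to 5)
plus the seeds of every stochastic stage. ``run_pipeline`` executes the
full synthetic-data study: simulate the compendium and cohorts, build
the per-cell-type networks, account for overlap, derive focus networks,
run discovery and validation differential expression, assemble the
biomarker panel, and evaluate it in a survival cohort (univariate screen
then stepwise Cox with a held-out risk split). Outputs are written as
TSV/JSON under an output directory together with a manifest of stage
counts, so a re-run with identical config reproduces identical counts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import focus as focus_mod
from . import networks as net_mod
from . import overlap as overlap_mod
from . import survival as surv_mod
from . import synthetic as syn
from .io import config_hash, write_expression
from .matrix import ExpressionMatrix


@dataclass
class PipelineConfig:
    # network construction
    anova_q: float = 0.01
    r_min: float = 0.9
    edge_q: float = 0.01
    # overlap / specificity
    max_networks: int = 2
    # focus networks
    n_permutations: int = 200
    enrich_q: float = 0.05
    # differential expression
    de_q: float = 0.05
    fc_min: float = 2.0
    filter_min_count: float = 1.0
    filter_min_proportion: float = 0.25
    # survival
    screen_q: float = 0.05
    k_max: int = 5
    train_fraction: float = 255 / 390
    # synthetic-study design
    n_cell_types: int = 5
    states_per_type: int = 3
    samples_per_state: int = 10
    n_background_genes: int = 300
    n_modules_per_cell_type: int = 1
    module_size: int = 8
    module_r: float = 0.95
    noise_sd: float = 1.0
    cohort_n_response: int = 15
    cohort_n_nonresponse: int = 15
    cohort_fold: float = 4.0
    cohort_dispersion: float = 0.5
    n_biomarkers: int = 10
    survival_n: int = 390
    survival_beta: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("anova_q", 0, 1), ("edge_q", 0, 1), ("de_q", 0, 1),
            ("enrich_q", 0, 1), ("screen_q", 0, 1),
            ("filter_min_proportion", 0, 1), ("train_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}); got {v}")
        if not -1 < self.r_min < 1:
            raise ValueError("r_min must be in (-1, 1)")
        if self.max_networks < 1 or self.k_max < 1:
            raise ValueError("max_networks and k_max must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _planted_design(config: PipelineConfig):
    """Compendium spec with one module per cell type, plus planted biomarkers."""
    modules = []
    gene_counter = 0
    cell_types = [f"CT{i + 1}" for i in range(config.n_cell_types)]
    for ct in cell_types:
        for _ in range(config.n_modules_per_cell_type):
            genes = tuple(
                f"MG{gene_counter + j + 1:04d}" for j in range(config.module_size)
            )
            gene_counter += config.module_size
            modules.append(
                syn.PlantedModule(
                    genes, (ct,), within_module_correlation=config.module_r
                )
            )
    return syn.CompendiumSpec(
        n_cell_types=config.n_cell_types,
        states_per_type=config.states_per_type,
        samples_per_state=config.samples_per_state,
        n_background_genes=config.n_background_genes,
        modules=tuple(modules),
        noise_sd=config.noise_sd,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full synthetic study; returns the manifest dictionary.

    Stage order: simulate -> build networks -> overlap/specificity ->
    focus networks -> discovery & validation DE -> biomarker panel ->
    survival screen, stepwise Cox, held-out risk split. Every stage's
    output counts enter the manifest; if ``out_dir`` is given, stage
    tables are also written there.
    """
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config.to_dict()), "stages": {}}

    # --- stage 1: compendium + networks -------------------------------
    comp_spec = _planted_design(config)
    compendium, truth = syn.simulate_compendium(comp_spec)
    manifest["stages"]["compendium"] = {
        "n_genes": compendium.n_genes,
        "n_samples": compendium.n_samples,
    }
    networks = net_mod.build_immunets(
        compendium, anova_q=config.anova_q, r_min=config.r_min, q_max=config.edge_q
    )
    summary = overlap_mod.network_summary(networks)
    manifest["stages"]["networks"] = {
        "n_networks": len(networks),
        "nodes": {r["network"]: int(r["n_nodes"]) for _, r in summary.iterrows()},
        "edges": {r["network"]: int(r["n_edges"]) for _, r in summary.iterrows()},
    }

    # --- stage 2: overlap + specificity filter ------------------------
    table = overlap_mod.membership(networks)
    overlap_matrix = overlap_mod.unique_overlap_matrix(table)
    selected = overlap_mod.specificity_filter(table, config.max_networks)
    manifest["stages"]["overlap"] = {
        "union_genes": table.union_size,
        "selected_genes": len(selected),
    }

    # --- stage 3: focus networks --------------------------------------
    ref_edges = syn.simulate_reference_network(
        truth,
        extra_genes=[f"BG{i + 1:05d}" for i in range(config.n_background_genes)],
        seed=config.seed + 1,
    )
    ref = focus_mod.load_reference_network(ref_edges)
    annotation_pairs = syn.simulate_annotation(
        truth, compendium.gene_ids, seed=config.seed + 2
    )
    annotation: dict = {}
    for g, t in annotation_pairs:
        annotation.setdefault(g, set()).add(t)
    background = set(compendium.gene_ids)
    focus_results = {}
    for ct, net in networks.items():
        genes_ct = net.nodes & selected
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            focus_results[ct] = focus_mod.coherence_filter(
                genes_ct, ref, n_permutations=config.n_permutations,
                q_max=config.enrich_q, seed=config.seed + 3,
            )
    manifest["stages"]["focus"] = {
        ct: {"retained": len(f.nodes), "clusters": len(f.clusters)}
        for ct, f in focus_results.items()
    }

    # --- stage 4: discovery + validation DE ---------------------------
    module_genes = [g for m in truth.modules for g in m.gene_ids]
    planted_up = tuple(module_genes[: config.n_biomarkers])
    cohort_genes = [f"G{i + 1:05d}" for i in range(300)]
    # biomarker genes carry their compendium ids into the cohorts
    rename = dict(zip(cohort_genes[: len(planted_up)], planted_up))

    de_tables = {}
    for label, seed_off in (("discovery", 10), ("validation", 11)):
        spec = syn.ResponseCohortSpec(
            n_response=config.cohort_n_response,
            n_nonresponse=config.cohort_n_nonresponse,
            n_genes=len(cohort_genes),
            planted_up=tuple(cohort_genes[: len(planted_up)]),
            fold=config.cohort_fold,
            dispersion=config.cohort_dispersion,
            seed=config.seed + seed_off,
        )
        cohort, _ = syn.simulate_response_cohort(spec)
        cohort = ExpressionMatrix(
            cohort.values.rename(index=rename), cohort.annotations
        )
        candidates = set(selected) | set(cohort.values.index[: len(cohort_genes) // 2])
        de_tables[label] = de_mod.de_pipeline(
            cohort,
            min_count=config.filter_min_count,
            min_proportion=config.filter_min_proportion,
            q_max=config.de_q,
            fc_min=config.fc_min,
        )
    panel = de_mod.validate_panel(de_tables["discovery"], de_tables["validation"])
    manifest["stages"]["de"] = {
        "discovery_passing": int(de_tables["discovery"]["passes"].sum()),
        "validation_passing": int(de_tables["validation"]["passes"].sum()),
        "panel_size": len(panel),
        "panel_planted_recall": (
            float(len(set(panel.index) & set(planted_up)) / len(planted_up))
            if len(planted_up)
            else np.nan
        ),
    }

    # --- stage 5: survival --------------------------------------------
    panel_genes = list(panel.index) if len(panel) else list(planted_up)
    # half the panel carries a real hazard effect (alternating sign),
    # half is prognostically null; expression is bimodal so the mixture
    # stratification has modes to find
    betas = tuple(
        (g, -config.survival_beta if i % 2 == 0 else 0.0)
        for i, g in enumerate(panel_genes)
    )
    surv_spec = syn.SurvivalCohortSpec(
        n_patients=config.survival_n,
        betas=betas,
        beta_age=0.02,
        beta_stage=0.3,
        baseline_hazard=0.02,
        censor_rate=0.01,
        bimodal=tuple((g, 4.0) for g in panel_genes),
        seed=config.seed + 20,
    )
    cohort_df, _ = syn.simulate_survival_cohort(surv_spec)
    screen = surv_mod.univariate_screen(
        cohort_df, panel_genes, k_max=config.k_max, seed=config.seed + 21
    )
    significant = screen.index[screen["q"] < config.screen_q].tolist()
    train, valid = surv_mod.stratified_split(
        cohort_df, fraction=config.train_fraction, seed=config.seed + 22
    )
    candidates = ["age", "stage_code"] + (significant or panel_genes[:2])
    model, trace = surv_mod.stepwise_aic(
        train, candidates, never_drop=("age", "stage_code")
    )
    ph = surv_mod.ph_check(model, train)
    strat = surv_mod.risk_split(model, train, valid)
    manifest["stages"]["survival"] = {
        "screen_significant": len(significant),
        "model_covariates": list(model.covariates),
        "model_aic": model.aic,
        "lr_p": model.lr_p,
        "ph_global_p": float(ph.loc["GLOBAL", "p"]),
        "train_sizes": list(strat.train_sizes),
        "valid_logrank_p": strat.p,
    }

    # --- write outputs -------------------------------------------------
    if out is not None:
        write_expression(compendium, out / "compendium.tsv")
        compendium.annotations.to_csv(out / "compendium_annotations.tsv", sep="\t")
        for ct, net in networks.items():
            net_mod.write_network_tsv(net, out / f"network_{ct}.tsv")
            net_mod.write_network_sif(net, out / f"network_{ct}.sif")
        overlap_mod.write_overlap_tsv(overlap_matrix, out / "overlap_matrix.tsv")
        overlap_mod.write_membership_tsv(table, out / "membership.tsv")
        for ct, f in focus_results.items():
            focus_mod.write_focus_sif(f, out / f"focus_{ct}.sif")
            focus_mod.write_focus_nodes(f, out / f"focus_{ct}_nodes.tsv")
        for label, tbl in de_tables.items():
            tbl.to_csv(out / f"de_{label}.tsv", sep="\t")
        panel.to_csv(out / "biomarker_panel.tsv", sep="\t")
        screen.to_csv(out / "survival_screen.tsv", sep="\t")
        model.summary.to_csv(out / "cox_model.tsv", sep="\t")
        ph.to_csv(out / "ph_check.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
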