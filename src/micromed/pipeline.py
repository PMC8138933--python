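"""End-to-end study pipeline on synthetic data.

Chains the full analysis the package implements: simulate a 2-community x
4-diet dataset -> preprocess (prevalence filter, zero replacement, INT,
log-CPM + MAD selection) -> diversity (rarefaction, alpha, beta, PCoA,
PERMANOVA) -> co-abundance modules + module-trait correlations -> zero-sum
log-contrast association of taxa with module eigenvalues -> mediation
(distance-based per diet, taxonomy-tree scan, module-based) -> tidy report
tables.  Returns everything as an in-memory dict; optionally writes TSVs.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import comodules as cm
from . import diversity as dv
from . import hoststats as hs
from . import logcontrast as lc
from . import mediation as md
from . import preprocess as pp
from . import synthdata as sd

DEFAULTS = dict(
    n_per_cell=8,
    n_genera=45,
    n_families=25,
    n_metabolites=300,
    n_metabolite_blocks=3,
    n_genes=1_000,
    n_gene_blocks=2,
    mad_top=500,
    within_block_corr=0.7,
    rarefy_depth=5_000,
    selection_B=100,
    mediation_B=199,
    n_perm=999,
)


def _gene_counts(latent: pd.DataFrame, rng) -> pd.DataFrame:
    """Continuous latent block matrix -> overdispersed RNA-seq-like counts."""
    log_mean = rng.normal(4.0, 1.5, size=latent.shape[1])
    mu = np.exp(log_mean[None, :] + 0.4 * np.asarray(latent))
    return pd.DataFrame(rng.poisson(mu), index=latent.index,
                        columns=latent.columns)


def run_study(seed: int = 0, out_dir=None, **overrides) -> dict:
    """Run the whole analysis on a freshly simulated dataset.

    Returns a dict with the generated data, intermediate tables, and the
    association / mediation reports, plus wall-clock timings per stage.
    """
    cfg = {**DEFAULTS, **overrides}
    timings = {}
    t0 = time.time()
    rng = np.random.default_rng(seed)

    # --- simulate -----------------------------------------------------------
    design = sd.StudyDesign(n_per_cell=cfg["n_per_cell"], seed=seed)
    tree = sd.make_taxonomy(cfg["n_genera"], cfg["n_families"], seed=seed)
    families = sorted(n.name for n in tree.preorder()
                      if n.name and n.name.startswith("f__")
                      and len(list(n.tips())) >= 2)
    counts, meta, truth = sd.sample_counts(
        design, tree, seed=seed + 1, mediating_family=families[0])
    taxa = list(counts.columns)
    fam_leaves = [t.name for t in tree.find(families[0]).tips()]

    # phenotype: community + diet + batch + planted taxa path through the
    # mediating family's log-ratio
    beta = np.zeros(len(taxa))
    beta[taxa.index(fam_leaves[0])] = 1.0
    beta[taxa.index(fam_leaves[1])] = -1.0
    pheno, effects = sd.make_phenotypes(
        counts, meta, beta, mediation_strength=0.5, noise_sd=1.0,
        seed=seed + 2, name="adiposity")
    truth.beta_true["adiposity"] = effects["beta_true"]
    truth.phenotype_effects["adiposity"] = {
        k: v for k, v in effects.items() if k != "beta_true"}

    # metabolite block 1 is driven by the mediating family's log-contrast, so
    # taxa -> metabolite-module -> phenotype paths are recoverable downstream
    driver = np.zeros(len(taxa))
    driver[taxa.index(fam_leaves[0])] = 1.0
    driver[taxa.index(fam_leaves[1])] = -1.0
    z_full = np.log(np.asarray(pp.zero_replace(counts)))
    metab, metab_ann, metab_truth = sd.make_omics(
        design, cfg["n_metabolites"], cfg["n_metabolite_blocks"],
        within_block_corr=cfg["within_block_corr"], seed=seed + 3,
        taxa_driver={0: driver}, taxa_logrel=z_full)
    gene_latent, gene_ann, gene_truth = sd.make_omics(
        design, cfg["n_genes"], cfg["n_gene_blocks"],
        within_block_corr=cfg["within_block_corr"], seed=seed + 4,
        block_size=100, prefix="gene")
    gene_counts = _gene_counts(gene_latent, rng)
    timings["simulate"] = time.time() - t0

    # --- preprocess ---------------------------------------------------------
    t0 = time.time()
    counts_f = pp.prevalence_filter(counts, 0.2)
    rel = pp.zero_replace(counts_f)
    metab_f = pp.prevalence_filter(metab, 0.2)
    int_cols, dropped = {}, []
    for c in metab_f.columns:
        vals, flag = pp.inverse_normal_transform(metab_f[c].to_numpy())
        if flag:
            dropped.append(c)
        else:
            int_cols[c] = vals
    metab_t = pd.DataFrame(int_cols, index=metab_f.index)
    logcpm = pp.logcpm_transform(gene_counts)
    genes_t = pp.mad_select(logcpm, min(cfg["mad_top"], logcpm.shape[1]))
    timings["preprocess"] = time.time() - t0

    # --- diversity ----------------------------------------------------------
    t0 = time.time()
    rare = dv.rarefy(counts_f, cfg["rarefy_depth"], seed=seed + 5)
    alpha = pd.DataFrame({
        "shannon": [dv.shannon(r) for r in rare.to_numpy()],
        "faith_pd": [dv.faith_pd(list(rare.columns[r > 0]), tree)
                     for r in rare.to_numpy()],
    }, index=rare.index)
    dms = {m: dv.beta_distance(
        pp.zero_replace(rare) if m == "bray_curtis" else rare, m,
        tree=tree if "unifrac" in m else None) for m in dv.METRICS}
    pcoa_coords, eigvals, _ = dv.pcoa(dms["unifrac_unweighted"])
    permanova_res = {
        m: dv.permanova(dms[m], meta["community"].to_numpy(),
                        n_perm=cfg["n_perm"], seed=seed + 6)
        for m in ("unifrac_unweighted", "unifrac_weighted")}
    timings["diversity"] = time.time() - t0

    # --- host statistics ----------------------------------------------------
    t0 = time.time()
    pheno_table = pd.concat([meta, pheno], axis=1)
    host = hs.phenotype_tests(pheno_table, ["adiposity"], n_perm=1_999,
                              seed=seed + 7)
    timings["hoststats"] = time.time() - t0

    # --- co-abundance modules ----------------------------------------------
    t0 = time.time()
    metab_modules = cm.detect_modules(metab_t)
    gene_modules = cm.detect_modules(genes_t)
    traits = pd.DataFrame({"adiposity": pheno})
    module_trait = cm.module_trait_corr(metab_modules.eigenvalues, traits)
    enrich = {}
    for m in metab_modules.modules:
        enrich[m] = cm.fisher_enrichment(
            metab_modules.features_in(m), metab_ann["pathway"],
            list(metab_t.columns))
    timings["modules"] = time.time() - t0

    # --- taxa association (log-contrast + stability selection) -------------
    t0 = time.time()
    responses = pd.concat([metab_modules.eigenvalues.add_prefix("metab_"),
                           gene_modules.eigenvalues.add_prefix("gene_")],
                          axis=1)
    selection = {}
    for name in responses.columns:
        prob = lc.LogContrastProblem.from_relative_abundance(
            rel, responses[name].to_numpy())
        selection[name] = lc.selection_protocol(
            prob, B=cfg["selection_B"], seed=seed + 8, with_bootstrap=False)
    network = lc.build_network(selection)
    timings["associate"] = time.time() - t0

    # --- mediation ----------------------------------------------------------
    t0 = time.time()
    x = (meta["community"] == design.communities[1]).to_numpy(float)
    batch = meta[["batch"]]
    med_rows = []
    for diet in ("C", "I", "P"):  # single-fiber diets
        idx = np.flatnonzero((meta["diet"] == diet).to_numpy())
        for metric in ("jaccard", "unifrac_unweighted"):
            sub_dm = dv.DistanceMatrix(
                [dms[metric].ids[i] for i in idx],
                dms[metric].data[np.ix_(idx, idx)], metric)
            res = md.distance_mediation_test(
                sub_dm, x[idx], pheno.to_numpy()[idx],
                covariates=batch.iloc[idx], n_perm=cfg["n_perm"],
                seed=seed + 9)
            row = res.as_row()
            row["diet"] = diet
            med_rows.append(row)
    distance_mediation = pd.DataFrame(med_rows)
    tree_scan = md.tree_mediation_scan(
        counts_f, tree, x, pheno.to_numpy(), covariates=batch,
        B=cfg["mediation_B"], seed=seed + 10)
    grey = metab_t[[f for f in metab_t.columns
                    if metab_modules.labels.get(f) == cm.GREY]]
    module_med = md.module_mediation(
        metab_modules.eigenvalues, x, pheno.to_numpy(), covariates=batch,
        unclustered=grey.iloc[:, :5], B=max(cfg["mediation_B"], 199),
        seed=seed + 11)
    timings["mediate"] = time.time() - t0

    results = {
        "design": design, "tree": tree, "counts": counts, "meta": meta,
        "truth": truth, "phenotypes": pheno_table, "relative_abundance": rel,
        "metabolites": metab_t, "metabolite_truth": metab_truth,
        "genes": genes_t, "gene_truth": gene_truth, "alpha": alpha,
        "distance_matrices": dms, "pcoa": pcoa_coords,
        "permanova": permanova_res, "host_stats": host,
        "metabolite_modules": metab_modules, "gene_modules": gene_modules,
        "module_trait": module_trait, "enrichment": enrich,
        "selection": selection, "network": network,
        "distance_mediation": distance_mediation, "tree_mediation": tree_scan,
        "module_mediation": module_med, "timings": timings,
        "mediating_family": families[0],
    }
    if out_dir is not None:
        _write_report(Path(out_dir), results)
    return results


def _write_report(out: Path, results: dict):
    out.mkdir(parents=True, exist_ok=True)
    results["counts"].to_csv(out / "counts.tsv", sep="\t")
    results["phenotypes"].to_csv(out / "phenotypes.tsv", sep="\t")
    results["alpha"].to_csv(out / "alpha_diversity.tsv", sep="\t")
    for m, dm in results["distance_matrices"].items():
        dm.to_frame().to_csv(out / f"distance_{m}.tsv", sep="\t")
    results["pcoa"].to_csv(out / "pcoa_unifrac_unweighted.tsv", sep="\t")
    results["host_stats"].to_csv(out / "host_stats.tsv", sep="\t", index=False)
    results["module_trait"].to_csv(out / "module_trait.tsv", sep="\t",
                                   index=False)
    results["network"].to_csv(out / "association_network.tsv", sep="\t",
                              index=False)
    results["distance_mediation"].to_csv(out / "distance_mediation.tsv",
                                         sep="\t", index=False)
    results["tree_mediation"].to_csv(out / "tree_mediation.tsv", sep="\t",
                                     index=False)
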