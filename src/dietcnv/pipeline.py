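"""End-to-end orchestration: simulate -> screen -> comparative -> DF -> pFDA.

Each ``run_*`` stage reads the configured inputs, computes its piece of
the analysis and writes plain-text tables into the output directory.
Every output starts with a provenance header line carrying the config
hash and master seed, and every stochastic stage derives its seed from
the master seed, so a pipeline run is byte-reproducible.

Stage order in :func:`run_all` mirrors the analysis: candidate screen,
phylogenetically corrected association tests plus signal statistics,
herbivore/carnivore discriminant with stepwise selection and validation,
phylogenetic discriminant over a lambda grid, duplication-mode calls, and
the quantitative trophic-level regressions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, discriminant, dupmode, ingest, screen, simulate
from . import trees, trophic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_screen", "run_comparative",
           "run_discriminant", "run_pfda", "run_dupmode",
           "run_trophic_regression", "run_all"]


@dataclass
class PipelineConfig:
    """Flat, human-editable configuration for the whole pipeline."""

    # inputs
    ortholog_tsv: str = "orthologs.tsv"
    newick: str = "tree.nwk"
    trophic_csv: str = "trophic.csv"
    locus_tsv: str = "loci.tsv"
    diet_csv: str = "diet.csv"
    relabel_csv: str | None = None
    # synthetic-data stage (writes the input files above)
    simulate: bool = False
    n_species: int = 32
    n_families: int = 100
    n_planted: int = 10
    planted_beta: float = float(np.log(4.0))
    planted_category: str = "herbivore"
    mu: float = float(np.log(1.2))
    sigma2_phylo: float = 0.05
    sigma2_resid: float = 0.02
    min_category_fraction: float = 0.30
    tandem_fraction: float = 0.5
    # analysis settings
    criteria: screen.ScreeningCriteria = field(
        default_factory=screen.ScreeningCriteria)
    glmm: comparative.GlmmConfig = field(
        default_factory=lambda: comparative.GlmmConfig().reduced())
    n_perm: int = 999
    bonferroni: bool = False
    alpha: float = 0.05
    alpha_enter: float = 0.2
    priors_mode: str = "proportions"  # or "fixed"
    fixed_priors: dict = field(
        default_factory=lambda: {"carnivore": 0.632, "herbivore": 0.368})
    pfda_grid_max: float = 0.1
    pfda_grid_step: float = 0.01
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "criteria" in doc:
            doc["criteria"] = screen.ScreeningCriteria(**doc["criteria"])
        if "glmm" in doc:
            doc["glmm"] = comparative.GlmmConfig(**doc["glmm"])
        return cls(**doc)

    _PATH_FIELDS = ("ortholog_tsv", "newick", "trophic_csv", "locus_tsv",
                    "diet_csv", "relabel_csv", "outdir")

    def config_hash(self) -> str:
        """Fingerprint of the analysis settings (file locations excluded,
        so a run relocated on disk hashes the same)."""
        doc = {k: v for k, v in self.to_dict().items()
               if k not in self._PATH_FIELDS}
        doc["relabelled"] = self.relabel_csv is not None
        text = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def _path(self, name: str) -> Path:
        return Path(self.outdir) / name

    def header(self) -> str:
        return f"# dietcnv config={self.config_hash()} seed={self.seed}\n"

    def _write(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        out = self._path(name)
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w") as fh:
            fh.write(self.header())
            df.to_csv(fh, sep="\t", index=index,
                      float_format="%.10g", lineterminator="\n")
        return out


def _load_inputs(config: PipelineConfig):
    matrix = ingest.read_ortholog_groups(config.ortholog_tsv)
    with open(config.newick) as fh:
        tree = trees.read_newick(fh.read())
    table = ingest.read_trophic_table(config.trophic_csv)
    if config.relabel_csv:
        table = ingest.apply_relabel(table, pd.read_csv(config.relabel_csv))
    return ingest.align_dataset(matrix, table, tree) + (tree,)


def run_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic input files named in the config."""
    params = simulate.SimParams(
        n_species=config.n_species, n_families=config.n_families,
        mu=config.mu, sigma2_phylo=config.sigma2_phylo,
        sigma2_resid=config.sigma2_resid,
        focal_category=config.planted_category, seed=config.seed,
    ).with_planted(config.n_planted, config.planted_beta)
    tree = simulate.simulate_tree(params)
    states = simulate.simulate_trophic_states(
        tree, params.Q, params.root_state, seed=config.seed + 1)
    # the simulated metadata must look like a usable comparative dataset:
    # every category present with a realistic minimum share (the smallest
    # real trophic class covers ~a fifth of species); resample the state
    # seed until that holds
    need = max(2, int(np.ceil(config.min_category_fraction
                              * config.n_species)))
    tries = 0
    while (states["category"].value_counts().reindex(
            simulate.CATEGORIES, fill_value=0).min() < need and tries < 200):
        tries += 1
        states = simulate.simulate_trophic_states(
            tree, params.Q, params.root_state, seed=config.seed + 1 + tries)
    matrix = simulate.simulate_copy_numbers(tree, states, params)
    loci = simulate.simulate_locus_table(
        matrix[matrix.columns[:min(20, config.n_families)]],
        tandem_fraction=config.tandem_fraction, seed=config.seed + 2)
    diet = simulate.simulate_diet_composition(states, seed=config.seed + 3)
    Path(config.ortholog_tsv).parent.mkdir(parents=True, exist_ok=True)
    simulate.write_ortholog_groups(matrix, config.ortholog_tsv)
    with open(config.newick, "w") as fh:
        fh.write(tree.newick() + "\n")
    states.to_csv(config.trophic_csv, index=False)
    loci.to_csv(config.locus_tsv, sep="\t", index=False)
    diet.to_csv(config.diet_csv, index=False)
    return {"n_species": config.n_species, "n_families": config.n_families}


def run_screen(config: PipelineConfig) -> pd.DataFrame:
    """Three-criterion screen per trophic category; writes diagnostics."""
    t0 = time.perf_counter()
    matrix, table, _, _ = _load_inputs(config)
    results = screen.screen_all_categories(matrix, table, config.criteria)
    frame = screen.results_frame(results)
    self_path = config._write("screen.tsv", frame)
    logger.info("screen: %d families x 3 categories in %.1fs -> %s",
                matrix.shape[1], time.perf_counter() - t0, self_path)
    return frame


def run_comparative(config: PipelineConfig) -> pd.DataFrame:
    """GLMM association tests + phylogenetic signals for screened families."""
    t0 = time.perf_counter()
    matrix, table, cov, _ = _load_inputs(config)
    screened = screen.screen_all_categories(matrix, table, config.criteria)
    cat_of = table.set_index("species")["category"]
    rows = []
    n_tests = sum(r.passed for rs in screened.values() for r in rs)
    test_i = 0
    for cat, results in screened.items():
        x = (cat_of.loc[cov.species] == cat).to_numpy(dtype=float)
        for r in results:
            if not r.passed:
                continue
            y = matrix[r.family].to_numpy()
            cfg = replace(config.glmm,
                          seed=(config.seed + 7919 * test_i) % (2**31))
            fit = comparative.fit_phylo_glmm(y, x, cov, cfg)
            lam, lam_p, _ = comparative.pagels_lambda(
                y.astype(float), cov)
            K, K_p = comparative.blombergs_k(
                y.astype(float), cov, n_perm=config.n_perm,
                seed=(config.seed + 104729 * test_i) % (2**31))
            p = fit.pmcmc_beta
            row = {
                "category": cat, "family": r.family,
                "beta_mean": fit.beta_mean,
                "beta_lo": fit.beta_ci[0], "beta_hi": fit.beta_ci[1],
                "pmcmc": float(p), "pmcmc_str": str(p),
                "lambda": lam, "lambda_p": float(lam_p),
                "K": K, "K_p": float(K_p),
            }
            if config.bonferroni:
                row["pmcmc_bonf"] = float(
                    comparative.bonferroni(p, n_tests))
            rows.append(row)
            test_i += 1
    frame = pd.DataFrame(rows)
    config._write("comparative.tsv", frame)
    logger.info("comparative: %d tests in %.1fs", test_i,
                time.perf_counter() - t0)
    return frame


def _df_families(config: PipelineConfig, matrix, table) -> list[str]:
    """Families feeding the discriminant: herbivore- or carnivore-associated
    per the comparative table when present, else per the screen."""
    comp_path = config._path("comparative.tsv")
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t", comment="#")
        sub = comp[(comp["category"].isin(["herbivore", "carnivore"]))
                   & (comp["pmcmc"] < config.alpha)]
        fams = sorted(set(sub["family"]))
        if fams:
            return fams
    screened = screen.screen_all_categories(matrix, table, config.criteria)
    return sorted({r.family for cat in ("herbivore", "carnivore")
                   for r in screened[cat] if r.passed})


def _hc_subset(matrix, table):
    mask = table["category"].isin(["herbivore", "carnivore"]).to_numpy()
    species = table.loc[mask, "species"].tolist()
    labels = table.loc[mask, "category"].to_numpy()
    return matrix.loc[species], labels


def _priors(config: PipelineConfig, labels) -> dict:
    if config.priors_mode == "fixed":
        return dict(config.fixed_priors)
    classes, counts = np.unique(labels, return_counts=True)
    return {c: float(k) / len(labels) for c, k in zip(classes, counts)}


def run_discriminant(config: PipelineConfig) -> dict:
    """LDA + stepwise selection + LOOCV + clade holdout; writes model JSON,
    scores and validation tables."""
    matrix, table, cov, tree = _load_inputs(config)
    fams = _df_families(config, matrix, table)
    if len(fams) < 2:
        raise RuntimeError("fewer than 2 discriminant families available")
    X, labels = _hc_subset(matrix[fams], table)
    priors = _priors(config, labels)
    model = discriminant.fit_lda(X, labels, priors=priors)
    trace = discriminant.stepwise_wilks(X, labels,
                                        alpha_enter=config.alpha_enter)
    selected = trace.selected or fams
    Xsel = X[selected]
    model_sel = discriminant.fit_lda(Xsel, labels, priors=priors)
    acc_full, pred_full = discriminant.loocv(X, labels, priors=priors)
    acc_sel, pred_sel = discriminant.loocv(Xsel, labels, priors=priors)
    scores_all = discriminant.df_scores(model_sel, matrix[selected])
    # clade holdout: try each half of the root split
    root_kids = tree._tree.seed_node.child_nodes()
    lab_by_sp = pd.Series(labels, index=X.index)
    holdout_rows = []
    for ci, child in enumerate(root_kids):
        clade = [lf.taxon.label for lf in child.leaf_iter()]
        clade_hc = [s for s in clade if s in X.index]
        if not clade_hc:
            continue
        train_lab = lab_by_sp.drop(clade_hc)
        if train_lab.nunique() < 2 or train_lab.value_counts().min() < 2:
            continue
        preds = discriminant.clade_holdout(Xsel, labels, clade_hc,
                                           priors=priors)
        truth = pd.Series(labels, index=X.index).loc[clade_hc]
        for sp in clade_hc:
            holdout_rows.append({"clade": f"root_child_{ci}", "species": sp,
                                 "true": truth[sp],
                                 "predicted": preds[sp]})
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "discriminant_model.json").write_text(
        model_sel.to_json() + "\n")
    config._write("df_scores.tsv",
                  scores_all.rename_axis("species").reset_index())
    config._write("stepwise.tsv", pd.DataFrame({
        "step": range(1, len(trace.selected) + 1),
        "family": trace.selected, "wilks": trace.wilks,
        "p_enter": trace.p_enter}))
    config._write("loocv.tsv", pd.DataFrame({
        "species": X.index, "true": labels,
        "pred_full": pred_full.to_numpy(), "pred_selected": pred_sel.to_numpy()}))
    if holdout_rows:
        config._write("clade_holdout.tsv", pd.DataFrame(holdout_rows))
    report = {
        "families_full": fams,
        "families_selected": selected,
        "wilks_full": discriminant.wilks_lambda(X, labels),
        "wilks_selected": discriminant.wilks_lambda(Xsel, labels),
        "loocv_accuracy_full": acc_full,
        "loocv_accuracy_selected": acc_sel,
        "priors": priors,
    }
    (outdir / "discriminant_report.json").write_text(
        json.dumps(report, indent=1, default=str) + "\n")
    return report


def run_pfda(config: PipelineConfig) -> pd.DataFrame:
    """Phylogenetic discriminant over the lambda grid; writes the per-lambda
    misclassification table."""
    matrix, table, cov, tree = _load_inputs(config)
    model_path = config._path("discriminant_model.json")
    if model_path.exists():
        model = discriminant.DiscriminantModel.from_json(
            model_path.read_text())
        fams = [f for f in model.features if f in matrix.columns]
    else:
        fams = _df_families(config, matrix, table)
    X, labels = _hc_subset(matrix[fams], table)
    priors = _priors(config, labels)
    sub = trees.prune_to_species(tree, set(X.index))
    ultra = (sub if trees.is_ultrametric(sub)
             else trees.make_ultrametric(sub, "extend"))
    grid = np.round(np.arange(0.0, config.pfda_grid_max + 1e-9,
                              config.pfda_grid_step), 10)
    lam_star, tab = discriminant.optimal_pfda_lambda(
        X, labels, ultra, grid=grid, priors=priors)
    tab["optimal"] = tab["lambda"] == lam_star
    config._write("pfda.tsv", tab)
    return tab


def run_dupmode(config: PipelineConfig) -> pd.DataFrame:
    """5-Mb duplication-mode calls and the per-species summary."""
    loci = ingest.read_locus_table(config.locus_tsv)
    calls = dupmode.classify_all(loci)
    call_frame = pd.DataFrame([{
        "family": c.family, "species": c.species, "call": c.call,
        "n_copies": c.n_copies} for c in calls])
    summary = dupmode.summarize_dup_calls(calls)
    config._write("dup_calls.tsv", call_frame)
    config._write("dup_summary.tsv", summary.reset_index())
    return summary


def run_trophic_regression(config: PipelineConfig) -> pd.DataFrame:
    """Copy number ~ TL (Poisson GLMM) and DF score ~ TL (Gaussian GLMM)."""
    matrix, table, cov, _ = _load_inputs(config)
    diet = ingest.read_diet_table(config.diet_csv)
    tl = trophic.trophic_levels_from_table(diet)
    species = [s for s in cov.species if s in tl.index]
    if len(species) < 4:
        raise RuntimeError("fewer than 4 species with trophic levels")
    cov_sub = cov.reorder(species) if species != cov.species else cov
    x = tl.loc[species].to_numpy()
    fams = _df_families(config, matrix, table)
    rows = []
    for i, fam in enumerate(fams):
        y = matrix[fam].loc[species].to_numpy()
        cfg = replace(config.glmm,
                      seed=(config.seed + 31 * i + 5) % (2**31))
        fit = comparative.fit_phylo_glmm(y, x, cov_sub, cfg)
        rows.append({"response": fam, "kind": "copy_number",
                     "beta_mean": fit.beta_mean,
                     "pmcmc": float(fit.pmcmc_beta),
                     "pmcmc_str": str(fit.pmcmc_beta)})
    model_path = config._path("discriminant_model.json")
    if model_path.exists():
        model = discriminant.DiscriminantModel.from_json(
            model_path.read_text())
        scores = discriminant.df_scores(model, matrix.loc[species])
        cfg = replace(config.glmm, family="gaussian",
                      seed=(config.seed + 991) % (2**31))
        fit = comparative.fit_phylo_glmm(
            scores.to_numpy(), x, cov_sub, cfg)
        rows.append({"response": "df_score", "kind": "df_score",
                     "beta_mean": fit.beta_mean,
                     "pmcmc": float(fit.pmcmc_beta),
                     "pmcmc_str": str(fit.pmcmc_beta)})
    frame = pd.DataFrame(rows)
    config._write("trophic_regression.tsv", frame)
    return frame


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in analysis order; returns a summary dict."""
    out: dict = {}
    if config.simulate:
        out["simulate"] = run_simulate(config)
    out["screen"] = run_screen(config)
    out["comparative"] = run_comparative(config)
    out["discriminant"] = run_discriminant(config)
    out["pfda"] = run_pfda(config)
    out["dupmode"] = run_dupmode(config)
    out["trophic"] = run_trophic_regression(config)
    return out
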