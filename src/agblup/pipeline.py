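"""Two-stage orchestration and the command-line interface.

Training learns all tunable state from the phenotyped (reference)
individuals: the cross-validation plan, per-fold association scans, the
plain-LMM baseline accuracy, pseudo-QTN candidates and their stepwise
audition, and — unless the plain fixed-effect family won — the kinship
weighting parameters.  Application predicts genetic values for every
individual from a learned model; with a pre-trained model only one fresh
association scan of the current reference is needed (to place the
kinship weights), so the expensive cross-validation never reruns.

Everything is driven by one seed, so a (config, seed) pair fixes every
output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cross_validation import cv_accuracy, make_cv_plan, run_fold_scans
from .genotype_io import (
    GenotypeMatrix,
    PhenotypeVector,
    impute_missing,
    qc_filter,
    read_covariates,
    read_pedigree,
    read_phenotype,
    read_plink,
    write_plink,
)
from .kinship import WeightParams, standard_kinship, weighted_kinship
from .mixed_model import blup_predict, fit_variance_components, glm_scan, mlm_scan
from .qtn_selection import ModelSpec, select_candidate_qtns, stepwise_model_select
from .weight_search import DEFAULT_ALPHA_GRID, DEFAULT_BETA_GRID, optimize_weights

__all__ = ["RunConfig", "train_model", "apply_model", "save_model", "load_model", "main"]

logger = logging.getLogger("agblup")


@dataclass
class RunConfig:
    """Knobs of one run; defaults follow the method's recommended settings."""

    scan_kind: str = "GLM"
    cv_repeats: int = 1
    cv_folds: int = 5
    seed: int = 0
    n_top: int = 15
    ld_r2_max: float = 0.3
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    beta_grid: tuple = DEFAULT_BETA_GRID
    bisection_max_iter: int = 10
    bisection_tol: float = 1e-5
    qc: bool = True
    maf_min: float = 0.01
    cr_min: float = 0.95
    hwe_p_min: float = 0.05


def train_model(
    y: PhenotypeVector,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    cfg: RunConfig | None = None,
) -> ModelSpec:
    """Learn the full model state from the phenotyped individuals.

    ``g`` may include unphenotyped individuals; the kinship is built on
    the full panel but every tuning quantity uses only phenotyped
    records.
    """
    cfg = cfg or RunConfig()
    if y.values.size != g.n_individuals:
        raise ValueError("phenotype not aligned to genotype rows")
    g = impute_missing(g)
    obs = np.flatnonzero(y.observed)
    if obs.size < 2 * cfg.cv_folds:
        raise ValueError("too few phenotyped individuals for the cross-validation plan")

    t0 = time.time()
    freq = g.allele_freq
    K_full = standard_kinship(g).values
    K = K_full[np.ix_(obs, obs)]
    g_pheno = g.subset_individuals(obs)
    y_obs = y.values[obs]
    cov_obs = None if covariates is None else np.atleast_2d(covariates)[obs]
    logger.info("kinship built in %.1fs (n=%d, m=%d)", time.time() - t0, g.n_individuals, g.n_markers)

    plan = make_cv_plan(
        obs.size,
        s=cfg.cv_repeats,
        v=cfg.cv_folds,
        seed=cfg.seed,
        stratify=y_obs if y.is_binary else None,
    )
    t0 = time.time()
    scans = run_fold_scans(
        plan, y_obs, g_pheno.values, scan_kind=cfg.scan_kind, K=K, covariates=cov_obs
    )
    logger.info("%d fold scans (%s) in %.1fs", plan.n_folds, cfg.scan_kind, time.time() - t0)

    a0 = cv_accuracy(
        plan, y_obs, K, G=g_pheno.values, covariates=cov_obs, cache_key="base"
    )
    logger.info("plain-LMM baseline CV accuracy: %.4f", a0)

    candidates, _ = select_candidate_qtns(
        plan, scans, g_pheno.values, n_top=cfg.n_top, r2_max=cfg.ld_r2_max
    )
    logger.info("pseudo-QTN candidates: %s", candidates)
    model = stepwise_model_select(
        candidates, plan, y_obs, g_pheno.values, K, a0,
        covariates=cov_obs, marker_ids=list(g.markers["id"]),
    )
    model.scan_kind = cfg.scan_kind
    model.seed = cfg.seed
    logger.info("stepwise family: %s (qtns=%s, acc=%.4f)", model.model_type,
                model.pseudo_qtn_ids, model.cv_accuracy)

    if model.model_type != "pQ":
        model = optimize_weights(
            plan, scans, y_obs, g_pheno, K, model, a0,
            covariates=cov_obs, freq=freq,
            alpha_grid=cfg.alpha_grid, beta_grid=cfg.beta_grid,
            seed=cfg.seed, max_iter=cfg.bisection_max_iter, tol=cfg.bisection_tol,
        )
        logger.info("after weight search: %s (params=%s, acc=%.4f)",
                    model.model_type, model.weight_params, model.cv_accuracy)
    return model


def apply_model(
    y: PhenotypeVector,
    g: GenotypeMatrix,
    model: ModelSpec,
    covariates: np.ndarray | None = None,
    scan_kind: str | None = None,
    merged_p_values: np.ndarray | None = None,
) -> np.ndarray:
    """Predict genetic values for every individual of the panel.

    Pseudo-QTNs are located by marker id.  For weighted-kinship models a
    fresh scan of the current phenotyped reference supplies the p-values
    (pass ``merged_p_values`` to use externally merged scan results
    instead).  Phenotyped and unphenotyped individuals both receive
    predictions.
    """
    g = impute_missing(g)
    obs = np.flatnonzero(y.observed)
    y_obs = y.values[obs]
    cov_all = None if covariates is None else np.atleast_2d(covariates)
    scan_kind = scan_kind or model.scan_kind

    if model.pseudo_qtn_ids:
        ids = list(g.markers["id"])
        lookup = {mid: j for j, mid in enumerate(ids)}
        missing = [mid for mid in model.pseudo_qtn_ids if mid not in lookup]
        if missing:
            raise ValueError(f"pseudo-QTN markers absent from the panel: {missing}")
        q_idx = [lookup[mid] for mid in model.pseudo_qtn_ids]
    else:
        q_idx = []

    if model.model_type == "pQ":
        F = np.hstack(
            [np.ones((g.n_individuals, 1))]
            + ([cov_all] if cov_all is not None else [])
            + [g.values[:, q_idx]]
        )
        coef, *_ = np.linalg.lstsq(F[obs], y_obs, rcond=None)
        return F @ coef

    if model.weight_params is not None:
        if merged_p_values is not None:
            pvals = merged_p_values
        else:
            cov_obs = cov_all[obs] if cov_all is not None else None
            if scan_kind.upper() == "GLM":
                scan = glm_scan(y_obs, g.values[obs], covariates=cov_obs)
            else:
                K0 = standard_kinship(g).values
                scan = mlm_scan(
                    y_obs, g.values[obs], K0[np.ix_(obs, obs)], covariates=cov_obs
                )
            pvals = scan.p_values
        K = weighted_kinship(g, pvals, model.weight_params).values
    else:
        K = standard_kinship(g).values

    Q_all = g.values[:, q_idx] if q_idx else None
    X_obs = None if cov_all is None else cov_all[obs]
    fixed = (
        None
        if (X_obs is None and Q_all is None)
        else np.hstack([p for p in (X_obs, None if Q_all is None else Q_all[obs]) if p is not None])
    )
    vc = fit_variance_components(y_obs, K[np.ix_(obs, obs)], X=fixed)
    res = blup_predict(y_obs, K, obs, vc, X=cov_all, Q=Q_all)
    return res.mu


def merge_cv_pvalues(scans) -> np.ndarray:
    """Mean of the per-fold scan p-values (the bootstrap-merge option)."""
    mats = [s.p_values for s in scans if s is not None]
    if not mats:
        raise ValueError("no valid scans to merge")
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# Model (de)serialisation


def save_model(model: ModelSpec, path) -> None:
    doc = {
        "model_type": model.model_type,
        "pseudo_qtn_ids": model.pseudo_qtn_ids,
        "alpha": model.weight_params.alpha if model.weight_params else None,
        "beta": model.weight_params.beta if model.weight_params else None,
        "reference_accuracy": model.reference_accuracy,
        "cv_accuracy": model.cv_accuracy,
        "scan_kind": model.scan_kind,
        "seed": model.seed,
        "trace": model.trace,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")


def load_model(path) -> ModelSpec:
    doc = json.loads(Path(path).read_text())
    wp = (
        WeightParams(alpha=doc["alpha"], beta=doc["beta"])
        if doc.get("alpha") is not None
        else None
    )
    return ModelSpec(
        model_type=doc["model_type"],
        pseudo_qtn_idx=[],
        pseudo_qtn_ids=list(doc.get("pseudo_qtn_ids", [])),
        weight_params=wp,
        reference_accuracy=doc.get("reference_accuracy", float("nan")),
        cv_accuracy=doc.get("cv_accuracy", float("nan")),
        trace=doc.get("trace", []),
        scan_kind=doc.get("scan_kind", "GLM"),
        seed=doc.get("seed"),
    )


# ---------------------------------------------------------------------------
# Command-line interface

import click  # noqa: E402


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage progress.")
def main(verbose: bool) -> None:
    """Genomic prediction with tuned pseudo-QTN covariates and weighted kinship."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s: %(message)s",
    )


def _load_inputs(bfile, pheno, covar, cfg: RunConfig):
    g, _ = read_plink(bfile)
    if cfg.qc:
        g = qc_filter(g, cfg.maf_min, cfg.cr_min, cfg.hwe_p_min)
    y = read_phenotype(pheno, g.individual_ids)
    cov = read_covariates(covar, g.individual_ids) if covar else None
    return g, y, cov


@main.command()
@click.option("--bfile", required=True, type=click.Path(), help="PLINK bed/bim/fam prefix.")
@click.option("--pheno", required=True, type=click.Path(exists=True))
@click.option("--covar", type=click.Path(exists=True))
@click.option("--scan", type=click.Choice(["glm", "mlm"]), default="glm")
@click.option("--cv-repeats", default=1, show_default=True)
@click.option("--cv-folds", default=5, show_default=True)
@click.option("--n-top", default=15, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--no-qc", is_flag=True, help="Skip marker QC filtering.")
@click.option("--out", required=True, type=click.Path(), help="Output directory.")
def train(bfile, pheno, covar, scan, cv_repeats, cv_folds, n_top, seed, no_qc, out):
    """Learn model type, pseudo QTNs and kinship weights; write a model file."""
    cfg = RunConfig(
        scan_kind=scan.upper(), cv_repeats=cv_repeats, cv_folds=cv_folds,
        n_top=n_top, seed=seed, qc=not no_qc,
    )
    if not Path(f"{bfile}.bed").exists():
        raise click.ClickException(f"genotype file not found: {bfile}.bed")
    g, y, cov = _load_inputs(bfile, pheno, covar, cfg)
    model = train_model(y, g, covariates=cov, cfg=cfg)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    save_model(model, outdir / "model.json")
    click.echo(
        f"model: {model.model_type}  pseudo-QTNs: {len(model.pseudo_qtn_ids)}  "
        f"CV accuracy {model.cv_accuracy:.4f} (baseline {model.reference_accuracy:.4f})"
    )


@main.command()
@click.option("--bfile", required=True, type=click.Path())
@click.option("--pheno", required=True, type=click.Path(exists=True))
@click.option("--covar", type=click.Path(exists=True))
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--no-qc", is_flag=True)
@click.option("--out", required=True, type=click.Path())
def predict(bfile, pheno, covar, model_path, no_qc, out):
    """Predict genetic values for all individuals with a trained model."""
    cfg = RunConfig(qc=not no_qc)
    if not Path(f"{bfile}.bed").exists():
        raise click.ClickException(f"genotype file not found: {bfile}.bed")
    g, y, cov = _load_inputs(bfile, pheno, covar, cfg)
    model = load_model(model_path)
    pred = apply_model(y, g, model, covariates=cov)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write("id\tphenotyped\tprediction\n")
        for iid, seen, p in zip(g.individual_ids, y.observed, pred):
            fh.write(f"{iid}\t{int(seen)}\t{p:.6g}\n")
    click.echo(f"wrote {outdir / 'predictions.tsv'}")


@main.command()
@click.option("--n", default=500, show_default=True, help="Individuals.")
@click.option("--m", default=1000, show_default=True, help="Markers.")
@click.option(
    "--architecture",
    type=click.Choice(["polygenic", "polygenic-major", "major", "mixed", "gamma"]),
    default="gamma", show_default=True,
)
@click.option("--h2", default=0.5, show_default=True)
@click.option("--ld", default=0.0, show_default=True, help="Adjacent-marker LD decay.")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def simulate(n, m, architecture, h2, ld, seed, out):
    """Write a simulated PLINK dataset with phenotype and truth files."""
    from .simulate import SimScenario, simulate_genotypes, simulate_phenotypes

    scen = {
        "polygenic": lambda: SimScenario.polygenic(h2, n_polygenes=min(10_000, m)),
        "polygenic-major": lambda: SimScenario.polygenic_plus_major(
            h2, n_polygenes=min(10_000, m - 10)
        ),
        "major": lambda: SimScenario.major_genes(h2),
        "mixed": lambda: SimScenario.mixed(
            h2, n_polygenes=min(10_000, max(m - 1010, 10)), n_moderate=min(1000, m // 2)
        ),
        "gamma": lambda: SimScenario.gamma_qtl_trait(h2, n_qtl=min(50, m)),
    }[architecture]()
    g = simulate_genotypes(n, m, ld_decay=ld, seed=seed)
    y, tbv, causal = simulate_phenotypes(g, scen, seed=seed + 1)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(g, outdir / "sim")
    with open(outdir / "sim.pheno", "w") as fh:
        for iid, val in zip(g.individual_ids, y.values):
            fh.write(f"{iid}\t{val:.6g}\n")
    with open(outdir / "sim.truth", "w") as fh:
        fh.write("id\ttbv\n")
        for iid, val in zip(g.individual_ids, tbv):
            fh.write(f"{iid}\t{val:.6g}\n")
    with open(outdir / "sim.causal", "w") as fh:
        for j in causal:
            fh.write(f"{g.markers['id'].iloc[j]}\n")
    click.echo(f"wrote simulated dataset under {outdir}")


@main.command()
@click.option("--bfile", required=True, type=click.Path())
@click.option("--pedigree", required=True, type=click.Path(exists=True))
@click.option("--pheno", required=True, type=click.Path(exists=True))
@click.option("--model", "model_path", type=click.Path(exists=True))
@click.option("--blend", default=0.05, show_default=True)
@click.option("--no-qc", is_flag=True)
@click.option("--out", required=True, type=click.Path())
def sstep(bfile, pedigree, pheno, model_path, blend, no_qc, out):
    """Single-step prediction for genotyped and non-genotyped individuals."""
    from .single_step import HMatrixConfig, ss_predict

    if not Path(f"{bfile}.bed").exists():
        raise click.ClickException(f"genotype file not found: {bfile}.bed")
    g, _ = read_plink(bfile)
    cfg = RunConfig(qc=not no_qc)
    if cfg.qc:
        g = qc_filter(g, cfg.maf_min, cfg.cr_min, cfg.hwe_p_min)
    ped = read_pedigree(pedigree)
    y = read_phenotype(pheno, ped.individuals)
    model = load_model(model_path) if model_path else None
    g = impute_missing(g)
    res = ss_predict(y, ped, g, model=model, cfg=HMatrixConfig(blend_weight=blend))
    genotyped = set(g.individual_ids)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write("id\tgenotyped\tprediction\n")
        for iid, p in zip(ped.individuals, res.mu):
            fh.write(f"{iid}\t{int(iid in genotyped)}\t{p:.6g}\n")
    click.echo(f"wrote {outdir / 'predictions.tsv'}")


if __name__ == "__main__":
    main()
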