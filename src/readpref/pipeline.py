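"""End-to-end pipeline: filter counts, fit both models, predict, estimate.

The full workflow the command line exposes as ``readpref run``:

1. load transcripts + counts and compute RPKM per gene;
2. keep the top-K genes by RPKM (training corpus);
3. fit the Poisson log-linear model as a diagnostic (deviance R², SEs);
4. cross-validate the boosted model at gene level, then train it on the
   whole corpus;
5. predict per-position preferences for every input gene, normalized to
   mean 1 over the training corpus;
6. write SSP-corrected expression estimates and a machine-readable run
   manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .context import ContextConfig
from .countdata import GeneCounts, rpkm, select_top_genes
from .express import estimate_gene
from .io import load_genes, write_expression, write_preferences
from .poislin import export_coefficients, fit_linear_pref, save_linear_model
from .treepref import (
    BoostParams,
    build_boost_training_set,
    cv_r2,
    fit_boost,
    predict_gene_log_pref,
    save_boost_model,
)

logger = logging.getLogger("readpref")


@dataclass
class RunConfig:
    fasta: str
    counts: str
    out_dir: str
    cfg: ContextConfig = field(default_factory=lambda: ContextConfig(25, 15))
    linear_cfg: ContextConfig | None = None  # defaults to cfg
    params: BoostParams = field(default_factory=BoostParams)
    top_k: int = 100
    n_folds: int = 5
    seed: int = 0
    fit_linear: bool = True

    def validate(self) -> None:
        for path in (self.fasta, self.counts):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.top_k < 1 or self.n_folds < 2:
            raise ValueError("top_k must be >= 1 and n_folds >= 2")


def run_pipeline(run: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    run.validate()
    os.makedirs(run.out_dir, exist_ok=True)
    stage = "load"
    try:
        genes = load_genes(run.fasta, run.counts)
        logger.info("load: %d genes, %d reads", len(genes), sum(g.N for g in genes))

        stage = "filter"
        total = sum(g.N for g in genes)
        for g in genes:
            g.rpkm = rpkm(g.N, g.L, total) if total > 0 else 0.0
        if run.top_k > len(genes):
            logger.info("filter: top_k=%d exceeds %d genes, using all",
                        run.top_k, len(genes))
        corpus = [g for g in select_top_genes(genes, run.top_k) if g.N > 0]
        logger.info("filter: %d training genes", len(corpus))

        manifest: dict = {
            "tool": "readpref",
            "version": __version__,
            "inputs": {"fasta": run.fasta, "counts": run.counts},
            "seed": run.seed,
            "context": {"w_up": run.cfg.w_up, "w_down": run.cfg.w_down},
            "boost_params": {
                "interaction_depth": run.params.interaction_depth,
                "shrinkage": run.params.shrinkage,
                "n_trees": run.params.n_trees,
                "subsample_fraction": run.params.subsample_fraction,
                "min_node_weight": run.params.min_node_weight,
                "seed": run.params.seed,
            },
            "top_k": run.top_k,
            "n_genes_input": len(genes),
            "n_genes_training": len(corpus),
        }

        if run.fit_linear:
            stage = "fit-linear"
            lin_cfg = run.linear_cfg or run.cfg
            linear = fit_linear_pref(corpus, lin_cfg)
            save_linear_model(linear, os.path.join(run.out_dir, "linear_model.tsv"))
            export_coefficients(
                linear, os.path.join(run.out_dir, "linear_coefficients.tsv")
            )
            diag = linear.diagnostics
            manifest["linear"] = {
                "r2": diag.r2,
                "d": diag.d,
                "d0": diag.d0,
                "n_iterations": diag.n_iterations,
                "converged": diag.converged,
            }
            logger.info("fit-linear: R2 = %.4f in %d iterations",
                        diag.r2, diag.n_iterations)
            logger.debug("fit-linear deviance trajectory: %s",
                         diag.deviance_trajectory.tolist())

        stage = "fit-boost"
        cv = cv_r2(corpus, run.cfg, run.params, n_folds=run.n_folds, seed=run.seed)
        manifest["cv"] = {
            "cv_r2": cv.cv_r2,
            "d_per_fold": cv.d.tolist(),
            "d0_per_fold": cv.d0.tolist(),
            "n_folds": run.n_folds,
        }
        logger.info("fit-boost: cross-validation R2 = %.4f", cv.cv_r2)
        ts = build_boost_training_set(corpus, run.cfg)
        model = fit_boost(ts, run.params)
        save_boost_model(model, os.path.join(run.out_dir, "boost_model.json"))

        stage = "predict"
        log_prefs = {g.gene_id: predict_gene_log_pref(model, g) for g in genes}
        # corpus normalization: mean preference 1 over all training positions
        corpus_sum = sum(np.exp(log_prefs[g.gene_id]).sum() for g in corpus)
        corpus_n = sum(g.L for g in corpus)
        scale = corpus_sum / corpus_n
        manifest["corpus_pref_scale"] = float(scale)
        gids, poss, vals = [], [], []
        for g in genes:
            a = log_prefs[g.gene_id] - np.log(scale)
            gids.extend([g.gene_id] * g.L)
            poss.extend(range(g.L))
            vals.extend(a.tolist())
        write_preferences(os.path.join(run.out_dir, "preferences.tsv"),
                          gids, poss, np.asarray(vals))

        stage = "express"
        estimates = [
            estimate_gene(g, np.exp(log_prefs[g.gene_id]) / scale) for g in genes
        ]
        write_expression(os.path.join(run.out_dir, "expression.tsv"), estimates)
        manifest["mean_fold_change"] = float(
            np.mean([e.fold_change for e in estimates])
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(os.path.join(run.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
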