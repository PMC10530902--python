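"""End-to-end orchestration: preprocess -> score -> background -> select ->
evaluate, with every intermediate artifact written to disk and a manifest
recording the configuration, seed fan-out, and artifact hashes."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io, preprocess, scoring
from .config import PipelineConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``.

    Stages: input parsing, optional preprocessing (id collapsing, gene
    universe filter, log transform, quantile normalization), repeated
    holdout scoring, label-shuffle background, empirical p-values, marker
    selection at each EP cutoff, and every evaluation for which an input
    was supplied (gene sets, survival table, edge list). All artifacts are
    written under ``config.out_dir``; a ``manifest.json`` records the
    config and the SHA-256 of each artifact so reruns are verifiable.

    Returns a dict with the in-memory results: ``scores`` (the per-gene
    table), ``marker_sets``, and whichever evaluation tables were produced.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    expr = io.read_expression(config.expression)
    labels = io.read_labels(config.labels)

    if not config.skip_preprocess:
        if config.gene_map:
            expr = preprocess.collapse_mean(expr, io.read_id_map(config.gene_map), axis="genes")
        elif expr.index.duplicated().any():
            expr = preprocess.collapse_mean(
                expr, {g: g for g in expr.index}, axis="genes"
            )
        if config.sample_map:
            smap = io.read_id_map(config.sample_map)
            expr = preprocess.collapse_mean(expr, smap, axis="samples")
            labels = labels.groupby(labels.index.map(smap)).first()
        if config.gene_universe:
            universe = [g for g in io.read_gene_list(config.gene_universe) if g in expr.index]
            expr = expr.loc[universe]
        expr = preprocess.log_transform(expr, base=config.log_base,
                                        pseudocount=config.pseudocount)
        expr = preprocess.quantile_normalize(expr)
    labels = labels[labels.index.isin(expr.columns)]
    expr = expr[labels.index]
    io.write_expression(expr, out / "expression_preprocessed.tsv")

    ss = np.random.SeedSequence(config.seed)
    score_seed, background_seed, eval_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    logger.info("seed fan-out: score=%d background=%d eval=%d",
                score_seed, background_seed, eval_seed)

    train_kwargs = dict(
        backend=config.backend,
        train_fraction=config.train_fraction,
        importance_type=config.importance_type,
        backend_params=config.backend_params or None,
    )
    logger.info("training %d models on %d genes x %d samples",
                config.n_models, *expr.shape)
    records = scoring.train_eval_models(
        expr, labels, config.n_models, seed=score_seed, **train_kwargs
    )
    ms = scoring.compute_ms(records)

    fi_wide = pd.DataFrame(
        {f"run_{r.run_index}": r.fi for r in records}, index=expr.index
    )
    io.write_score_table(fi_wide, out / "feature_importances.tsv")
    pd.DataFrame(
        {"run": [r.run_index for r in records],
         "auc": [r.auc for r in records],
         "split_seed": [r.split_seed for r in records]}
    ).to_csv(out / "runs.tsv", sep="\t", index=False)

    logger.info("building background pool: %d shuffles x %d models",
                config.n_shuffles, config.n_models)
    pool = scoring.build_background(
        expr, labels, config.n_shuffles, config.n_models,
        seed=background_seed, **train_kwargs,
    )
    pd.DataFrame({"ms": pool.values}).to_csv(out / "background_pool.tsv",
                                             sep="\t", index=False)

    ep = scoring.empirical_pvalues(ms, pool)
    scores = scoring.score_table(expr.index, ms, ep, config.ep_cutoffs)
    io.write_score_table(scores, out / "scores.tsv")
    marker_sets = scoring.select_markers(scores, config.ep_cutoffs)
    io.write_gmt(
        {f"markers_ep_{s.cutoff:g}": set(s.genes) for s in marker_sets if s.genes},
        out / "marker_sets.gmt",
    )

    results = {"scores": scores, "marker_sets": marker_sets, "pool": pool,
               "records": records}

    # evaluations: run whichever inputs were supplied, on the largest
    # non-empty marker set (the screening set)
    eval_sets = [s for s in marker_sets if s.genes]
    if eval_sets:
        screen_set = max(eval_sets, key=lambda s: len(s.genes))
        if config.gene_sets:
            collection = io.read_gmt(config.gene_sets)
            rows = []
            for mset in eval_sets:
                for name, ref in collection.items():
                    k, p = evaluation.hypergeom_test(mset.genes, ref, set(expr.index))
                    rows.append({"cutoff": mset.cutoff, "reference": name,
                                 "markers_n": len(mset.genes),
                                 "reference_n": len(ref & set(expr.index)),
                                 "universe_n": expr.shape[0], "overlap": k, "p": p})
            enrich = pd.DataFrame(rows)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enrich
        if config.survival:
            surv = io.read_survival(config.survival)
            screen = evaluation.km_logrank_screen(
                expr, surv, sorted(screen_set.genes), labels=labels,
                cohort_filter=config.survival_cohort,
            )
            screen.to_csv(out / "survival_screen.tsv", sep="\t")
            results["survival_screen"] = screen
        if config.network:
            edges = io.read_edges(config.network)
            counts, mean = evaluation.ppi_adjacency(screen_set.genes, edges)
            counts.to_frame().to_csv(out / "adjacency.tsv", sep="\t", index_label="gene")
            results["adjacency"] = (counts, mean)
        ttest = evaluation.flag_nonsignificant_ttest(
            expr, labels, sorted(screen_set.genes), alpha=config.alpha_ttest
        )
        ttest.to_csv(out / "ttest_invisible.tsv", sep="\t")
        results["ttest_invisible"] = ttest

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "seeds": {"score": score_seed, "background": background_seed, "eval": eval_seed},
        "artifacts": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
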