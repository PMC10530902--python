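"""Importance-weighted marker scoring with permutation empirical p-values.

The core statistic is the per-gene *marker score* (here called the
metastasis score, MS, after the binary metastasis-status labels it was
designed for):

    MS_n = sum_k FI_nk * AUC_k

where K classifiers are trained on independent random 80/20 holdout splits,
FI_nk is gene n's (per-model sum-normalized) feature importance in model k
and AUC_k is model k's area under the ROC curve on its held-out 20%. The
AUC acts as a per-model weight: importances from better-generalizing models
count more.

Significance is assessed with an empirical p-value (EP) against a
label-permutation background: the full scoring procedure is rerun
``n_shuffles`` times on cohorts whose status labels are randomly permuted
(class sizes preserved), all per-gene scores are pooled, and

    EP_n = #{b in pool : b >= MS_n} / |pool|

floored at 1/|pool|. Marker sets are the genes with EP at or below each of
a list of increasing cutoffs; they are nested by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "RunRecord",
    "BackgroundPool",
    "MarkerSet",
    "train_eval_models",
    "compute_ms",
    "build_background",
    "empirical_pvalues",
    "score_table",
    "select_markers",
]

logger = logging.getLogger(__name__)

#: label encoding used throughout: negative (no spread) / positive (spread)
NEGATIVE_LABEL = "M0"
POSITIVE_LABEL = "M1"

_MAX_SPLIT_RETRIES = 100


@dataclass
class RunRecord:
    """One trained model: its per-gene importance vector and held-out AUC."""

    run_index: int
    fi: np.ndarray  # per-gene importances, >= 0, summing to 1 (or all zero)
    auc: float  # held-out AUC in [0, 1]
    split_seed: int


@dataclass
class BackgroundPool:
    """Pooled per-gene scores from label-shuffled reruns of the scoring."""

    values: np.ndarray
    n_shuffles: int
    n_genes: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def size(self) -> int:
        return self.values.size

    @staticmethod
    def expected_size(n_genes: int, n_shuffles: int) -> int:
        """Pool size implied by the construction: one score per gene per shuffle."""
        return int(n_genes) * int(n_shuffles)


@dataclass
class MarkerSet:
    """Genes selected at one EP cutoff, with the score value at the cutoff."""

    cutoff: float
    genes: frozenset
    ms_threshold: float | None = None  # smallest MS among selected genes


# ---------------------------------------------------------------------------
# model backends

def _make_model(backend: str, seed: int, params: dict | None):
    params = dict(params or {})
    if backend == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("n_jobs", 1)
        return XGBClassifier(random_state=seed, **params)
    if backend == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        params.setdefault("n_jobs", 1)
        return RandomForestClassifier(random_state=seed, **params)
    if backend == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model backend {backend!r}")


def _importances(model, backend: str, n_features: int, importance_type: str) -> np.ndarray:
    if backend == "xgboost":
        booster = model.get_booster()
        score = booster.get_score(importance_type=importance_type)
        fi = np.zeros(n_features)
        for name, val in score.items():
            fi[int(name[1:])] = val  # feature names are f0, f1, ...
    else:
        fi = np.asarray(model.feature_importances_, dtype=float)
    fi = np.clip(fi, 0.0, None)
    total = fi.sum()
    return fi / total if total > 0 else fi


# ---------------------------------------------------------------------------
# Algorithm core

def train_eval_models(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_models: int,
    seed: int,
    backend: str = "xgboost",
    train_fraction: float = 0.8,
    importance_type: str = "total_gain",
    backend_params: dict | None = None,
) -> list:
    """Repeatedly train classifiers on random holdout splits.

    Each of ``n_models`` runs draws an independent, non-stratified random
    split (``train_fraction`` train, remainder test; seeds fanned out
    deterministically from ``seed``), fits the backend classifier on the
    training fold, normalizes its importance vector to sum 1 (an all-zero
    vector is kept if the model makes no split), and computes the AUC on the
    held-out fold only. Splits that leave a single class in either fold are
    resampled (logged).

    Parameters
    ----------
    expr : pandas.DataFrame
        Genes x samples expression matrix.
    labels : pandas.Series
        Per-sample status ("M0"/"M1"), covering all columns of ``expr``.
    n_models : int
        Number of independent runs (the paper-scale default is 50).
    seed : int
        Master seed for the split sequence.
    backend : {"xgboost", "random_forest", "adaboost"}
        Classifier family; gradient boosting is the default.
    importance_type : str
        XGBoost importance flavour ("total_gain" default; "weight" counts
        splits). Ignored by the sklearn backends, which expose impurity
        importances.
    backend_params : dict, optional
        Extra keyword arguments for the classifier constructor.

    Returns
    -------
    list of RunRecord
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some expression samples")
    classes = set(labels.unique())
    if len(classes) < 2:
        raise ValueError("cohort contains a single class; cannot train")

    X = expr.to_numpy().T  # samples x genes
    y = (labels.to_numpy() == POSITIVE_LABEL).astype(int)
    n_samples, n_genes = X.shape
    n_train = int(round(train_fraction * n_samples))
    if n_train < 1 or n_train >= n_samples:
        raise ValueError("train fraction leaves an empty fold")

    seeds = np.random.SeedSequence(seed).generate_state(n_models) % (2**31)
    records = []
    for k, split_seed in enumerate(seeds):
        rng = np.random.default_rng(split_seed)
        for attempt in range(_MAX_SPLIT_RETRIES):
            perm = rng.permutation(n_samples)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                break
            logger.info("run %d: resampling single-class split (attempt %d)", k, attempt + 1)
        else:
            raise RuntimeError(f"run {k}: could not draw a two-class split")
        model = _make_model(backend, int(split_seed), backend_params)
        model.fit(X[tr], y[tr])
        proba = model.predict_proba(X[te])[:, 1]
        auc = float(roc_auc_score(y[te], proba))
        fi = _importances(model, backend, n_genes, importance_type)
        records.append(RunRecord(run_index=k, fi=fi, auc=auc, split_seed=int(split_seed)))
    return records


def compute_ms(records) -> np.ndarray:
    """Per-gene marker score: the inner product of importances with AUCs.

    ``MS_n = sum_k FI_nk * AUC_k``. Genes never used by any model score 0.
    """
    if not records:
        raise ValueError("no run records")
    n_genes = records[0].fi.shape[0]
    for rec in records:
        if rec.fi.shape[0] != n_genes:
            raise ValueError("run records have inconsistent gene dimensions")
    fi_matrix = np.stack([rec.fi for rec in records], axis=1)  # genes x runs
    aucs = np.array([rec.auc for rec in records])
    return fi_matrix @ aucs


def build_background(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_shuffles: int,
    n_models: int,
    seed: int,
    **train_kwargs,
) -> BackgroundPool:
    """Build the label-permutation background pool of marker scores.

    For each of ``n_shuffles`` permutations the status labels are shuffled
    uniformly at random (class sizes preserved), the full scoring procedure
    (``n_models`` holdout runs + inner product) is recomputed, and all
    per-gene scores are pooled. The pool size is ``n_shuffles * n_genes``
    (191,770 at the original 19,177-gene, 10-shuffle scale).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels = labels.reindex(expr.columns)
    ss = np.random.SeedSequence(seed)
    shuffle_seeds = ss.generate_state(2 * n_shuffles) % (2**31)
    pool = []
    for s in range(n_shuffles):
        rng = np.random.default_rng(shuffle_seeds[2 * s])
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index, name=labels.name
        )
        records = train_eval_models(
            expr, permuted, n_models, seed=int(shuffle_seeds[2 * s + 1]), **train_kwargs
        )
        pool.append(compute_ms(records))
    values = np.concatenate(pool)
    return BackgroundPool(values=values, n_shuffles=n_shuffles, n_genes=expr.shape[0])


def empirical_pvalues(ms, pool: BackgroundPool) -> np.ndarray:
    """Empirical p-values: inclusive upper-tail rank in the background pool.

    ``EP_n = #{b in pool : b >= MS_n} / |pool|``, floored at ``1/|pool|``
    so that EP lies in (0, 1]. EP is nonincreasing in MS.
    """
    values = np.asarray(ms, dtype=float)
    if pool.size == 0:
        raise ValueError("empty background pool")
    sorted_pool = np.sort(pool.values)
    n_ge = pool.size - np.searchsorted(sorted_pool, values, side="left")
    return np.maximum(n_ge, 1) / pool.size


def score_table(
    genes,
    ms,
    ep,
    ep_cutoffs=(0.001, 0.005, 0.01),
) -> pd.DataFrame:
    """Assemble the per-gene score table with selection flags per cutoff."""
    table = pd.DataFrame({"ms": np.asarray(ms), "ep": np.asarray(ep)},
                         index=pd.Index(genes, name="gene"))
    for c in ep_cutoffs:
        table[f"selected_{c:g}"] = table["ep"] <= c
    return table


def select_markers(scores: pd.DataFrame, ep_cutoffs) -> list:
    """Select one nested marker set per EP cutoff.

    ``scores`` must have columns ``ms`` and ``ep`` indexed by gene. Cutoffs
    must be strictly increasing within (0, 1]. Each set records the smallest
    score among its selected genes (the score value at the cutoff).
    """
    cutoffs = list(ep_cutoffs)
    if any(c <= 0 or c > 1 for c in cutoffs):
        raise ValueError(f"EP cutoffs must lie in (0,1], got {cutoffs}")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"EP cutoffs must be strictly increasing, got {cutoffs}")
    sets = []
    for c in cutoffs:
        selected = scores.index[scores["ep"] <= c]
        ms_threshold = float(scores.loc[selected, "ms"].min()) if len(selected) else None
        sets.append(MarkerSet(cutoff=float(c), genes=frozenset(selected), ms_threshold=ms_threshold))
    return sets
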