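"""Evaluation battery for selected marker sets.

Five complementary checks of a marker set's quality:

* classification: repeated-holdout AUC using only the marker genes, and its
  position against a null of equally-sized random gene subsets;
* enrichment: upper-tail hypergeometric overlap with reference gene sets
  (curated marker databases or disease-term collections in GMT form);
* survival: a per-gene median-expression-split Kaplan-Meier / log-rank
  screen;
* univariate contrast: Welch t-tests flagging markers invisible to
  per-gene testing;
* network context: adjacency counts of markers among markers in an
  undirected interaction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import NEGATIVE_LABEL, POSITIVE_LABEL, train_eval_models

__all__ = [
    "SubsetAUCResult",
    "evaluate_subset_auc",
    "random_subset_null",
    "hypergeom_test",
    "km_logrank_screen",
    "flag_nonsignificant_ttest",
    "ppi_adjacency",
]

logger = logging.getLogger(__name__)


@dataclass
class SubsetAUCResult:
    """Per-run holdout AUCs of models restricted to a gene subset."""

    aucs: np.ndarray
    genes: frozenset

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))


def evaluate_subset_auc(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes,
    n_models: int,
    seed: int,
    **train_kwargs,
) -> SubsetAUCResult:
    """Repeated-holdout AUC of classifiers using only the given genes.

    Restricts the matrix to ``genes`` and reruns the repeated 80/20
    training; returns all per-run held-out AUCs.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing[:5]}")
    records = train_eval_models(expr.loc[genes], labels, n_models, seed, **train_kwargs)
    return SubsetAUCResult(
        aucs=np.array([r.auc for r in records]), genes=frozenset(genes)
    )


def random_subset_null(
    expr: pd.DataFrame,
    labels: pd.Series,
    subset_size: int,
    n_draws: int,
    models_per_draw: int,
    seed: int,
    reference_auc: float | None = None,
    **train_kwargs,
):
    """Null distribution of mean AUCs over random equally-sized gene subsets.

    Draws ``n_draws`` uniform gene subsets of ``subset_size``, evaluates each
    with ``models_per_draw`` holdout runs, and returns the per-draw mean
    AUCs plus (if ``reference_auc`` is given) the empirical percentile of
    the reference among the null draws (fraction of draws at or below it).
    """
    if subset_size > expr.shape[0]:
        raise ValueError("subset_size exceeds the number of genes")
    ss = np.random.SeedSequence(seed)
    draw_seeds = ss.generate_state(2 * n_draws) % (2**31)
    genes = np.asarray(expr.index)
    null_aucs = []
    for d in range(n_draws):
        rng = np.random.default_rng(draw_seeds[2 * d])
        subset = rng.choice(genes, subset_size, replace=False)
        res = evaluate_subset_auc(
            expr, labels, list(subset), models_per_draw,
            seed=int(draw_seeds[2 * d + 1]), **train_kwargs,
        )
        null_aucs.append(res.mean)
    null_aucs = np.array(null_aucs)
    percentile = None
    if reference_auc is not None:
        percentile = float(np.mean(null_aucs <= reference_auc))
    return null_aucs, percentile


def hypergeom_test(markers, reference, universe):
    """Upper-tail hypergeometric overlap test.

    With universe size N, reference size K (after intersecting the reference
    with the universe), marker-set size n and overlap k, returns
    ``(k, P(X >= k))`` for X ~ Hypergeometric(N, K, n) — the probability of
    at least the observed overlap under uniform sampling (inclusive tail).
    """
    markers, reference, universe = set(markers), set(reference), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not markers <= universe:
        raise ValueError("marker set is not contained in the universe")
    reference &= universe
    k = len(markers & reference)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(reference), len(markers)))
    return k, p


def _logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square (1 df) and p-value via lifelines.

    Degenerate inputs with no events in either group give statistic 0, p 1.
    """
    if int(np.sum(events_a)) + int(np.sum(events_b)) == 0:
        return 0.0, 1.0
    from lifelines.statistics import logrank_test

    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, float(res.p_value)


def km_logrank_screen(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes,
    labels: pd.Series | None = None,
    cohort_filter: str | None = None,
    return_curves: bool = False,
):
    """Median-expression-split survival screen over a set of genes.

    For each gene the cohort is split at the gene's median expression
    (values strictly below the median form the low group; values at or
    above it the high group) and the two groups are compared with a
    log-rank test. If ``cohort_filter`` is given (e.g. the positive class
    only), the cohort is first restricted to samples with that label.
    Genes for which either group has fewer than 2 samples (e.g. constant
    expression) are skipped with a logged warning.

    Returns a DataFrame indexed by gene with columns ``n_low``, ``n_high``,
    ``statistic``, ``p``; with ``return_curves=True`` also a dict mapping
    gene -> Kaplan-Meier step-function DataFrame (time, survival, group).
    """
    surv = survival.set_index("sample_id") if "sample_id" in survival.columns else survival
    samples = [s for s in surv.index if s in expr.columns]
    if cohort_filter is not None:
        if labels is None:
            raise ValueError("cohort_filter requires labels")
        samples = [s for s in samples if labels.get(s) == cohort_filter]
    surv = surv.loc[samples]
    times = surv["time_days"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)

    rows = {}
    curves = {}
    for gene in genes:
        vals = expr.loc[gene, samples].to_numpy(dtype=float)
        low = vals < np.median(vals)
        if low.sum() < 2 or (~low).sum() < 2:
            logger.warning("gene %s skipped in survival screen: group < 2", gene)
            continue
        stat, p = _logrank(times[low], events[low], times[~low], events[~low])
        rows[gene] = {"n_low": int(low.sum()), "n_high": int((~low).sum()),
                      "statistic": stat, "p": p}
        if return_curves:
            curves[gene] = _km_curves(times, events, low)
    result = pd.DataFrame.from_dict(rows, orient="index")
    result.index.name = "gene"
    return (result, curves) if return_curves else result


def _km_curves(times, events, low_mask) -> pd.DataFrame:
    from lifelines import KaplanMeierFitter

    frames = []
    for name, mask in (("low", low_mask), ("high", ~low_mask)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "group": name,
        }))
    return pd.concat(frames, ignore_index=True)


def flag_nonsignificant_ttest(
    expr: pd.DataFrame,
    labels: pd.Series,
    markers,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Markers invisible to univariate testing.

    Runs a two-sided Welch two-sample t-test (M0 vs M1) per marker gene and
    returns the markers whose p-value exceeds ``alpha`` — genes a per-gene
    differential test would not have found. Zero-variance genes (identical
    values in both classes) are defined to have p = 1 and are flagged.

    Returns a DataFrame indexed by gene with columns ``t`` and ``p``,
    restricted to the flagged genes.
    """
    labels = labels.reindex(expr.columns)
    g0 = expr.columns[(labels == NEGATIVE_LABEL).to_numpy()]
    g1 = expr.columns[(labels == POSITIVE_LABEL).to_numpy()]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs >= 2 samples for the t-test")
    markers = list(markers)
    a = expr.loc[markers, g0].to_numpy()
    b = expr.loc[markers, g1].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no signal
    table = pd.DataFrame({"t": t, "p": p}, index=pd.Index(markers, name="gene"))
    return table[table["p"] > alpha]


def ppi_adjacency(markers, network, reference=None) -> tuple:
    """Per-gene count of adjacent markers in an interaction network.

    For each gene g of ``reference`` (default: the marker set itself),
    ``count(g) = |neighbors(g) ∩ markers \\ {g}|``; genes absent from the
    network count 0. Returns ``(counts, mean)`` where ``counts`` is a Series
    indexed by the reference genes and ``mean`` is the average count over
    the reference — the context value against which individual counts are
    judged.

    ``network`` may be a networkx Graph or a two-column edge DataFrame.
    """
    import networkx as nx

    if isinstance(network, pd.DataFrame):
        g = nx.from_pandas_edgelist(network, network.columns[0], network.columns[1])
    else:
        g = network
    marker_set = set(markers)
    reference = sorted(marker_set if reference is None else set(reference))
    counts = {}
    for m in reference:
        if g.has_node(m):
            counts[m] = len((set(g.neighbors(m)) & marker_set) - {m})
        else:
            counts[m] = 0
    series = pd.Series(counts, name="adjacent_markers", dtype=int)
    return series, (float(series.mean()) if len(series) else 0.0)
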