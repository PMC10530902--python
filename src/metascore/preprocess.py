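"""Expression-matrix preprocessing: label binarization, ID collapsing,
log transform, and quantile normalization.

The intended order is fixed: collapse gene ids -> collapse sample ids ->
log transform -> quantile normalization. Collapsing averages duplicate
rows/columns (e.g. several transcript ids mapping to one gene symbol, or
several aliquot barcodes mapping to one participant); the log transform is
log2(x+1) by default so zero expression maps to zero; quantile
normalization forces every sample onto the common reference distribution
formed by averaging rank-ordered values across samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "binarize_n_stage",
    "collapse_mean",
    "log_transform",
    "quantile_normalize",
]

logger = logging.getLogger(__name__)

_N_STAGE_MAP = {"N0": "M0", "N1": "M1", "N2": "M1", "N3": "M1"}
_UNKNOWN = {"unknown", "", None}


def binarize_n_stage(stage_table) -> pd.Series:
    """Binarize nodal stage into two-class metastasis status.

    N0 (no nodal spread) maps to M0; N1/N2/N3 (any nodal spread) map to M1.
    Samples with stage ``"unknown"`` (or missing) are dropped; the dropped
    count is logged. Any other stage string raises ``ValueError`` naming the
    offending sample.

    Parameters
    ----------
    stage_table : mapping or pandas.Series
        sample_id -> stage in {"N0","N1","N2","N3","unknown"}.

    Returns
    -------
    pandas.Series
        sample_id -> "M0"/"M1".
    """
    if not isinstance(stage_table, pd.Series):
        stage_table = pd.Series(dict(stage_table))
    out = {}
    dropped = []
    for sample, stage in stage_table.items():
        if stage in _UNKNOWN or (isinstance(stage, float) and np.isnan(stage)):
            dropped.append(sample)
        elif stage in _N_STAGE_MAP:
            out[sample] = _N_STAGE_MAP[stage]
        else:
            raise ValueError(
                f"unrecognized N stage {stage!r} for sample {sample!r}"
            )
    if dropped:
        logger.info("dropped %d samples with unknown N stage", len(dropped))
    return pd.Series(out, name="status", dtype=object)


def collapse_mean(matrix: pd.DataFrame, id_map, axis: str = "genes") -> pd.DataFrame:
    """Collapse rows (or columns) to group means under an id mapping.

    Ids present in the matrix but absent from ``id_map`` are dropped with a
    logged count. Output ids follow the order of first appearance of each
    group among the mapped input ids.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x samples.
    id_map : mapping
        old_id -> group_id.
    axis : {"genes", "samples"}
        Which axis to collapse.
    """
    if not id_map:
        raise ValueError("empty id mapping")
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    id_map = dict(id_map)
    work = matrix if axis == "genes" else matrix.T
    mapped_mask = work.index.isin(id_map)
    n_dropped = int((~mapped_mask).sum())
    if n_dropped:
        logger.info("dropped %d unmapped %s ids", n_dropped, axis)
    work = work.loc[mapped_mask]
    groups = work.index.map(id_map)
    # sort=False preserves order of first appearance
    collapsed = work.groupby(groups, sort=False).mean()
    collapsed.index.name = matrix.index.name if axis == "genes" else matrix.columns.name
    return collapsed if axis == "genes" else collapsed.T


def log_transform(matrix: pd.DataFrame, base: float = 2.0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log(x + pseudocount); default log2(x+1), so 0 -> 0.

    All values must be >= 0 (raw expression); raises ``ValueError`` otherwise.
    """
    values = matrix.to_numpy()
    if (values < 0).any():
        raise ValueError("log transform requires nonnegative expression values")
    out = np.log(values + pseudocount) / np.log(base)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to a common reference.

    The reference is the across-sample mean of rank-ordered values. Each
    sample's values are replaced by reference values at their within-sample
    ranks; tied values receive the mean of the reference values at their
    tied ranks. After the operation every column's sorted vector equals the
    reference, and the operation is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties: average the reference values assigned within each tied run
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
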