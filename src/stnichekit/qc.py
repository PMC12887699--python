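"""Quality control, log-normalization, marker detection, signature scoring.

QC boundary semantics are literal: cells with *fewer than* ``min_counts``
total counts or *exceeding* ``max_mito`` mitochondrial fraction are dropped,
so equality keeps the cell; whole samples are then dropped when their
surviving cell count falls below ``min_cells_per_sample``.

Marker detection follows the Seurat FindAllMarkers convention: one-vs-rest
two-sided Wilcoxon rank-sum per gene on log-normalized values, genes
pre-filtered to fraction_in >= 0.1 and log2FC >= 0.25, log2FC computed on
mean expm1 with a 1e-9 pseudocount, BH correction over all reported tests.
For tiny groups (pooled n <= 10) the p-value is the exact enumeration value
rather than the normal approximation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._stats import bh_adjust, ranksum_exact_p
from .core import CountMatrix, GeneSet, NormalizedMatrix

log = logging.getLogger("stnichekit")

__all__ = ["qc_filter", "lognormalize", "find_markers", "signature_score", "MARKER_COLUMNS"]

MARKER_COLUMNS = [
    "cluster_label",
    "gene_id",
    "log2_fold_change",
    "fraction_in",
    "fraction_out",
    "p_value",
    "q_value",
]


def qc_filter(
    matrix: CountMatrix,
    min_counts: int = 1000,
    max_mito: float = 0.15,
    min_cells_per_sample: int = 1000,
) -> CountMatrix:
    """Drop low-count / high-mito cells, then whole under-sized samples.

    Keeps cells with total counts >= min_counts AND mito_fraction <= max_mito
    (equality kept on both boundaries), then drops samples whose surviving
    cell count is below min_cells_per_sample.  Order is preserved.
    Idempotent by construction.
    """
    meta = matrix.obs_meta
    for col in ("mito_fraction", "sample_id"):
        if col not in meta.columns:
            raise ValueError(f"qc_filter requires obs_meta column {col!r}")
    totals = matrix.obs_totals()
    pass_counts = totals >= min_counts
    pass_mito = meta["mito_fraction"].to_numpy() <= max_mito
    keep = pass_counts & pass_mito

    surviving = meta.loc[keep, "sample_id"].value_counts()
    good_samples = set(surviving[surviving >= min_cells_per_sample].index)
    pass_sample = meta["sample_id"].isin(good_samples).to_numpy()
    final = keep & pass_sample

    tally = {
        "low_counts": int((~pass_counts).sum()),
        "high_mito": int((pass_counts & ~pass_mito).sum()),
        "small_sample": int((keep & ~pass_sample).sum()),
    }
    log.info(
        "qc_filter: %d/%d cells kept (excluded: %s; samples kept: %d)",
        int(final.sum()), matrix.n_obs, tally, len(good_samples),
    )
    if not final.any():
        raise ValueError(f"qc_filter removed every cell; exclusion tally: {tally}")
    return matrix.subset_obs(final)


def lognormalize(matrix: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale * count / cell_total); zero-total cells stay all-zero."""
    x = matrix.dense().astype(float)
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.warning("lognormalize: %d observations with zero total left all-zero", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    values = np.log1p(scale * x / safe[:, None])
    values[zero] = 0.0
    return NormalizedMatrix(values=values, obs_ids=matrix.obs_ids, gene_ids=matrix.gene_ids)


def _ranksum_pvals_vectorized(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Tie/continuity-corrected two-sided MWU p per gene column."""
    res = stats.mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided", method="asymptotic")
    return np.asarray(res.pvalue, dtype=float)


def find_markers(
    norm: NormalizedMatrix,
    labels,
    min_fraction: float = 0.1,
    min_log2fc: float = 0.25,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker table per cluster label.

    Returns a MarkerTable DataFrame sorted within cluster by ascending
    q_value then descending log2 fold change.  Labels with fewer than 3
    observations are excluded with a warning; at least two usable labels
    are required.
    """
    labels = pd.Series(labels)
    if len(labels) != len(norm.obs_ids):
        raise ValueError("labels must align with the normalized matrix rows")
    labels.index = norm.obs_ids
    values = norm.values
    expm1 = np.expm1(values)

    usable = []
    for lab, n in labels.value_counts().items():
        if n < 3:
            log.warning("find_markers: label %r has %d (<3) observations; excluded", lab, n)
        else:
            usable.append(lab)
    if len(usable) < 2:
        raise ValueError("find_markers requires >=2 labels with >=3 observations each")
    usable = sorted(map(str, usable))

    eps = 1e-9
    rows = []
    for lab in usable:
        mask = (labels.astype(str) == lab).to_numpy()
        x_in, x_out = values[mask], values[~mask]
        frac_in = (x_in > 0).mean(axis=0)
        frac_out = (x_out > 0).mean(axis=0)
        log2fc = np.log2((expm1[mask].mean(axis=0) + eps) / (expm1[~mask].mean(axis=0) + eps))
        gate = (frac_in >= min_fraction) & (log2fc >= min_log2fc)
        idx = np.flatnonzero(gate)
        if idx.size == 0:
            continue
        n_total = len(x_in) + len(x_out)
        if n_total <= exact_max_n:
            pvals = np.array([ranksum_exact_p(x_in[:, j], x_out[:, j]) for j in idx])
        else:
            pvals = _ranksum_pvals_vectorized(x_in[:, idx], x_out[:, idx])
        for j, p in zip(idx, pvals):
            rows.append(
                (lab, norm.gene_ids[j], float(log2fc[j]), float(frac_in[j]), float(frac_out[j]), float(p))
            )

    table = pd.DataFrame(rows, columns=MARKER_COLUMNS[:6])
    if table.empty:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table = (
        table.sort_values(
            ["cluster_label", "q_value", "log2_fold_change"],
            ascending=[True, True, False],
            kind="stable",
        )
        .reset_index(drop=True)
    )
    log.info("find_markers: %d marker rows over %d clusters", len(table), len(usable))
    return table


def signature_score(norm: NormalizedMatrix, gene_set: GeneSet) -> pd.Series:
    """Mean normalized expression over the set genes present in the matrix.

    Absent genes are dropped with a warning; if no set gene is present the
    call fails.  Invariant to gene order and to absent genes being listed.
    """
    present = [g for g in gene_set.genes if g in norm.gene_ids]
    missing = set(gene_set.genes) - set(present)
    if missing:
        log.warning(
            "signature_score(%s): %d/%d genes absent from matrix",
            gene_set.name, len(missing), len(gene_set.genes),
        )
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    cols = norm.gene_ids.get_indexer(sorted(present))
    score = norm.values[:, cols].mean(axis=1)
    return pd.Series(score, index=norm.obs_ids, name=gene_set.name)
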