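"""Neighbor-aware ligand-receptor colocalization scoring.

The score for a spot combines its own expression of one signal with the
maximum expression of the partner signal among its K nearest neighboring
spots (self excluded), in both directions, keeping the larger product:

    s_i = max( a_i * max_{j in N(i)} b_j ,  b_i * max_{j in N(i)} a_j )

Signals are depth-normalized counts (relative counts rescaled by the median
spot total); extreme scores are winsorized at a high quantile; "high"
expression masks select the top decile of each signal, and their overlap is
compared against the independence expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import hypergeom_tails
from .core import SpatialDataset
from .spatial import NeighborGraph

log = logging.getLogger("stnichekit")

__all__ = ["depth_normalize", "coloc_score", "high_mask", "overlap_map", "ColocResult", "colocalize"]


def depth_normalize(spatial: SpatialDataset, genes) -> np.ndarray:
    """Per-spot depth-normalized signal for one or more genes.

    value = count / spot_total * median(spot_total); a multi-gene signal is
    the mean of the per-gene normalized values.  Zero-total spots yield 0
    with a warning; genes absent from the matrix are dropped with a warning
    and having none present is fatal.
    """
    if isinstance(genes, str):
        genes = [genes]
    present = [g for g in genes if g in spatial.matrix.gene_ids]
    missing = set(genes) - set(present)
    if missing:
        log.warning("depth_normalize: genes absent from matrix: %s", sorted(missing))
    if not present:
        raise ValueError(f"none of the listed genes present: {sorted(genes)}")
    totals = spatial.matrix.obs_totals().astype(float)
    zero = totals == 0
    if zero.any():
        log.warning("depth_normalize: %d zero-total spots set to signal 0", int(zero.sum()))
    med = float(np.median(totals))
    cols = spatial.matrix.gene_ids.get_indexer(present)
    x = spatial.matrix.dense()[:, cols].astype(float)
    safe = np.where(zero, 1.0, totals)
    normalized = x / safe[:, None] * med
    normalized[zero] = 0.0
    return normalized.mean(axis=1)


def coloc_score(sig_a, sig_b, graph: NeighborGraph, trim_q: float = 0.99) -> np.ndarray:
    """Per-spot colocalization scores, winsorized at the trim_q quantile.

    Values above the trim_q quantile of the raw scores are capped at that
    quantile (spots are kept, not dropped).
    """
    sig_a = np.asarray(sig_a, dtype=float)
    sig_b = np.asarray(sig_b, dtype=float)
    if sig_a.shape != sig_b.shape or len(sig_a) != graph.n_spots:
        raise ValueError(
            f"signal/graph size mismatch: {sig_a.shape}, {sig_b.shape}, n_spots={graph.n_spots}"
        )
    nb_max_a = sig_a[graph.indices].max(axis=1)
    nb_max_b = sig_b[graph.indices].max(axis=1)
    scores = np.maximum(sig_a * nb_max_b, sig_b * nb_max_a)
    if trim_q is not None and trim_q < 1.0:
        cap = np.quantile(scores, trim_q)
        scores = np.minimum(scores, cap)
    return scores


def high_mask(signal, top_frac: float = 0.10) -> np.ndarray:
    """Boolean mask of the ceil(top_frac * n) largest values.

    Ties at the threshold are broken by ascending spot index so exactly
    ceil(top_frac * n) spots are selected, bit-reproducibly.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 10:
        log.warning("high_mask: only %d spots (<10); top-fraction mask is coarse", n)
    n_high = min(n, math.ceil(top_frac * n))
    order = np.lexsort((np.arange(n), -signal))  # by value desc, then index asc
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_high]] = True
    return mask


def overlap_map(mask_a, mask_b) -> dict:
    """Overlap of two high-expression masks over the same spot universe.

    Returns the AND mask, overlap count, Jaccard index, the expected count
    under independence (n * f_a * f_b), and the hypergeometric enrichment p
    with spots as the universe.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must cover the same spot universe")
    n = len(mask_a)
    overlap = mask_a & mask_b
    count = int(overlap.sum())
    union = int((mask_a | mask_b).sum())
    jaccard = count / union if union else 0.0
    expected = n * mask_a.mean() * mask_b.mean()
    p_enrich, _ = hypergeom_tails(n, int(mask_a.sum()), int(mask_b.sum()), count)
    return {
        "mask": overlap,
        "count": count,
        "jaccard": float(jaccard),
        "expected": float(expected),
        "p_enrich": float(p_enrich),
    }


@dataclass
class ColocResult:
    """Scores plus the two high-expression masks and their overlap summary."""

    scores: pd.Series
    mask_a: np.ndarray
    mask_b: np.ndarray
    overlap: dict
    trim_q: float
    top_frac: float


def colocalize(
    spatial: SpatialDataset,
    genes_a,
    genes_b,
    graph: NeighborGraph,
    trim_q: float = 0.99,
    top_frac: float = 0.10,
) -> ColocResult:
    """End-to-end colocalization of two gene signals on one spatial sample."""
    sig_a = depth_normalize(spatial, genes_a)
    sig_b = depth_normalize(spatial, genes_b)
    scores = coloc_score(sig_a, sig_b, graph, trim_q=trim_q)
    mask_a = high_mask(sig_a, top_frac)
    mask_b = high_mask(sig_b, top_frac)
    return ColocResult(
        scores=pd.Series(scores, index=spatial.matrix.obs_ids, name="coloc_score"),
        mask_a=mask_a,
        mask_b=mask_b,
        overlap=overlap_map(mask_a, mask_b),
        trim_q=trim_q,
        top_frac=top_frac,
    )
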