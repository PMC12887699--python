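"""Spot neighborhood structure and spatial statistics.

Four primitives: a deterministic Euclidean KNN graph (self excluded, ties
broken by ascending spot index), permutation z-scores for label-pair
neighborhood enrichment, a signed nearest-member radial distance to a target
region (negative inside, positive outside, square-root transformed for
display), and binned distance-expression profiles along that axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import SpatialDataset

log = logging.getLogger("stnichekit")

__all__ = [
    "NeighborGraph",
    "knn_graph",
    "nhood_enrichment",
    "RadialDistanceField",
    "radial_distance",
    "distance_profile",
]


@dataclass
class NeighborGraph:
    """Per-spot K nearest neighbors (indices and distances), self excluded."""

    indices: np.ndarray   # (n, k) int
    distances: np.ndarray # (n, k) float
    k: int
    metric: str = "euclidean"

    @property
    def n_spots(self) -> int:
        return self.indices.shape[0]


def knn_graph(coords, k: int = 6, chunk: int = 512) -> NeighborGraph:
    """Euclidean KNN excluding self; distance ties broken by ascending index.

    Duplicate coordinates are allowed (zero distances, self still excluded).
    If fewer than k other spots exist, all others are used.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("knn_graph requires at least 2 spots")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    k_eff = min(k, n - 1)
    indices = np.empty((n, k_eff), dtype=np.intp)
    distances = np.empty((n, k_eff), dtype=float)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        rows = np.arange(start, stop)
        d[rows - start, rows] = np.inf  # exclude self
        # stable argsort on distance -> ties resolved by ascending spot index
        order = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
        indices[start:stop] = order
        distances[start:stop] = np.take_along_axis(d, order, axis=1)
    return NeighborGraph(indices=indices, distances=distances, k=k_eff)


def nhood_enrichment(
    labels, graph: NeighborGraph, n_perms: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Permutation z-scores for neighborhood label-pair enrichment.

    Observed directed neighbor-pair counts per label pair are compared with
    a null built by permuting the label vector over spots n_perms times;
    z = (obs - mean_null) / sd_null, with z = 0 where sd_null = 0.  The
    matrix is symmetrized by averaging (i, j) and (j, i).
    """
    if seed is None:
        raise ValueError("nhood_enrichment requires an explicit seed")
    labels = pd.Series(labels).astype(str)
    cats = sorted(labels.unique())
    n_cat = len(cats)
    if n_cat < 2:
        log.warning("nhood_enrichment: single label; returning all-zero matrix")
        return pd.DataFrame(0.0, index=cats, columns=cats)
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()

    src = np.repeat(np.arange(graph.n_spots), graph.indices.shape[1])
    dst = graph.indices.ravel()

    def pair_counts(c: np.ndarray) -> np.ndarray:
        return np.bincount(c[src] * n_cat + c[dst], minlength=n_cat * n_cat).astype(float)

    obs = pair_counts(codes)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perms, n_cat * n_cat))
    for p in range(n_perms):
        null[p] = pair_counts(rng.permutation(codes))
    mean, sd = null.mean(axis=0), null.std(axis=0)
    z = np.zeros_like(obs)
    nz = sd > 0
    z[nz] = (obs[nz] - mean[nz]) / sd[nz]
    z = z.reshape(n_cat, n_cat)
    z = (z + z.T) / 2.0
    return pd.DataFrame(z, index=cats, columns=cats)


@dataclass
class RadialDistanceField:
    """Signed (and optionally sqrt-transformed) distance of each spot to a
    target region: <= 0 inside the region, > 0 outside."""

    values: pd.Series
    raw: pd.Series
    target_region: str
    transform: str = "signed_sqrt"


def radial_distance(
    spatial: SpatialDataset, target_region: str, transform: str = "signed_sqrt"
) -> RadialDistanceField:
    """Nearest-member signed distance to a target region.

    Outside the region: +distance to the nearest target spot; inside:
    -distance to the nearest non-target spot.  'signed_sqrt' stores
    sign(d) * sqrt(|d|) (the display convention for radial profiles);
    'none' stores the raw signed distance.
    """
    inside = (spatial.region_label == target_region).to_numpy()
    if not inside.any():
        raise ValueError(f"target region {target_region!r} is empty")
    if inside.all():
        raise ValueError(f"target region {target_region!r} covers all spots")
    coords = spatial.coords
    raw = np.empty(len(inside))
    raw[~inside] = cdist(coords[~inside], coords[inside]).min(axis=1)
    raw[inside] = -cdist(coords[inside], coords[~inside]).min(axis=1)
    if transform == "signed_sqrt":
        values = np.sign(raw) * np.sqrt(np.abs(raw))
    elif transform == "none":
        values = raw.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")
    index = spatial.matrix.obs_ids
    return RadialDistanceField(
        values=pd.Series(values, index=index, name="distance"),
        raw=pd.Series(raw, index=index, name="raw_distance"),
        target_region=target_region,
        transform=transform,
    )


def distance_profile(
    expr, field: RadialDistanceField, n_bins: int = 25, min_spots: int = 3
) -> pd.DataFrame:
    """Binned expression along the radial-distance axis.

    ``expr``: DataFrame (spots x genes) or Series of per-spot values aligned
    with the field.  Bins are equal-width over the observed transformed
    range; per gene and bin the mean, spot count and normal-approximation
    95% CI are reported.  Bins with fewer than ``min_spots`` spots are
    emitted with missing statistics.
    """
    if isinstance(expr, pd.Series):
        expr = expr.to_frame()
    expr = expr.loc[field.values.index]
    x = field.values.to_numpy()
    lo, hi = float(x.min()), float(x.max())
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0

    rows = []
    for gene in expr.columns:
        v = expr[gene].to_numpy(dtype=float)
        for b in range(n_bins):
            sel = v[which == b]
            n = len(sel)
            if n < min_spots:
                rows.append((gene, b, centers[b], n, np.nan, np.nan, np.nan))
                continue
            m = float(sel.mean())
            half = 1.96 * float(sel.std(ddof=1)) / np.sqrt(n) if n > 1 else 0.0
            rows.append((gene, b, centers[b], n, m, m - half, m + half))
    return pd.DataFrame(
        rows, columns=["gene", "bin", "bin_center", "n_spots", "mean", "ci_low", "ci_high"]
    )
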