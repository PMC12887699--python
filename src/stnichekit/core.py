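"""Core in-memory containers shared by every pipeline stage.

The pipeline moves four kinds of objects around: raw count matrices (cells or
spots × genes), spatial samples (counts + planar spot coordinates + region
labels), gene signatures, and the sample→group design used for cohort
statistics.  Each container validates its own invariants at construction so
downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "SpatialDataset",
    "GeneSet",
    "GroupDesign",
]


def _check_unique(ids: Sequence[str], what: str) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:10]
        raise ValueError(f"duplicate {what}: {dups}")
    return idx


@dataclass
class CountMatrix:
    """Observations × genes non-negative integer counts with metadata.

    ``counts`` may be a dense ndarray or any scipy sparse matrix; it is kept
    as given.  ``obs_meta`` is indexed by ``obs_ids`` and must cover exactly
    those observations.  Optional metadata columns used downstream:
    ``sample_id``, ``cluster_label``, ``mito_fraction``.
    """

    counts: "np.ndarray | sp.spmatrix"
    obs_ids: pd.Index
    gene_ids: pd.Index
    obs_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "obs_ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        n_obs, n_genes = self.counts.shape
        if n_obs != len(self.obs_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.obs_ids)} obs_ids x {len(self.gene_ids)} gene_ids"
            )
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and np.min(data) < 0:
            raise ValueError("counts must be non-negative")
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=self.obs_ids)
        else:
            if not self.obs_meta.index.equals(pd.Index(self.obs_ids)):
                if set(self.obs_meta.index) != set(self.obs_ids):
                    raise ValueError("obs_meta must cover exactly obs_ids")
                self.obs_meta = self.obs_meta.loc[self.obs_ids]

    # -- convenience -------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def obs_totals(self) -> np.ndarray:
        """Total counts per observation (sequencing depth)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_obs(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, (pd.Index, list)):
            pos = self.obs_ids.get_indexer(mask_or_ids)
            if (pos < 0).any():
                raise KeyError("unknown obs ids in subset")
        else:
            pos = np.flatnonzero(np.asarray(mask_or_ids))
        return CountMatrix(
            counts=self.counts[pos],
            obs_ids=self.obs_ids[pos],
            gene_ids=self.gene_ids,
            obs_meta=self.obs_meta.iloc[pos],
        )

    def to_anndata(self):
        """Interop hook for the scanpy ecosystem (requires anndata)."""
        import anndata as ad

        return ad.AnnData(
            X=sp.csr_matrix(self.counts),
            obs=self.obs_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression values aligned with a CountMatrix."""

    values: np.ndarray
    obs_ids: pd.Index
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.obs_ids = pd.Index(self.obs_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.values.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)


@dataclass
class SpatialDataset:
    """One spatial sample: spot counts, planar coordinates, region labels.

    Coordinates are abstract planar units (no image registration); distances
    are relative throughout.  ``region_label`` values are drawn from the
    finite ``regions`` set (declared or inferred from the labels).
    """

    matrix: CountMatrix
    coords: np.ndarray
    region_label: pd.Series
    regions: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.matrix.n_obs, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({self.matrix.n_obs}, 2)"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        self.region_label = pd.Series(self.region_label)
        if len(self.region_label) != self.matrix.n_obs:
            raise ValueError("one region label per spot required")
        self.region_label.index = self.matrix.obs_ids
        if self.regions is None:
            self.regions = tuple(pd.unique(self.region_label))
        else:
            self.regions = tuple(self.regions)
            unknown = set(self.region_label) - set(self.regions)
            if unknown:
                raise ValueError(f"region labels outside declared set: {sorted(unknown)}")

    @property
    def n_spots(self) -> int:
        return self.matrix.n_obs


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene identifiers."""

    name: str
    genes: tuple

    def __init__(self, name: str, genes: Sequence[str]):
        genes = tuple(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} has duplicate genes")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GroupDesign:
    """obs → sample → group mapping with exactly two group levels."""

    sample_to_group: pd.Series
    obs_to_sample: pd.Series

    def __post_init__(self) -> None:
        self.sample_to_group = pd.Series(self.sample_to_group)
        self.obs_to_sample = pd.Series(self.obs_to_sample)
        levels = pd.unique(self.sample_to_group)
        if len(levels) != 2:
            raise ValueError(f"exactly two group levels required, got {list(levels)}")
        unknown = set(self.obs_to_sample) - set(self.sample_to_group.index)
        if unknown:
            raise ValueError(f"observations map to undeclared samples: {sorted(unknown)[:5]}")

    @property
    def groups(self) -> tuple:
        return tuple(sorted(pd.unique(self.sample_to_group)))

    def obs_groups(self) -> pd.Series:
        """Group label per observation."""
        return self.obs_to_sample.map(self.sample_to_group)
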