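"""Paired single-cell / spatial simulator with planted ground truth.

The generator emulates the structure of a neoadjuvant-ICB cohort: cell types
with disjoint planted marker genes (negative-binomial counts, overdispersed
like real scRNA-seq), a square-lattice spatial sample partitioned into a
tumor-like core, a stromal-immune interface ring, and outer stroma, and a
two-arm responder/non-responder design in which one cell type is planted at
a configurable odds ratio between the arms.  Spots are small mixtures of
2-5 cells, mirroring the sub-cellular resolution of spot-based platforms
(the reason niche annotation needs a marker-overlap test at all).

At the interface ring the two configured partner types are planted in
adjacent lattice positions (a checkerboard of typeA-dominant and
typeB-dominant spots), giving downstream colocalization something real to
find.  The dominant fractions of the two partners are deliberately
asymmetric so that every region, including the interface, has a strictly
dominant type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CountMatrix, GroupDesign, SpatialDataset

__all__ = ["SimulationConfig", "GroundTruth", "simulate_paired", "simulate_null_spatial"]

REGIONS = ("core", "interface", "stroma")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired simulator.

    ``dispersion`` is the negative-binomial size r (variance = mu + mu^2/r);
    ``region_layout`` gives the core and interface radii as fractions of the
    lattice side; ``depth_sigma`` is the lognormal sigma of per-cell depth
    factors; ``mito_beta`` the Beta(a, b) parameters of simulated
    mitochondrial fractions.
    """

    cell_types: tuple = ("epithelial", "fibroblast", "tcell", "lpcaf", "lam")
    n_genes: int = 300
    markers_per_type: int = 10
    marker_fold: float = 8.0
    base_mean: float = 5.0
    dispersion: float = 2.0
    n_cells_per_sample: int = 1000
    n_samples_per_group: int = 10
    enriched_type: str = "lam"
    enrichment_or: float = 3.0
    grid_side: int = 20
    region_layout: Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.28, "interface": 0.42}
    )
    interface_pair: tuple = ("lpcaf", "lam")
    cells_per_spot: tuple = (2, 5)
    depth_sigma: float = 0.3
    mito_beta: tuple = (2.0, 25.0)
    seed: int = 0

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def validate(self) -> None:
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                f"markers_per_type x n_cell_types = "
                f"{self.markers_per_type * self.n_cell_types} exceeds n_genes={self.n_genes}"
            )
        if self.enrichment_or <= 0:
            raise ValueError("enrichment_or must be > 0")
        if self.grid_side < 4:
            raise ValueError("grid_side must be >= 4")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.markers_per_type * self.marker_fold >= self.n_genes:
            raise ValueError(
                "markers_per_type x marker_fold must stay below n_genes "
                "(mean-preserving folds need positive background expression)"
            )
        if self.enriched_type not in self.cell_types:
            raise ValueError(f"enriched_type {self.enriched_type!r} not in cell_types")
        for t in self.interface_pair:
            if t not in self.cell_types:
                raise ValueError(f"interface type {t!r} not in cell_types")
        if self.seed is None:
            raise ValueError("simulation requires an explicit seed")


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream recovery checks."""

    cell_types: pd.Series              # obs_id -> type
    spot_region: pd.Series             # spot_id -> region
    region_composition: dict           # region -> {type: expected fraction}
    marker_genes: dict                 # type -> list of gene ids
    interface_pair: tuple
    enriched_type: str
    enrichment_or: float
    spot_type_counts: pd.DataFrame = None  # realized cells per type per spot
    spot_dominant: pd.Series = None        # interface spots -> dominant partner

    def dominant_type(self, region: str) -> str:
        comp = self.region_composition[region]
        return max(comp, key=comp.get)

    def to_json_dict(self) -> dict:
        return {
            "cell_types": self.cell_types.to_dict(),
            "spot_region": self.spot_region.to_dict(),
            "region_composition": self.region_composition,
            "marker_genes": self.marker_genes,
            "interface_pair": list(self.interface_pair),
            "enriched_type": self.enriched_type,
            "enrichment_or": self.enrichment_or,
        }


# ---------------------------------------------------------------------------


def _type_means(cfg: SimulationConfig) -> tuple[np.ndarray, dict]:
    """Per-type mean expression vectors and the planted marker map.

    Marker folds are mean-preserving: boosting a type's markers is paid for
    by proportionally down-scaling its non-marker genes, so every type has
    the same expected total counts.  This keeps sequencing depth independent
    of cell-type composition — without it, library-size normalization would
    induce spurious correlation between unrelated genes across spots.
    """
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    means = np.full((cfg.n_cell_types, cfg.n_genes), cfg.base_mean)
    m = cfg.markers_per_type
    background_scale = (cfg.n_genes - m * cfg.marker_fold) / (cfg.n_genes - m)
    markers: dict[str, list[str]] = {}
    for t, name in enumerate(cfg.cell_types):
        lo, hi = t * m, (t + 1) * m
        means[t] *= background_scale
        means[t, lo:hi] = cfg.base_mean * cfg.marker_fold
        markers[name] = genes[lo:hi]
    return means, markers


def _nb_counts(rng: np.random.Generator, means: np.ndarray, r: float) -> np.ndarray:
    """Negative-binomial draws with size r and the given mean matrix."""
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def _draw_cells(rng, cfg, type_means, type_codes):
    """Counts for cells of the given type codes, with lognormal depth factors."""
    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=len(type_codes))
    mu = type_means[type_codes] * depth[:, None]
    return _nb_counts(rng, mu, cfg.dispersion)


def _group_proportions(cfg: SimulationConfig) -> dict:
    """Cell-type proportions per arm; the enriched arm's odds for
    ``enriched_type`` are multiplied by the planted odds ratio."""
    k = cfg.n_cell_types
    base = np.full(k, 1.0 / k)
    e_idx = cfg.cell_types.index(cfg.enriched_type)
    odds = base[e_idx] / (1 - base[e_idx]) * cfg.enrichment_or
    p_enriched = odds / (1 + odds)
    enriched = base * (1 - p_enriched) / (1 - base[e_idx])
    enriched[e_idx] = p_enriched
    # "NE" (non-expanded / non-responder) is the arm carrying the enrichment
    return {"E": base, "NE": enriched}


def _region_compositions(cfg: SimulationConfig) -> dict:
    """Expected per-spot compositions; interface split into A/B-dominant."""
    k = cfg.n_cell_types
    names = cfg.cell_types
    a, b = cfg.interface_pair

    def comp(weights: dict) -> np.ndarray:
        rest = (1.0 - sum(weights.values())) / (k - len(weights))
        return np.array([weights.get(n, rest) for n in names])

    return {
        "core": comp({names[0]: 0.8}),
        "stroma": comp({names[1]: 0.8}),
        "interface_a": comp({a: 0.65, b: 0.15}),
        "interface_b": comp({b: 0.40, a: 0.30}),
    }


def _lattice(cfg: SimulationConfig):
    """Lattice coordinates, region label and checkerboard parity per spot."""
    g = cfg.grid_side
    ix, iy = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    center = (g - 1) / 2.0
    r = np.hypot(ix - center, iy - center)
    r_core = cfg.region_layout["core"] * g
    r_int = cfg.region_layout["interface"] * g
    region = np.where(r <= r_core, "core", np.where(r <= r_int, "interface", "stroma"))
    parity = (ix + iy) % 2  # 0 -> typeA-dominant at the interface
    coords = np.column_stack([ix, iy]).astype(float)
    return coords, region, parity


def simulate_paired(cfg: SimulationConfig):
    """Generate (cells: CountMatrix, spatial: SpatialDataset, design, truth).

    Identical config + seed gives bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    type_means, markers = _type_means(cfg)
    genes = pd.Index([f"g{i:04d}" for i in range(cfg.n_genes)])

    # ---- single cells across samples and arms ----------------------------
    props = _group_proportions(cfg)
    type_codes_all, sample_ids, cell_ids = [], [], []
    for group in ("E", "NE"):
        for s in range(cfg.n_samples_per_group):
            sid = f"{group}{s}"
            codes = rng.choice(cfg.n_cell_types, size=cfg.n_cells_per_sample, p=props[group])
            type_codes_all.append(codes)
            sample_ids += [sid] * cfg.n_cells_per_sample
            cell_ids += [f"{sid}_c{i:05d}" for i in range(cfg.n_cells_per_sample)]
    type_codes = np.concatenate(type_codes_all)
    counts = _draw_cells(rng, cfg, type_means, type_codes)
    mito = rng.beta(cfg.mito_beta[0], cfg.mito_beta[1], size=len(type_codes))
    cell_types = pd.Series(
        np.asarray(cfg.cell_types)[type_codes], index=pd.Index(cell_ids), name="cell_type"
    )
    obs_meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cluster_label": cell_types.values,
            "mito_fraction": mito,
        },
        index=pd.Index(cell_ids),
    )
    cells = CountMatrix(counts=counts, obs_ids=pd.Index(cell_ids), gene_ids=genes, obs_meta=obs_meta)

    sample_to_group = pd.Series(
        {f"{g}{s}": g for g in ("E", "NE") for s in range(cfg.n_samples_per_group)}
    )
    design = GroupDesign(
        sample_to_group=sample_to_group,
        obs_to_sample=pd.Series(sample_ids, index=pd.Index(cell_ids)),
    )

    # ---- spatial sample ---------------------------------------------------
    coords, region, parity = _lattice(cfg)
    comps = _region_compositions(cfg)
    n_spots = len(region)
    spot_ids = pd.Index([f"spot_{i:04d}" for i in range(n_spots)])

    lo, hi = cfg.cells_per_spot
    n_cells_spot = rng.integers(lo, hi + 1, size=n_spots)
    spot_type_counts = np.zeros((n_spots, cfg.n_cell_types), dtype=int)
    dominant = {}
    for i in range(n_spots):
        if region[i] == "interface":
            key = "interface_a" if parity[i] == 0 else "interface_b"
            dominant[spot_ids[i]] = cfg.interface_pair[0 if parity[i] == 0 else 1]
        else:
            key = region[i]
        spot_type_counts[i] = rng.multinomial(n_cells_spot[i], comps[key])
    constituent_codes = np.repeat(
        np.tile(np.arange(cfg.n_cell_types), n_spots), spot_type_counts.ravel()
    )
    constituent_counts = _draw_cells(rng, cfg, type_means, constituent_codes)
    owner = np.repeat(np.arange(n_spots), spot_type_counts.sum(axis=1))
    spot_counts = np.zeros((n_spots, cfg.n_genes), dtype=np.int64)
    np.add.at(spot_counts, owner, constituent_counts)

    spot_meta = pd.DataFrame(
        {"sample_id": "spatial0", "x": coords[:, 0], "y": coords[:, 1], "region": region},
        index=spot_ids,
    )
    spatial = SpatialDataset(
        matrix=CountMatrix(counts=spot_counts, obs_ids=spot_ids, gene_ids=genes, obs_meta=spot_meta),
        coords=coords,
        region_label=pd.Series(region, index=spot_ids, name="region"),
        regions=REGIONS,
    )

    # ---- ground truth -----------------------------------------------------
    n_a = int(((region == "interface") & (parity == 0)).sum())
    n_b = int(((region == "interface") & (parity == 1)).sum())
    iface = (comps["interface_a"] * n_a + comps["interface_b"] * n_b) / max(n_a + n_b, 1)
    region_composition = {
        "core": dict(zip(cfg.cell_types, comps["core"].round(12))),
        "interface": dict(zip(cfg.cell_types, iface.round(12))),
        "stroma": dict(zip(cfg.cell_types, comps["stroma"].round(12))),
    }
    truth = GroundTruth(
        cell_types=cell_types,
        spot_region=pd.Series(region, index=spot_ids, name="region"),
        region_composition=region_composition,
        marker_genes=markers,
        interface_pair=tuple(cfg.interface_pair),
        enriched_type=cfg.enriched_type,
        enrichment_or=cfg.enrichment_or,
        spot_type_counts=pd.DataFrame(spot_type_counts, index=spot_ids, columns=cfg.cell_types),
        spot_dominant=pd.Series(dominant, name="dominant_type"),
    )
    return cells, spatial, design, truth


def simulate_null_spatial(cfg: SimulationConfig) -> SpatialDataset:
    """Negative control: same lattice, uniformly random region labels, every
    spot an even mixture of all types, nothing planted."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    type_means, _ = _type_means(cfg)
    genes = pd.Index([f"g{i:04d}" for i in range(cfg.n_genes)])
    coords, _, _ = _lattice(cfg)
    n_spots = len(coords)
    spot_ids = pd.Index([f"spot_{i:04d}" for i in range(n_spots)])

    region = np.asarray(REGIONS)[rng.integers(0, len(REGIONS), size=n_spots)]
    lo, hi = cfg.cells_per_spot
    n_cells_spot = rng.integers(lo, hi + 1, size=n_spots)
    uniform = np.full(cfg.n_cell_types, 1.0 / cfg.n_cell_types)
    spot_type_counts = rng.multinomial(n_cells_spot, uniform)
    constituent_codes = np.repeat(
        np.tile(np.arange(cfg.n_cell_types), n_spots), spot_type_counts.ravel()
    )
    constituent_counts = _draw_cells(rng, cfg, type_means, constituent_codes)
    owner = np.repeat(np.arange(n_spots), spot_type_counts.sum(axis=1))
    spot_counts = np.zeros((n_spots, cfg.n_genes), dtype=np.int64)
    np.add.at(spot_counts, owner, constituent_counts)

    spot_meta = pd.DataFrame(
        {"sample_id": "null0", "x": coords[:, 0], "y": coords[:, 1], "region": region},
        index=spot_ids,
    )
    return SpatialDataset(
        matrix=CountMatrix(counts=spot_counts, obs_ids=spot_ids, gene_ids=genes, obs_meta=spot_meta),
        coords=coords,
        region_label=pd.Series(region, index=spot_ids, name="region"),
        regions=REGIONS,
    )
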