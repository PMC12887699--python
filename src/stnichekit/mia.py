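"""Multimodal Intersection Analysis: hypergeometric overlap of cell-type
marker sets with spatial-cluster marker sets, plus rule-based niche naming.

Spot-based platforms do not resolve single cells, so spatial clusters are
annotated by testing whether the genes that mark a cluster overlap the
genes that mark a cell type more than chance: the overlap k of the two
top-marker sets within a shared gene universe follows a hypergeometric
distribution under independence.  The signed score is -log10(p) of the
smaller tail, positive for enrichment, negative for depletion, so a single
matrix drives both heatmaps and niche-assignment rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import hypergeom_tails
from .core import GeneSet

log = logging.getLogger("stnichekit")

__all__ = [
    "hypergeom_overlap",
    "mia_matrix",
    "annotate_niches",
    "EnrichmentMatrix",
    "NicheRule",
    "NicheAnnotation",
]

P_FLOOR = 1e-300


def hypergeom_overlap(universe_n: int, set_a: GeneSet, set_b: GeneSet):
    """(k, p_enrich, p_deplete) for the overlap of two gene sets.

    k = |A n B|; p_enrich = P(X >= k) and p_deplete = P(X <= k) for
    X ~ Hypergeometric(universe_n, |A|, |B|).  Both tails include P(X = k),
    so p_enrich + p_deplete >= 1 always.
    """
    if universe_n < max(len(set_a), len(set_b)):
        raise ValueError(
            f"universe_n={universe_n} smaller than a set "
            f"(|{set_a.name}|={len(set_a)}, |{set_b.name}|={len(set_b)})"
        )
    k = len(set(set_a.genes) & set(set_b.genes))
    p_enrich, p_deplete = hypergeom_tails(universe_n, len(set_a), len(set_b), k)
    return k, p_enrich, p_deplete


@dataclass
class EnrichmentMatrix:
    """Signed MIA scores (rows: cell types, cols: spatial clusters) with the
    companion raw p-value and overlap-count matrices."""

    score: pd.DataFrame
    p_enrich: pd.DataFrame
    p_deplete: pd.DataFrame
    overlap: pd.DataFrame

    @property
    def cell_types(self) -> pd.Index:
        return self.score.index

    @property
    def clusters(self) -> pd.Index:
        return self.score.columns


def _top_marker_sets(markers: pd.DataFrame, top_n: int) -> dict[str, list[str]]:
    """Up to top_n genes per cluster, best first (q ascending, log2FC descending)."""
    ordered = markers.sort_values(
        ["q_value", "log2_fold_change"], ascending=[True, False], kind="stable"
    )
    return {
        str(lab): grp["gene_id"].head(top_n).tolist()
        for lab, grp in ordered.groupby("cluster_label", sort=True)
    }


def _signed_score(p_enrich: float, p_deplete: float) -> float:
    if p_enrich <= p_deplete:
        return -np.log10(max(p_enrich, P_FLOOR))
    return np.log10(max(p_deplete, P_FLOOR))


def mia_matrix(
    ct_markers: pd.DataFrame,
    region_markers: pd.DataFrame,
    universe,
    top_n: int = 100,
    max_q: float | None = None,
    cell_types=None,
    clusters=None,
) -> EnrichmentMatrix:
    """Pairwise hypergeometric enrichment of cell-type vs region marker sets.

    ``universe`` is the list of genes tested in both modalities; every marker
    gene must belong to it.  ``max_q`` optionally restricts both tables to
    significant markers (q < max_q) before the top_n cut, so that clusters
    with few true markers are not padded with noise genes that merely pass
    the fold-change gate.  ``cell_types`` / ``clusters`` optionally declare
    the full row/column sets; any declared cluster contributing zero markers
    yields a zero-score column/row with a warning.
    """
    if ct_markers.empty or region_markers.empty:
        raise ValueError("marker tables must be non-empty")
    universe = pd.Index(universe)
    if universe.has_duplicates:
        raise ValueError("universe contains duplicate genes")
    uni = set(universe)
    for name, table in (("cell-type", ct_markers), ("region", region_markers)):
        offenders = sorted(set(table["gene_id"]) - uni)
        if offenders:
            raise ValueError(f"{name} marker genes outside declared universe: {offenders[:10]}")

    if max_q is not None:
        ct_markers = ct_markers[ct_markers["q_value"] < max_q]
        region_markers = region_markers[region_markers["q_value"] < max_q]
        if ct_markers.empty or region_markers.empty:
            raise ValueError(f"no markers left at q < {max_q}")
    ct_sets = _top_marker_sets(ct_markers, top_n)
    rg_sets = _top_marker_sets(region_markers, top_n)
    for declared, sets in ((cell_types, ct_sets), (clusters, rg_sets)):
        for name in declared or ():
            sets.setdefault(str(name), [])
    types, regions = list(ct_sets), list(rg_sets)
    for lab, sets in (("cell type", ct_sets), ("region", rg_sets)):
        for name, genes in sets.items():
            if not genes:
                log.warning("mia_matrix: %s %r has zero markers; scores set to 0", lab, name)

    n = len(universe)
    score = pd.DataFrame(0.0, index=types, columns=regions)
    p_en = pd.DataFrame(1.0, index=types, columns=regions)
    p_de = pd.DataFrame(1.0, index=types, columns=regions)
    kmat = pd.DataFrame(0, index=types, columns=regions)
    for t in types:
        if not ct_sets[t]:
            continue
        set_t = GeneSet(t, ct_sets[t])
        for r in regions:
            if not rg_sets[r]:
                continue
            k, pe, pd_ = hypergeom_overlap(n, set_t, GeneSet(r, rg_sets[r]))
            score.loc[t, r] = _signed_score(pe, pd_)
            p_en.loc[t, r], p_de.loc[t, r], kmat.loc[t, r] = pe, pd_, k
    return EnrichmentMatrix(score=score, p_enrich=p_en, p_deplete=p_de, overlap=kmat)


@dataclass(frozen=True)
class NicheRule:
    """A niche is assigned when every required cell type scores above
    ``min_score`` (1.3 ~ p < 0.05 on the -log10 scale)."""

    name: str
    required_types: tuple
    min_score: float = 1.3

    def matches(self, column: pd.Series) -> bool:
        return all(
            t in column.index and column[t] > self.min_score for t in self.required_types
        )


@dataclass
class NicheAnnotation:
    """spatial cluster -> niche name, with the winning rule evidence."""

    assignment: dict
    record: dict = field(default_factory=dict)


def annotate_niches(em: EnrichmentMatrix, rules) -> NicheAnnotation:
    """Label each spatial cluster by the first matching rule (ordered rules;
    compound rules must precede the single-type rules they subsume).
    Unmatched clusters are labeled 'unassigned'."""
    rules = [r if isinstance(r, NicheRule) else NicheRule(**r) for r in rules]
    assignment, record = {}, {}
    for cluster in em.clusters:
        column = em.score[cluster]
        assignment[cluster] = "unassigned"
        for rule in rules:
            if rule.matches(column):
                assignment[cluster] = rule.name
                record[cluster] = {
                    "rule": rule.name,
                    "types": {t: float(column[t]) for t in rule.required_types},
                }
                break
    return NicheAnnotation(assignment=assignment, record=record)
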