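"""End-to-end orchestration: simulate -> qc -> markers -> mia -> spatial ->
coloc -> cohort, from a single config, with seeded reproducibility and a
run manifest (parameters, per-stage row counts, output checksums).

Every threshold of the underlying stages is surfaced in the config; there
are no hidden defaults outside ``DEFAULT_CONFIG``.  Stochastic stages
(simulation, permutation enrichment) refuse to run without an explicit
seed.  Rerunning with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as skio
from .coloc import colocalize
from .cohort import proportion_test, proportions, subtype_or
from .core import GeneSet
from .mia import annotate_niches, mia_matrix
from .qc import find_markers, lognormalize, qc_filter, signature_score
from .simulate import SimulationConfig, simulate_paired
from .spatial import distance_profile, knn_graph, nhood_enrichment, radial_distance

log = logging.getLogger("stnichekit")

__all__ = ["DEFAULT_CONFIG", "STAGES", "run_pipeline"]

STAGES = ("simulate", "qc", "markers", "mia", "spatial", "coloc", "cohort")

# Demonstration-scale defaults: small enough to run anywhere, structured like
# the full study conditions.  QC thresholds here are matched to the simulated
# sequencing depth; the library defaults of qc_filter itself keep the
# real-data values (1000 counts, 15% mito, 1000 cells/sample).
DEFAULT_CONFIG: dict = {
    "seed": None,  # mandatory
    "simulate": {
        "n_genes": 150,
        "n_cells_per_sample": 400,
        "n_samples_per_group": 2,
        "grid_side": 16,
    },
    "qc": {"min_counts": 500, "max_mito": 0.15, "min_cells_per_sample": 100},
    "markers": {"min_fraction": 0.1, "min_log2fc": 0.25},
    "mia": {"top_n": 100, "max_q": 0.05, "niche_rules": None},  # rules default to planted structure
    "spatial": {"k": 6, "n_perms": 1000, "radial_target": "interface", "n_bins": 25},
    "coloc": {"genes_a": "auto", "genes_b": "auto", "k": 6, "trim_q": 0.99, "top_frac": 0.10},
    "cohort": {"within": None},
    "stages": {s: True for s in STAGES},
}

_STAGE_DEPS = {
    "qc": ("simulate",),
    "markers": ("qc",),
    "mia": ("markers",),
    "spatial": ("simulate",),
    "coloc": ("simulate",),
    "cohort": ("simulate",),
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if isinstance(val, dict):
            out[key] = _merge(val, override.get(key, {}) or {})
        else:
            out[key] = override.get(key, val)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    return sum(1 for _ in open(path)) - 1  # minus header


def run_pipeline(config: dict, outdir) -> Path:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the run directory.  A stage failure halts the run with the
    failing stage named; outputs of completed stages are retained.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if cfg["seed"] is None:
        raise ValueError("pipeline config requires an explicit seed")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    enabled = {s for s, on in cfg["stages"].items() if on}
    if "simulate" not in enabled:
        raise ValueError("the simulate stage is required in this orchestration")
    for stage in STAGES:
        if stage in enabled and any(d not in enabled for d in _STAGE_DEPS.get(stage, ())):
            log.warning("stage %s skipped: dependency disabled", stage)
            enabled.discard(stage)

    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    completed: list[str] = []
    state: dict = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = path

    def run_stage(name, fn):
        if name not in enabled:
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage named
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        completed.append(name)
        log.info("pipeline: stage %s done", name)

    # ---- stages ----------------------------------------------------------
    def stage_simulate():
        sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
        cells, spatial, design, truth = simulate_paired(sim_cfg)
        state.update(cells=cells, spatial=spatial, design=design, truth=truth, sim_cfg=sim_cfg)
        for k, v in skio.write_count_matrix(cells, outdir, "cells").items():
            record(f"cells_{k}", Path(v))
        for k, v in skio.write_count_matrix(spatial.matrix, outdir, "spots").items():
            record(f"spots_{k}", Path(v))
        skio.write_design(design, outdir / "design.tsv")
        record("design", outdir / "design.tsv")
        (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), sort_keys=True, indent=1))
        record("truth", outdir / "truth.json")
        counts["simulate_cells"] = cells.n_obs
        counts["simulate_spots"] = spatial.n_spots

    def stage_qc():
        state["cells_qc"] = qc_filter(state["cells"], **cfg["qc"])
        state["norm_cells"] = lognormalize(state["cells_qc"])
        counts["qc_cells_kept"] = state["cells_qc"].n_obs

    def stage_markers():
        norm = state["norm_cells"]
        labels = state["cells_qc"].obs_meta["cluster_label"]
        ct = find_markers(norm, labels, **cfg["markers"])
        norm_spots = lognormalize(state["spatial"].matrix)
        rg = find_markers(norm_spots, state["spatial"].region_label, **cfg["markers"])
        state.update(ct_markers=ct, region_markers=rg, norm_spots=norm_spots)
        skio.write_table(ct, outdir / "cell_markers.tsv")
        skio.write_table(rg, outdir / "region_markers.tsv")
        record("cell_markers", outdir / "cell_markers.tsv")
        record("region_markers", outdir / "region_markers.tsv")
        counts["markers_celltype_rows"] = len(ct)
        counts["markers_region_rows"] = len(rg)

    def stage_mia():
        universe = list(state["cells"].gene_ids)
        em = mia_matrix(
            state["ct_markers"], state["region_markers"], universe,
            top_n=cfg["mia"]["top_n"], max_q=cfg["mia"]["max_q"],
        )
        rules = cfg["mia"]["niche_rules"]
        if rules is None:
            truth, sim_cfg = state["truth"], state["sim_cfg"]
            pair = list(truth.interface_pair)
            rules = [
                {"name": "stromal-immune interface niche", "required_types": tuple(pair)},
                {"name": "tumor core niche", "required_types": (sim_cfg.cell_types[0],)},
                {"name": "stromal niche", "required_types": (sim_cfg.cell_types[1],)},
            ]
        ann = annotate_niches(em, rules)
        state.update(mia=em, niches=ann)
        skio.write_table(em.score, outdir / "mia_scores.tsv")
        skio.write_table(em.p_enrich, outdir / "mia_p_enrich.tsv")
        skio.write_table(em.p_deplete, outdir / "mia_p_deplete.tsv")
        niche_df = pd.Series(ann.assignment, name="niche").rename_axis("cluster").to_frame()
        skio.write_table(niche_df, outdir / "niches.tsv")
        for name in ("mia_scores", "mia_p_enrich", "mia_p_deplete", "niches"):
            record(name, outdir / f"{name}.tsv")
        counts["mia_cells_types"] = em.score.shape[0]
        counts["mia_clusters"] = em.score.shape[1]

    def stage_spatial():
        sp_cfg = cfg["spatial"]
        spatial = state["spatial"]
        graph = knn_graph(spatial.coords, k=sp_cfg["k"])
        state["graph"] = graph
        z = nhood_enrichment(
            spatial.region_label, graph, n_perms=sp_cfg["n_perms"], seed=cfg["seed"] + 1
        )
        skio.write_table(z, outdir / "proximity_z.tsv")
        record("proximity_z", outdir / "proximity_z.tsv")
        field = radial_distance(spatial, sp_cfg["radial_target"])
        dist_df = pd.DataFrame({"distance": field.values, "raw_distance": field.raw})
        skio.write_table(dist_df, outdir / "radial_distance.tsv")
        record("radial_distance", outdir / "radial_distance.tsv")
        truth = state["truth"]
        genes = [truth.marker_genes[t][0] for t in truth.interface_pair]
        norm_spots = state.get("norm_spots") or lognormalize(spatial.matrix)
        expr = norm_spots.to_frame()[genes]
        prof = distance_profile(expr, field, n_bins=sp_cfg["n_bins"])
        skio.write_table(prof, outdir / "distance_profile.tsv")
        record("distance_profile", outdir / "distance_profile.tsv")
        counts["spatial_pairs"] = z.size

    def stage_coloc():
        co_cfg = cfg["coloc"]
        truth = state["truth"]
        a, b = truth.interface_pair
        genes_a = co_cfg["genes_a"]
        genes_b = co_cfg["genes_b"]
        if genes_a == "auto":
            genes_a = truth.marker_genes[a][:1]       # single flagship marker
        if genes_b == "auto":
            genes_b = truth.marker_genes[b][:2]       # multi-gene partner signal
        graph = state.get("graph") or knn_graph(state["spatial"].coords, k=co_cfg["k"])
        res = colocalize(
            state["spatial"], genes_a, genes_b, graph,
            trim_q=co_cfg["trim_q"], top_frac=co_cfg["top_frac"],
        )
        out = pd.DataFrame(
            {
                "coloc_score": res.scores,
                "high_a": res.mask_a,
                "high_b": res.mask_b,
                "overlap": res.overlap["mask"],
            }
        )
        skio.write_table(out, outdir / "coloc_scores.tsv")
        record("coloc_scores", outdir / "coloc_scores.tsv")
        summary = {k: res.overlap[k] for k in ("count", "jaccard", "expected", "p_enrich")}
        (outdir / "coloc_summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
        record("coloc_summary", outdir / "coloc_summary.json")
        counts["coloc_high_overlap"] = res.overlap["count"]

    def stage_cohort():
        truth, design = state["truth"], state["design"]
        pt = proportions(truth.cell_types, design, within=cfg["cohort"]["within"])
        skio.write_table(pt, outdir / "proportions.tsv")
        record("proportions", outdir / "proportions.tsv")
        tests = pd.DataFrame(
            [(ct, proportion_test(pt, ct)) for ct in sorted(pt["cell_type"].unique())],
            columns=["cell_type", "p_value"],
        )
        skio.write_table(tests, outdir / "proportion_tests.tsv")
        record("proportion_tests", outdir / "proportion_tests.tsv")
        or_table = subtype_or(truth.cell_types, design)
        skio.write_table(or_table, outdir / "subtype_or.tsv")
        record("subtype_or", outdir / "subtype_or.tsv")
        counts["cohort_types"] = len(or_table)

    for name, fn in (
        ("simulate", stage_simulate),
        ("qc", stage_qc),
        ("markers", stage_markers),
        ("mia", stage_mia),
        ("spatial", stage_spatial),
        ("coloc", stage_coloc),
        ("cohort", stage_cohort),
    ):
        run_stage(name, fn)

    manifest = {
        "config": cfg,
        "stages": completed,
        "counts": counts,
        "outputs": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1, default=str))
    return outdir
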