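# stnichekit

Spatial niche annotation and ligand–receptor colocalization analysis for
spot-based spatial transcriptomics paired with scRNA-seq.

Spot-based platforms capture small mixtures of cells per spot, so spatial
clusters cannot be assigned cell identities directly.  This package
implements the analysis chain used to characterize tumor-microenvironment
niches and stromal–immune interactions in that setting — for example, the
co-enrichment of lipid-processing fibroblasts (ABCA8⁺ lpCAF) and
lipid-associated macrophages (APOE⁺ LAM) at the stromal–immune interface of
immunotherapy-resistant triple-negative breast cancer:

1. **QC & normalization** — cells with < 1,000 counts or > 15% mitochondrial
   content excluded, samples with < 1,000 surviving cells dropped; values
   log-normalized as ln(1 + 10⁴·cᵢⱼ/Σⱼcᵢⱼ).
2. **Marker detection** — one-vs-rest two-sided Wilcoxon rank-sum per gene
   (exact by enumeration for tiny groups), gated at fraction-expressing ≥ 0.1
   and log₂FC ≥ 0.25, Benjamini–Hochberg correction.
3. **MIA niche annotation** — for cell type *T* with top marker set *A* and
   spatial cluster *R* with top marker set *B* in a shared universe of *N*
   genes, the overlap k = |A∩B| is scored with the hypergeometric tails
   P(X ≥ k) (enrichment) and P(X ≤ k) (depletion); the signed score is
   −log₁₀ of the smaller tail (negative for depletion).  Ordered rules over
   this matrix name the niches (e.g. "immune and interstitial region" when
   fibroblast and immune types are co-enriched).
4. **Spatial statistics** — K-nearest-neighbor spot graph (K = 6, self
   excluded); permutation z-scores for region–region adjacency; signed
   radial distance to a target niche (negative inside, positive outside,
   displayed as sign(d)·√|d|) with binned distance–expression profiles.
5. **Colocalization** — per-spot depth-normalized signals a, b and
   sᵢ = max(aᵢ·max_{j∈N(i)} bⱼ, bᵢ·max_{j∈N(i)} aⱼ), winsorized at the 0.99
   quantile; top-decile "high" masks and their overlap vs the independence
   expectation n·f_a·f_b.
6. **Cohort statistics** — per-sample subtype proportions compared between
   response groups by exact/asymptotic rank-sum tests; pooled-cell 2×2 odds
   ratios with Haldane–Anscombe correction, Woolf 95% CI and Fisher exact p.

A fully seeded synthetic generator produces paired single-cell + spatial
datasets with planted ground truth (marker genes, a core/interface/stroma
lattice, an adjacent interface cell-type pair, and a planted subtype odds
ratio between responder arms), so the entire chain is testable without any
external download.

## Worked example

```python
import stnichekit as sk

cfg = sk.SimulationConfig(n_genes=120, n_cells_per_sample=300,
                          n_samples_per_group=2, grid_side=16, seed=7)
cells, spatial, design, truth = sk.simulate_paired(cfg)

kept = sk.qc_filter(cells, min_counts=400, max_mito=0.15, min_cells_per_sample=50)
ct = sk.find_markers(sk.lognormalize(kept), kept.obs_meta["cluster_label"])
rg = sk.find_markers(sk.lognormalize(spatial.matrix), spatial.region_label)
em = sk.mia_matrix(ct, rg, list(cells.gene_ids), max_q=0.05)
print(em.score.round(1))
```

prints the signed MIA matrix (rows: cell types, columns: spatial clusters):

```
            core  interface  stroma
epithelial  13.0       -0.9    -0.4
fibroblast  -0.5       -1.0    13.0
lam         -0.5        6.5    -0.5
lpcaf       -0.4        8.3    -0.4
tcell       -0.5        0.2    -0.4
```

Epithelial cells are enriched in the core (score 13.0 ≈ p = 10⁻¹³),
fibroblasts in the stroma, and the planted partner pair (lpcaf, lam) is
co-enriched in the interface ring, so the ordered niche rules label it:

```python
rules = [
    {"name": "stromal-immune interface", "required_types": ("lpcaf", "lam")},
    {"name": "tumor core", "required_types": ("epithelial",)},
    {"name": "stroma", "required_types": ("fibroblast",)},
]
sk.annotate_niches(em, rules).assignment
# {'core': 'tumor core', 'interface': 'stromal-immune interface', 'stroma': 'stroma'}
```

Colocalization of the pair's flagship markers concentrates at the interface
(mean winsorized score 12283 on interface spots vs 1466 elsewhere for this
seed), and the cohort stage recovers the planted enrichment of `lam` in the
non-responder arm (odds ratio NE vs E = 2.69, Fisher p = 2.5 × 10⁻¹⁴ at this
small 2-samples-per-arm scale; the planted value is 3).

The same chain runs from the command line:

```sh
stnichekit run --config pipeline.yaml --seed 7 --out runs/demo
```

writing every intermediate table plus `manifest.json` (parameters, per-stage
counts, SHA-256 checksums; reruns with the same seed are bit-identical).
Individual stages are exposed as `stnichekit simulate | qc | markers | mia |
proximity | radial | coloc | cohort`.

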