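"""Readers and writers for the pipeline's on-disk formats.

Conventions: count matrices are MatrixMarket coordinate files (1-based, per
the standard) or dense TSV of plain numbers; every metadata/coordinate/result
table is TSV with a header row; gene sets are one gene per line or
``name<TAB>gene`` two-column files; configuration is YAML or JSON.  Floats
are written at 6 significant digits and round-trip losslessly at that
precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .core import CountMatrix, GeneSet, GroupDesign

log = logging.getLogger("stnichekit")

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "write_table",
    "read_gene_sets",
    "read_design",
    "load_config",
]


def _read_ids(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_count_matrix(path_matrix, path_obs_meta, path_gene_ids) -> CountMatrix:
    """Load a validated CountMatrix from MTX or dense TSV plus ID files.

    ``path_obs_meta`` is a TSV with header whose first column is the obs id;
    ``path_gene_ids`` is one gene id per line.  Row/column orientation of the
    matrix is auto-detected from the lengths of the two ID files.
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        mat = scipy.io.mmread(path_matrix)
        mat = sp.csr_matrix(mat)
    else:
        arr = pd.read_csv(path_matrix, sep="\t", header=None).to_numpy()
        mat = np.asarray(arr)
    obs_meta = pd.read_csv(path_obs_meta, sep="\t", index_col=0)
    obs_meta.index = obs_meta.index.astype(str)
    gene_ids = _read_ids(path_gene_ids)
    n_obs, n_genes = len(obs_meta), len(gene_ids)

    if mat.shape == (n_obs, n_genes):
        pass
    elif mat.shape == (n_genes, n_obs):
        mat = mat.T
        if sp.issparse(mat):
            mat = sp.csr_matrix(mat)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"(obs={n_obs}, genes={n_genes}) nor its transpose"
        )
    cm = CountMatrix(
        counts=mat,
        obs_ids=pd.Index(obs_meta.index),
        gene_ids=pd.Index(gene_ids),
        obs_meta=obs_meta,
    )
    log.info("read_count_matrix: %d obs x %d genes from %s", cm.n_obs, cm.n_genes, path_matrix)
    return cm


def write_count_matrix(cm: CountMatrix, outdir, prefix: str = "counts") -> dict:
    """Write a CountMatrix as <prefix>.mtx + <prefix>_obs.tsv + <prefix>_genes.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.mtx",
        "obs": outdir / f"{prefix}_obs.tsv",
        "genes": outdir / f"{prefix}_genes.txt",
    }
    mat = sp.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(paths["matrix"]), mat, field="integer")
    obs = cm.obs_meta.copy()
    obs.index.name = "obs_id"
    obs.to_csv(paths["obs"], sep="\t", float_format="%.6g")
    paths["genes"].write_text("\n".join(cm.gene_ids) + "\n")
    return {k: str(v) for k, v in paths.items()}


def write_table(obj, path) -> None:
    """Write a result table (DataFrame/Series/score vector) as TSV.

    Floats at 6 significant digits.  DataFrames with a plain RangeIndex are
    written without the index; anything with a meaningful index keeps it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(obj, "score"):  # EnrichmentMatrix-like
        obj = obj.score
    if isinstance(obj, pd.Series):
        obj = obj.to_frame(name=obj.name or "value")
    if isinstance(obj, np.ndarray):
        obj = pd.DataFrame({"value": obj})
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    write_index = not isinstance(obj.index, pd.RangeIndex)
    if write_index and obj.index.name is None:
        obj = obj.rename_axis("id")
    obj.to_csv(path, sep="\t", float_format="%.6g", index=write_index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from TSV: either one gene per line (a single set named
    after the file stem) or two columns ``name<TAB>gene``."""
    path = Path(path)
    rows = [line.rstrip("\n").split("\t") for line in path.read_text().splitlines() if line.strip()]
    if all(len(r) == 1 for r in rows):
        return [GeneSet(path.stem, [r[0] for r in rows])]
    sets: dict[str, list[str]] = {}
    for r in rows:
        if len(r) != 2:
            raise ValueError(f"gene set line with {len(r)} fields in {path}")
        sets.setdefault(r[0], []).append(r[1])
    return [GeneSet(name, genes) for name, genes in sets.items()]


def read_design(path) -> GroupDesign:
    """Read a design TSV with columns obs_id, sample_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"obs_id", "sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    sample_to_group = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    obs_to_sample = df.set_index("obs_id")["sample_id"]
    return GroupDesign(sample_to_group=sample_to_group, obs_to_sample=obs_to_sample)


def write_design(design: GroupDesign, path) -> None:
    df = pd.DataFrame(
        {
            "obs_id": design.obs_to_sample.index,
            "sample_id": design.obs_to_sample.values,
        }
    )
    df["group"] = df["sample_id"].map(design.sample_to_group)
    df.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
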