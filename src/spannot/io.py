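"""Readers and writers for the standard on-disk formats.

Counts come in as 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv, genes x spots) or as a dense delimited matrix
with genes as rows; coordinates as a TSV with columns spot_id, x, y;
marker lists as JSON mapping pattern name to gene symbols.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_mtx_dir",
    "read_dense_counts",
    "read_coords",
    "read_markers_json",
    "write_markers_json",
    "write_mtx_dir",
    "write_labels_csv",
    "write_posterior_csv",
    "write_qc_report",
    "to_anndata",
]


def read_mtx_dir(path):
    """10x convention: matrix.mtx, features.tsv, barcodes.tsv (genes x spots)."""
    path = Path(path)
    counts = spio.mmread(path / "matrix.mtx")
    if sparse.issparse(counts):
        counts = counts.toarray()
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    gene_names = feats.iloc[:, -1].astype(str).to_numpy(dtype=object) \
        if feats.shape[1] > 1 else feats.iloc[:, 0].astype(str).to_numpy(dtype=object)
    return np.asarray(counts), gene_names, barcodes.iloc[:, 0].astype(str).to_numpy(dtype=object)


def read_dense_counts(path, sep=None):
    """Dense delimited matrix, genes as rows, first column gene names."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    return df.to_numpy(dtype=float), df.index.astype(str).to_numpy(dtype=object), \
        df.columns.astype(str).to_numpy(dtype=object)


def read_coords(path, sep="\t"):
    """Coordinates TSV with columns spot_id, x, y."""
    df = pd.read_csv(path, sep=sep)
    need = {"spot_id", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"coordinate file needs columns {sorted(need)}, got {list(df.columns)}")
    return df["spot_id"].astype(str).to_numpy(dtype=object), \
        df[["x", "y"]].to_numpy(dtype=float)


def read_markers_json(path) -> Dict[str, list]:
    with open(path) as fh:
        markers = json.load(fh)
    if not isinstance(markers, dict):
        raise ValueError("marker JSON must map pattern name -> list of genes")
    empties = [p for p, g in markers.items() if not g]
    if len(empties) > 1:
        raise ValueError(f"at most one marker-free pattern allowed, got {empties}")
    return {str(p): [str(g) for g in genes] for p, genes in markers.items()}


def write_markers_json(markers: Dict[str, list], path):
    with open(path, "w") as fh:
        json.dump(markers, fh, indent=1)


def write_mtx_dir(counts, gene_names, spot_ids, path):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(np.asarray(counts)))
    pd.DataFrame({"gene": gene_names}).to_csv(path / "features.tsv", sep="\t",
                                              header=False, index=False)
    pd.DataFrame({"barcode": spot_ids}).to_csv(path / "barcodes.tsv", sep="\t",
                                               header=False, index=False)


def write_coords(spot_ids, coords, path, sep="\t"):
    pd.DataFrame({"spot_id": spot_ids, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, sep=sep, index=False)


def write_labels_csv(spot_ids, labels, path, method: str = ""):
    pd.DataFrame({"spot_id": spot_ids, "label": labels, "method": method}).to_csv(
        path, index=False)


def write_posterior_csv(spot_ids, posterior, pattern_names, path):
    df = pd.DataFrame(np.asarray(posterior), columns=list(pattern_names))
    df.insert(0, "spot_id", spot_ids)
    df.to_csv(path, index=False)


def write_qc_report(qc_log: dict, path):
    with open(path, "w") as fh:
        json.dump(qc_log, fh, indent=1)


def write_image_stack_tiff(stack, path):
    """Pattern/feature image stack as a multi-page TIFF (one page per channel)."""
    import tifffile

    arr = np.asarray(stack, dtype=np.float32)
    tifffile.imwrite(path, np.moveaxis(arr, -1, 0))


def to_anndata(state):
    """SpotTable as an AnnData (spots as obs, genes as var)."""
    import anndata as ad

    adata = ad.AnnData(
        X=state.counts.T.astype(float),
        obs=pd.DataFrame(index=pd.Index(state.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(state.gene_names, name="gene")),
    )
    adata.obsm["spatial"] = state.coords.copy()
    if state.denoised is not None:
        adata.layers["denoised"] = state.denoised.T.copy()
    if state.size_factors is not None:
        adata.obs["size_factor"] = state.size_factors
    return adata
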