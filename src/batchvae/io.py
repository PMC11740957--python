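"""Readers and writers for count/normalized matrices and reports.

Supported matrix formats:

* delimited text (TSV/CSV): genes as rows, a header row of sample ids —
  the conventional bulk RNA-seq layout; transposed on read into the
  samples x genes AnnData orientation.
* ``.h5ad``: the annotated-matrix HDF5 container, read/written via anndata.

Sample metadata is a TSV with columns ``sample_id``, ``source`` and
optionally ``indication``.
"""

from __future__ import annotations

import pathlib

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "read_metadata",
    "write_matrix",
    "write_tmm_factors",
    "attach_metadata",
]


def _sep_for(path: pathlib.Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path, metadata=None) -> ad.AnnData:
    """Read a count matrix (TSV/CSV genes x samples, or .h5ad) into AnnData
    (samples x genes); optionally attach a metadata TSV."""
    path = pathlib.Path(path)
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
        if df.index.has_duplicates:
            raise ValueError("duplicated gene identifiers in matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicated sample identifiers in matrix")
        adata = ad.AnnData(
            X=df.to_numpy().T,
            obs=pd.DataFrame(index=df.columns.astype(str)),
            var=pd.DataFrame(index=df.index.astype(str)),
        )
    if metadata is not None:
        adata = attach_metadata(adata, read_metadata(metadata))
    return adata


def read_metadata(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if "sample_id" not in meta.columns or "source" not in meta.columns:
        raise ValueError("metadata needs 'sample_id' and 'source' columns")
    return meta.set_index("sample_id")


def attach_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} samples lack metadata rows (first: {missing[0]!r})"
        )
    adata = adata.copy()
    aligned = meta.reindex(adata.obs_names)
    adata.obs["source"] = aligned["source"].astype(str)
    if "indication" in aligned.columns:
        adata.obs["indication"] = aligned["indication"]
    return adata


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_matrix(adata: ad.AnnData, path, provenance: dict | None = None) -> None:
    """Write samples x genes AnnData to .h5ad or genes x samples delimited
    text; text files carry a ``#``-commented provenance header."""
    path = pathlib.Path(path)
    if path.suffix == ".h5ad":
        out = adata.copy()
        if provenance:
            out.uns["provenance"] = {k: str(v) for k, v in provenance.items()}
        out.write_h5ad(path)
        return
    df = pd.DataFrame(
        np.asarray(adata.X).T, index=adata.var_names, columns=adata.obs_names
    )
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep=_sep_for(path))


def write_tmm_factors(sample_ids, factors, path, provenance: dict | None = None) -> None:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        pd.DataFrame({"sample_id": sample_ids, "tmm_factor": factors}).to_csv(
            fh, sep="\t", index=False
        )
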