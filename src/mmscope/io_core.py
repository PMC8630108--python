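"""Reading/writing of 10x-style count matrices, quality control, and log-normalization.

The in-memory container for a cells-by-genes count matrix is an
:class:`anndata.AnnData` with raw integer counts in ``.X`` (CSR sparse),
per-cell annotations in ``.obs`` (``patient_id``, ``timepoint``,
``fraction``, optional ``cell_type`` / ``doublet_score``) and per-gene
annotations in ``.var`` (optional ``mito`` / ``blacklist`` flags).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "EmptyResultError",
    "BLACKLIST_GENES",
    "IG_PREFIXES",
    "MITO_PREFIXES",
    "read_counts",
    "write_counts",
    "read_cell_metadata",
    "qc_filter",
    "normalize_log",
    "read_gene_order",
    "write_gene_order",
    "read_arm_boundaries",
    "write_arm_boundaries",
    "assign_arms",
    "sort_genome",
]


class FormatError(ValueError):
    """An on-disk file violates the expected format."""


class EmptyResultError(RuntimeError):
    """A filtering step removed every cell."""


#: Genes highly upregulated across all cell types in myeloma samples and
#: therefore uninformative for differential comparisons.
BLACKLIST_GENES = (
    "SLC25A6", "CD99", "IL3RA", "CSF2RA", "MTRNR2L8", "MTRNR2L12",
    "ARL6IP4", "POLR2F", "GTPBP6", "EEF1A1", "H3F3A", "TMSB4X",
)

#: Immunoglobulin gene-symbol prefixes. Ig transcripts are extremely abundant
#: in plasma/myeloma cells and cause ambient-RNA batch effects.
IG_PREFIXES = ("IGH", "IGK", "IGL")

#: Mitochondrially encoded gene-symbol prefixes.
MITO_PREFIXES = ("MT-",)


def _read_tsv_column(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    *,
    cells_in_rows: bool = False,
) -> ad.AnnData:
    """Read an MTX triplet matrix with barcode/feature TSVs into AnnData.

    Parameters
    ----------
    matrix_path, barcodes_path, features_path
        Matrix Market coordinate file and the two one-entry-per-line TSVs.
    cells_in_rows
        Declared on-disk orientation. The 10x convention stores genes in
        rows (``False``, default); the returned matrix is always
        cells x genes.

    Raises
    ------
    FormatError
        If header dimensions disagree with the TSV lengths, values are
        non-integer, or identifiers are duplicated.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError(f"{matrix_path}: matrix contains non-integer values")
        mat = mat.astype(np.int64)
    if mat.data.size and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: matrix contains negative counts")

    barcodes = _read_tsv_column(barcodes_path)
    with open(features_path) as fh:
        feature_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    features = [row[0] for row in feature_rows]

    n_cells, n_genes = (mat.shape[0], mat.shape[1]) if cells_in_rows else (mat.shape[1], mat.shape[0])
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix header declares {n_cells} cells"
        )
    if len(features) != n_genes:
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix header declares {n_genes} genes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate cell barcodes")
    if len(set(features)) != len(features):
        raise FormatError(f"{features_path}: duplicate gene identifiers")

    x = sp.csr_matrix(mat if cells_in_rows else mat.T)
    var = pd.DataFrame(index=pd.Index(features, name="gene_id"))
    if feature_rows and len(feature_rows[0]) > 1:
        var["feature_name"] = [row[1] for row in feature_rows]
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=var,
    )
    return adata


def write_counts(adata: ad.AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write counts as ``matrix.mtx`` (genes x cells, 10x convention) plus
    ``barcodes.tsv`` / ``features.tsv``. Triplets are written in canonical
    column-major order so identical matrices yield identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = sp.csc_matrix(adata.X).T.tocsc()  # genes x cells, canonical order
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), x.tocoo(), field="integer")
    paths["barcodes"].write_text("".join(f"{b}\n" for b in adata.obs_names))
    paths["features"].write_text("".join(f"{g}\n" for g in adata.var_names))
    return paths


def read_cell_metadata(adata: ad.AnnData, path: str | Path) -> ad.AnnData:
    """Attach a cell-metadata TSV (with header, first column = cell id) to ``.obs``."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise FormatError(f"{path}: metadata missing for {len(missing)} cells (e.g. {missing[0]})")
    adata = adata.copy()
    adata.obs = adata.obs.join(meta.loc[adata.obs_names])
    return adata


def _mito_mask(adata: ad.AnnData, mito_prefixes: tuple[str, ...]) -> np.ndarray:
    if "mito" in adata.var:
        return adata.var["mito"].to_numpy(dtype=bool)
    return np.asarray(adata.var_names.str.startswith(mito_prefixes))


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 400,
    max_mito_frac: float = 0.10,
    doublet_threshold: float = 0.4,
    *,
    drop_blacklist: bool = True,
    drop_immunoglobulin: bool = True,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
    ig_prefixes: tuple[str, ...] = IG_PREFIXES,
    blacklist: tuple[str, ...] = BLACKLIST_GENES,
) -> ad.AnnData:
    """Apply per-cell quality filters and optional gene-axis removal.

    Cells are *removed* when they have fewer than ``min_genes`` detected
    genes, more than ``max_mito_frac`` mitochondrial counts, or a doublet
    score above ``doublet_threshold``; boundary cells (exactly at a
    threshold) are retained. Doublet scores are consumed, never computed;
    cells without a score pass that filter.

    QC metrics (``n_genes_detected``, ``mito_frac``) are computed on the raw
    matrix the first time and stored in ``.obs``; a second application reuses
    them, which makes the filter idempotent even after immunoglobulin/
    blacklist genes have been removed from the gene axis. Raw counts of
    removed genes are kept in ``.obsm["removed_gene_counts"]``.
    """
    adata = adata.copy()
    x = sp.csr_matrix(adata.X)

    if "n_genes_detected" not in adata.obs:
        adata.obs["n_genes_detected"] = np.asarray((x > 0).sum(axis=1)).ravel()
    if "mito_frac" not in adata.obs:
        mito = _mito_mask(adata, mito_prefixes)
        total = np.asarray(x.sum(axis=1)).ravel().astype(float)
        mito_counts = np.asarray(x[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            adata.obs["mito_frac"] = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    pass_genes = adata.obs["n_genes_detected"].to_numpy() >= min_genes
    pass_mito = adata.obs["mito_frac"].to_numpy() <= max_mito_frac
    if "doublet_score" in adata.obs:
        score = adata.obs["doublet_score"].to_numpy(dtype=float)
        pass_doublet = np.isnan(score) | (score <= doublet_threshold)
    else:
        pass_doublet = np.ones(adata.n_obs, dtype=bool)

    keep = pass_genes & pass_mito & pass_doublet
    if not keep.any():
        raise EmptyResultError(
            "QC removed all cells "
            f"(failing min_genes: {int((~pass_genes).sum())}, "
            f"mito: {int((~pass_mito).sum())}, doublet: {int((~pass_doublet).sum())})"
        )
    adata = adata[keep].copy()

    drop = np.zeros(adata.n_vars, dtype=bool)
    if drop_blacklist:
        if "blacklist" in adata.var:
            drop |= adata.var["blacklist"].to_numpy(dtype=bool)
        drop |= adata.var_names.isin(blacklist)
    if drop_immunoglobulin:
        drop |= np.asarray(adata.var_names.str.startswith(ig_prefixes))
    if drop.any():
        removed = pd.DataFrame(
            sp.csr_matrix(adata.X)[:, drop].toarray(),
            index=adata.obs_names,
            columns=adata.var_names[drop],
        )
        adata = adata[:, ~drop].copy()
        adata.obsm["removed_gene_counts"] = removed
    adata.uns["qc"] = {
        "min_genes": min_genes,
        "max_mito_frac": max_mito_frac,
        "doublet_threshold": doublet_threshold,
        "n_cells_kept": int(adata.n_obs),
        "n_genes_removed": int(drop.sum()),
    }
    return adata


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Total-count normalize to ``scale_factor`` and natural-log transform.

    ``value(c, g) = ln(count(c, g) / total(c) * scale_factor + 1)``.
    Raw counts are preserved in ``.layers["counts"]``.
    """
    totals = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()
    if (totals <= 0).any():
        n_zero = int((totals <= 0).sum())
        raise ValueError(
            f"{n_zero} cells have zero total counts; run qc_filter before normalization"
        )
    adata = adata.copy()
    adata.layers["counts"] = sp.csr_matrix(adata.X).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=scale_factor)
        sc.pp.log1p(adata)
    adata.uns["normalization"] = {"scale_factor": scale_factor, "log_base": "e"}
    return adata


# ---------------------------------------------------------------------------
# Gene order / chromosome arms
# ---------------------------------------------------------------------------

_CHROM_RANK = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_key(chrom: pd.Series) -> pd.Series:
    stripped = chrom.astype(str).str.removeprefix("chr")
    return stripped.map(lambda c: _CHROM_RANK.get(c, 100)).astype(int)


def read_gene_order(path: str | Path) -> pd.DataFrame:
    """Read a 4-column, headerless gene-order TSV (gene, chrom, start, end)."""
    order = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "chrom", "start", "end"],
        dtype={"gene": str, "chrom": str},
    )
    if order["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in gene order file")
    if (order["start"] > order["end"]).any():
        raise FormatError(f"{path}: gene order rows with start > end")
    return order


def write_gene_order(order: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    order[["gene", "chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_arm_boundaries(path: str | Path) -> pd.DataFrame:
    """Read a 3-column arm-boundary TSV (chrom, arm, boundary).

    ``boundary`` is the last genomic position belonging to the arm; arms of a
    chromosome are stacked in increasing boundary order.
    """
    arms = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "arm", "boundary"],
        dtype={"chrom": str, "arm": str},
    )
    return arms


def write_arm_boundaries(arms: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    arms[["chrom", "arm", "boundary"]].to_csv(path, sep="\t", header=False, index=False)
    return path


def assign_arms(order: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    """Annotate each gene with its chromosome-arm label (e.g. ``"1q"``).

    A gene belongs to the first arm of its chromosome whose boundary is at or
    beyond the gene start; genes beyond the last boundary take the last arm.
    """
    order = order.copy()
    labels = np.empty(len(order), dtype=object)
    arm_by_chrom = {c: g.sort_values("boundary") for c, g in arms.groupby("chrom")}
    for i, (chrom, start) in enumerate(zip(order["chrom"], order["start"])):
        chrom_arms = arm_by_chrom.get(str(chrom))
        if chrom_arms is None:
            labels[i] = None
            continue
        hit = chrom_arms.loc[chrom_arms["boundary"] >= start, "arm"]
        labels[i] = hit.iloc[0] if len(hit) else chrom_arms["arm"].iloc[-1]
    order["arm"] = labels
    return order


def sort_genome(order: pd.DataFrame) -> pd.DataFrame:
    """Sort genes by chromosome (natural order), start, then gene id."""
    key = _chrom_key(order["chrom"])
    return (
        order.assign(_k=key)
        .sort_values(["_k", "start", "gene"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
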