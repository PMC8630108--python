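"""Expression-inferred copy-number profiles, subclone calling, and clone dynamics.

The CNA signal of a cell is obtained from log-normalized expression by
(1) dropping lowly expressed genes, (2) subtracting the per-gene mean of a
normal reference population, (3) clipping residuals at a few reference
standard deviations, (4) smoothing along the genome with a moving average
that never crosses a chromosome boundary, and (5) recentering each cell at
its median signal. Tumor subclones are groups of cells with a shared CNA
profile, found by hierarchical clustering of the smoothed signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

__all__ = [
    "CNAProfileMatrix",
    "SubcloneSet",
    "infer_cna_profiles",
    "call_subclones",
    "call_region_state",
    "fraction_aberrant_cells",
    "classify_1q_group",
    "match_closest_clone",
    "clone_fractions",
    "clone_stability_score",
]

GROUP_LABELS = ("ND_rare", "subclonal", "dominant")


@dataclass
class CNAProfileMatrix:
    """Smoothed per-cell CNA signal, genome-ordered, neutral ~ 0."""

    signal: pd.DataFrame  # cells x retained genes
    gene_order: pd.DataFrame  # retained genes: gene, chrom, start, arm
    window: int
    reference_ids: list[str]

    @property
    def tumor_ids(self) -> pd.Index:
        return self.signal.index.difference(self.reference_ids, sort=False)

    def arms(self, min_genes: int = 1) -> list[str]:
        counts = self.gene_order["arm"].value_counts()
        return [a for a in self.gene_order["arm"].unique() if counts[a] >= min_genes]

    def arm_gene_mask(self, arm: str) -> np.ndarray:
        if arm not in set(self.gene_order["arm"]):
            raise KeyError(f"arm {arm!r} has no retained genes in the gene order")
        return (self.gene_order["arm"] == arm).to_numpy()

    def arm_means(self, cells: pd.Index | list[str], arm: str) -> np.ndarray:
        mask = self.arm_gene_mask(arm)
        return self.signal.loc[cells].to_numpy()[:, mask].mean(axis=1)

    def reference_arm_sd(self, arm: str) -> float:
        """SD across reference cells of their mean signal over the arm."""
        vals = self.arm_means(pd.Index(self.reference_ids), arm)
        return float(vals.std(ddof=1))


def infer_cna_profiles(
    norm: ad.AnnData,
    order: pd.DataFrame,
    reference_cells: list[str] | pd.Index,
    mean_cutoff: float = 0.1,
    window: int = 101,
    clip_sd: float = 3.0,
) -> CNAProfileMatrix:
    """Infer smoothed CNA profiles for every cell in ``norm``.

    Parameters
    ----------
    norm
        Log-normalized expression (cells x genes).
    order
        Gene-order table with columns gene, chrom, start and arm
        (see :func:`mmscope.io_core.assign_arms`).
    reference_cells
        Cells assumed copy-number neutral (e.g. normal plasma cells); at
        least 30 are required for a stable baseline.
    mean_cutoff
        Genes with mean normalized expression below this value (across all
        cells) are dropped before smoothing.
    window
        Odd moving-average span in genes; the symmetric window shrinks at
        chromosome boundaries and never crosses them.
    clip_sd
        Residuals are clipped at this many reference standard deviations
        per gene so single outlier genes cannot mimic a CNA.
    """
    reference_cells = [c for c in reference_cells]
    if len(reference_cells) < 30:
        raise ValueError(
            f"need at least 30 reference cells for a CNA baseline, got {len(reference_cells)}"
        )
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")

    from .io_core import sort_genome

    order = sort_genome(order[order["gene"].isin(norm.var_names)])
    x = norm[:, order["gene"].to_numpy()].X
    x = np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float)

    keep = x.mean(axis=0) >= mean_cutoff
    if keep.sum() < 2 * window:
        raise ValueError(
            f"only {int(keep.sum())} genes pass the mean-expression cutoff "
            f"{mean_cutoff}; need at least {2 * window} (2 x window)"
        )
    order = order.loc[keep].reset_index(drop=True)
    x = x[:, keep]

    ref_rows = norm.obs_names.get_indexer(reference_cells)
    mu = x[ref_rows].mean(axis=0)
    sd = np.maximum(x[ref_rows].std(axis=0, ddof=1), 1e-8)
    resid = np.clip(x - mu, -clip_sd * sd, clip_sd * sd)

    smoothed = np.empty_like(resid)
    half = window // 2
    start = 0
    for _, block in order.groupby("chrom", sort=False):
        n = len(block)
        sl = slice(start, start + n)
        csum = np.concatenate(
            [np.zeros((resid.shape[0], 1)), np.cumsum(resid[:, sl], axis=1)], axis=1
        )
        idx = np.arange(n)
        h = np.minimum(np.minimum(idx, n - 1 - idx), half)
        lo, hi = idx - h, idx + h
        smoothed[:, sl] = (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)
        start += n

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    signal = pd.DataFrame(smoothed, index=norm.obs_names, columns=order["gene"])
    return CNAProfileMatrix(
        signal=signal, gene_order=order, window=window, reference_ids=reference_cells
    )


@dataclass
class SubcloneSet:
    """Per-cell subclone labels with per-subclone profiles and arm states."""

    labels: pd.Series  # non-reference cells -> subclone id
    profiles: pd.DataFrame  # subclone x retained genes (mean CNA signal)
    sizes: pd.Series
    arm_states: pd.DataFrame  # subclone x arm in {gain, neutral, loss}
    cna: CNAProfileMatrix
    linkage: np.ndarray | None = None
    single_clone_fallback: bool = False
    params: dict = field(default_factory=dict)

    @property
    def subclone_ids(self) -> list[str]:
        return list(self.profiles.index)


def _states_for_profiles(
    profiles: pd.DataFrame,
    cna: CNAProfileMatrix,
    arms: list[str],
    sd_mult: float,
) -> pd.DataFrame:
    states = {}
    for arm in arms:
        mask = cna.arm_gene_mask(arm)
        thresh = sd_mult * cna.reference_arm_sd(arm)
        means = profiles.to_numpy()[:, mask].mean(axis=1)
        states[arm] = np.where(
            means > thresh, "gain", np.where(means < -thresh, "loss", "neutral")
        )
    return pd.DataFrame(states, index=profiles.index)


def call_subclones(
    cna: CNAProfileMatrix,
    linkage: str = "ward",
    min_cells: int = 40,
    *,
    merge_identical_states: bool = True,
    state_sd_mult: float = 3.0,
    min_arm_genes: int = 10,
) -> SubcloneSet:
    """Partition non-reference cells into CNA subclones.

    Cells are clustered hierarchically (Euclidean distance on smoothed
    profiles) and the dendrogram is cut at the largest number of clusters
    for which every cluster keeps at least ``min_cells`` members; smaller
    planted clones are thereby absorbed into their nearest relative. Since
    a fine cut can split one genomic clone into clusters that differ only
    by expression noise, clusters whose per-arm copy-number states are
    identical are merged back together (``merge_identical_states``) — a
    subclone is defined by its CNA genotype, not by expression substructure.

    Ties are broken deterministically; final labels ``SC1, SC2, ...`` are
    ordered by decreasing size, then by first cell.
    """
    cells = cna.tumor_ids
    x = cna.signal.loc[cells].to_numpy()
    n = len(cells)
    arms = cna.arms(min_genes=min_arm_genes)

    if n < min_cells:
        warnings.warn(
            f"only {n} non-reference cells (< {min_cells}); returning a single subclone"
        )
        labels = pd.Series(["SC1"] * n, index=cells, name="subclone")
        profiles = pd.DataFrame(
            x.mean(axis=0, keepdims=True), index=["SC1"], columns=cna.signal.columns
        )
        return SubcloneSet(
            labels=labels,
            profiles=profiles,
            sizes=pd.Series({"SC1": n}),
            arm_states=_states_for_profiles(profiles, cna, arms, state_sd_mult),
            cna=cna,
            single_clone_fallback=True,
            params={"min_cells": min_cells, "linkage": linkage},
        )

    z = sch.linkage(x, method=linkage)
    best = np.ones(n, dtype=int)
    for k in range(n // min_cells, 1, -1):
        cand = sch.fcluster(z, t=k, criterion="maxclust")
        sizes = np.bincount(cand)[1:]
        if len(sizes[sizes > 0]) == k and sizes[sizes > 0].min() >= min_cells:
            best = cand
            break

    groups = pd.Series(best, index=cells)
    if merge_identical_states and groups.nunique() > 1:
        centroids = pd.DataFrame(
            {g: x[(groups == g).to_numpy()].mean(axis=0) for g in sorted(groups.unique())}
        ).T
        centroids.columns = cna.signal.columns
        states = _states_for_profiles(centroids, cna, arms, state_sd_mult)
        genotype = states.apply(tuple, axis=1)
        remap = {g: genotype.index[genotype == genotype[g]][0] for g in genotype.index}
        groups = groups.map(remap)

    # deterministic final labels: by decreasing size, tie by first cell index
    first_pos = {g: i for i, g in reversed(list(enumerate(groups)))}
    ordered = sorted(
        groups.unique(), key=lambda g: (-int((groups == g).sum()), first_pos[g])
    )
    rename = {g: f"SC{i + 1}" for i, g in enumerate(ordered)}
    labels = groups.map(rename).rename("subclone")

    profiles = pd.DataFrame(
        {sc: x[(labels == sc).to_numpy()].mean(axis=0) for sc in rename.values()}
    ).T
    profiles.columns = cna.signal.columns
    sizes = labels.value_counts().reindex(profiles.index)
    return SubcloneSet(
        labels=labels,
        profiles=profiles,
        sizes=sizes,
        arm_states=_states_for_profiles(profiles, cna, arms, state_sd_mult),
        cna=cna,
        linkage=z,
        params={
            "min_cells": min_cells,
            "linkage": linkage,
            "merge_identical_states": merge_identical_states,
            "state_sd_mult": state_sd_mult,
        },
    )


def call_region_state(
    sub: SubcloneSet,
    arm: str,
    gain_thresh: float | None = None,
    loss_thresh: float | None = None,
    min_arm_genes: int = 10,
) -> pd.Series:
    """Gain/neutral/loss call per subclone for one chromosome arm.

    Default thresholds are +/- 3 standard deviations of the reference
    cells' mean signal over the arm.
    """
    mask = sub.cna.arm_gene_mask(arm)
    if mask.sum() < min_arm_genes:
        raise ValueError(
            f"arm {arm!r} has only {int(mask.sum())} retained genes (< {min_arm_genes})"
        )
    ref_sd = sub.cna.reference_arm_sd(arm)
    if gain_thresh is None:
        gain_thresh = 3.0 * ref_sd
    if loss_thresh is None:
        loss_thresh = -3.0 * ref_sd
    means = sub.profiles.to_numpy()[:, mask].mean(axis=1)
    return pd.Series(
        np.where(means > gain_thresh, "gain", np.where(means < loss_thresh, "loss", "neutral")),
        index=sub.profiles.index,
        name=arm,
    )


def fraction_aberrant_cells(sub: SubcloneSet, arm: str = "1q") -> float:
    """Fraction of tumor cells sitting in subclones called ``gain`` on ``arm``."""
    states = (
        sub.arm_states[arm] if arm in sub.arm_states.columns else call_region_state(sub, arm)
    )
    gained = states.index[states == "gain"]
    return float(sub.labels.isin(gained).sum() / len(sub.labels))


def classify_1q_group(fraction: float) -> str:
    """Classify a 1q-gain cell fraction into the three abundance bands:
    not-detected/rare [0, 0.1), subclonal [0.1, 0.8], dominant (0.8, 1]."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < 0.10:
        return "ND_rare"
    if fraction > 0.80:
        return "dominant"
    return "subclonal"


def match_closest_clone(
    sub: SubcloneSet, target: str, exclude_arm: str = "1q"
) -> str:
    """Genetically closest subclone to ``target`` without a gain on
    ``exclude_arm``: minimal Euclidean distance between mean CNA profiles
    computed over genes outside the excluded arm; ties break to the lower
    subclone label."""
    if target not in sub.profiles.index:
        raise KeyError(f"unknown subclone {target!r}")
    states = (
        sub.arm_states[exclude_arm]
        if exclude_arm in sub.arm_states.columns
        else call_region_state(sub, exclude_arm)
    )
    candidates = [s for s in sub.profiles.index if s != target and states[s] != "gain"]
    if not candidates:
        raise ValueError(f"no {exclude_arm}-neutral comparator clone for {target!r}")
    outside = ~sub.cna.arm_gene_mask(exclude_arm)
    t = sub.profiles.loc[target].to_numpy()[outside]
    dists = {
        c: float(np.linalg.norm(sub.profiles.loc[c].to_numpy()[outside] - t))
        for c in candidates
    }
    return min(sorted(candidates), key=lambda c: dists[c])


def clone_fractions(labels: pd.Series, sample_ids: pd.Series) -> pd.DataFrame:
    """Subclone fraction table: one row per sample, one column per subclone;
    rows sum to 1."""
    df = pd.crosstab(sample_ids.loc[labels.index], labels)
    return df.div(df.sum(axis=1), axis=0)


def clone_stability_score(
    pre: Mapping[str, float], post: Mapping[str, float]
) -> float:
    """Mean over clones of min/max of the pre/post fraction pair.

    For each clone in the union of the two maps with ``max(f_pre, f_post)
    > 0``, the ratio ``min/max`` is computed (a clone absent at one
    timepoint contributes 0); the score is the mean ratio. 1 means a
    perfectly stable clonal composition, 0 a complete turnover.
    """
    union = set(pre) | set(post)
    ratios = []
    for clone in union:
        a, b = float(pre.get(clone, 0.0)), float(post.get(clone, 0.0))
        hi = max(a, b)
        if hi > 0:
            ratios.append(min(a, b) / hi)
    if not ratios:
        raise ValueError("both fraction maps are all-zero")
    return float(np.mean(ratios))
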