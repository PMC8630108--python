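"""Ligand-receptor interaction testing, cohort summaries, and networks.

A pair is scored between a sender and a receiver cell type as the mean of
the ligand-complex expression in the sender and the receptor-complex
expression in the receiver (complex expression per cell = minimum over
subunits). Significance comes from a cell-type label permutation null,
run per patient; cohort summaries average significant-interaction counts
and sum interaction strengths across patients, and the interaction
network connects every cell type to its top-k partners by summed strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_lr_pairs",
    "load_default_pairs",
    "InteractionResult",
    "test_interactions",
    "count_interactions",
    "interaction_strength",
    "build_network",
    "network_to_json",
]


def load_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Read a ligand-receptor pair CSV (pair_id, ligand_genes, receptor_genes,
    direction); multi-subunit complexes join genes with ``+``."""
    df = pd.read_csv(path)
    required = {"pair_id", "ligand_genes", "receptor_genes"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pair table must have columns {sorted(required)}")
    df = df.copy()
    df["ligand_genes"] = df["ligand_genes"].str.split("+")
    df["receptor_genes"] = df["receptor_genes"].str.split("+")
    return df


def load_default_pairs() -> pd.DataFrame:
    """The packaged ~40-pair table covering the myeloma-relevant axes
    (MIF-CD74, IL18-IL18R1/IL18RAP, CD48-CD244, FAM3C-KIR2DL3, CD47, ...)."""
    with resources.as_file(resources.files("mmscope.data") / "lr_pairs.csv") as p:
        return load_lr_pairs(p)


@dataclass
class InteractionResult:
    """Per (pair, sender, receiver) statistics for one patient sample."""

    table: pd.DataFrame
    eligible_types: list[str]
    n_perm: int
    alpha: float
    seed: int | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def test_interactions(
    norm: ad.AnnData,
    labels: pd.Series | str,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_cells: int = 20,
    min_frac: float = 0.1,
    seed: int = 0,
) -> InteractionResult:
    """Permutation test of ligand-receptor co-expression between cell types.

    Only cell types with more than ``min_cells`` cells enter the test; a
    pair is tested for sender A and receiver B when the ligand complex is
    expressed in more than ``min_frac`` of A and the receptor complex in
    more than ``min_frac`` of B. The p-value uses the add-one estimator
    ``(1 + #{permuted statistic >= observed}) / (n_perm + 1)`` so it is
    never exactly zero.
    """
    if isinstance(labels, str):
        labels = norm.obs[labels]
    labels = labels.reindex(norm.obs_names)

    counts = labels.value_counts()
    eligible = sorted(counts.index[counts > min_cells])
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 cell types with more than {min_cells} cells, "
            f"got {len(eligible)}"
        )
    cell_mask = labels.isin(eligible).to_numpy()
    sub = norm[cell_mask]
    lab = labels[cell_mask]

    gene_pos = {g: i for i, g in enumerate(sub.var_names)}
    x = sub.X
    x = np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float)

    kept_pairs = []
    complex_cols: list[np.ndarray] = []
    for _, row in pairs.iterrows():
        genes = list(row["ligand_genes"]) + list(row["receptor_genes"])
        missing = [g for g in genes if g not in gene_pos]
        if missing:
            logger.info("skipping pair %s: missing genes %s", row["pair_id"], missing)
            continue
        lig = x[:, [gene_pos[g] for g in row["ligand_genes"]]].min(axis=1)
        rec = x[:, [gene_pos[g] for g in row["receptor_genes"]]].min(axis=1)
        kept_pairs.append(row["pair_id"])
        complex_cols.append(lig)
        complex_cols.append(rec)
    n_pairs = len(kept_pairs)
    if n_pairs == 0:
        raise ValueError("no ligand-receptor pair could be resolved against the matrix")
    c = np.column_stack(complex_cols)  # cells x (2 * n_pairs)

    type_codes = pd.Categorical(lab, categories=eligible).codes
    n_types = len(eligible)
    type_counts = np.bincount(type_codes, minlength=n_types)

    def group_means(mat: np.ndarray, codes: np.ndarray) -> np.ndarray:
        order = np.argsort(codes, kind="stable")
        starts = np.concatenate([[0], np.cumsum(type_counts)[:-1]])
        sums = np.add.reduceat(mat[order], starts, axis=0)
        return sums / type_counts[:, None]

    mean_by_type = group_means(c, type_codes)  # n_types x 2P
    frac_by_type = group_means((c > 0).astype(float), type_codes)
    lig_mean, rec_mean = mean_by_type[:, 0::2], mean_by_type[:, 1::2]
    lig_frac, rec_frac = frac_by_type[:, 0::2], frac_by_type[:, 1::2]

    # observed statistic and testability for every ordered (sender, receiver)
    obs = 0.5 * (lig_mean[:, None, :] + rec_mean[None, :, :])  # A x B x P
    tested = (lig_frac[:, None, :] > min_frac) & (rec_frac[None, :, :] > min_frac)

    rng = np.random.default_rng(seed)
    ge = np.zeros_like(obs, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(type_counts)[:-1]])
    for _ in range(n_perm):
        order = rng.permutation(c.shape[0])
        sums = np.add.reduceat(c[order], starts, axis=0)
        means = sums / type_counts[:, None]
        lm, rm = means[:, 0::2], means[:, 1::2]
        stat = 0.5 * (lm[:, None, :] + rm[None, :, :])
        ge += stat >= obs

    p = (1.0 + ge) / (n_perm + 1.0)
    rows = []
    for a_i, a in enumerate(eligible):
        for b_i, b in enumerate(eligible):
            for p_i, pair_id in enumerate(kept_pairs):
                is_tested = bool(tested[a_i, b_i, p_i])
                pval = float(p[a_i, b_i, p_i]) if is_tested else np.nan
                rows.append(
                    {
                        "pair_id": pair_id,
                        "sender": a,
                        "receiver": b,
                        "statistic": float(obs[a_i, b_i, p_i]),
                        "p_value": pval,
                        "tested": is_tested,
                        "significant": is_tested and pval < alpha,
                        "frac_ligand_sender": float(lig_frac[a_i, p_i]),
                        "frac_receptor_receiver": float(rec_frac[b_i, p_i]),
                    }
                )
    table = pd.DataFrame(rows)
    return InteractionResult(
        table=table, eligible_types=eligible, n_perm=n_perm, alpha=alpha, seed=seed
    )


def count_interactions(
    results: Mapping[str, InteractionResult]
) -> pd.DataFrame:
    """Mean number of significant interactions per ordered cell-type pair,
    averaged over the patients in which both types were eligible."""
    all_types = sorted({t for r in results.values() for t in r.eligible_types})
    total = pd.DataFrame(0.0, index=all_types, columns=all_types)
    n_elig = pd.DataFrame(0, index=all_types, columns=all_types)
    for r in results.values():
        elig = r.eligible_types
        n_elig.loc[elig, elig] += 1
        sig = r.significant.groupby(["sender", "receiver"], observed=True).size()
        for (a, b), cnt in sig.items():
            total.loc[a, b] += cnt
    with np.errstate(invalid="ignore"):
        return total / n_elig.replace(0, np.nan)


def interaction_strength(
    results: Mapping[str, InteractionResult]
) -> pd.DataFrame:
    """Summed observed statistics of significant interactions per ordered
    cell-type pair, summed across patients."""
    all_types = sorted({t for r in results.values() for t in r.eligible_types})
    total = pd.DataFrame(0.0, index=all_types, columns=all_types)
    for r in results.values():
        sig = r.significant.groupby(["sender", "receiver"], observed=True)["statistic"].sum()
        for (a, b), s in sig.items():
            total.loc[a, b] += s
    return total


def build_network(strengths: pd.DataFrame, k: int = 4) -> nx.Graph:
    """Undirected top-k interaction network.

    Each cell type selects its ``k`` strongest partners by symmetrized
    strength (``strength(A,B) + strength(B,A)``; ties break
    lexicographically); the graph is the union of all selections. Node
    attributes: ``degree`` on the union graph and ``strength`` (sum of
    incident edge weights).
    """
    if k < 1:
        raise ValueError(f"k must be at least 1, got {k}")
    if len(strengths.index) < 2:
        raise ValueError("need at least 2 cell types to build a network")
    types = sorted(strengths.index)
    s = strengths.reindex(index=types, columns=types).fillna(0.0)
    sym = s + s.T
    g = nx.Graph()
    g.add_nodes_from(types)
    for a in types:
        partners = sorted(
            (b for b in types if b != a), key=lambda b: (-sym.loc[a, b], b)
        )[:k]
        for b in partners:
            g.add_edge(a, b, weight=float(sym.loc[a, b]))
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
        g.nodes[node]["strength"] = float(
            sum(d["weight"] for _, _, d in g.edges(node, data=True))
        )
    return g


def network_to_json(g: nx.Graph) -> dict:
    return {
        "nodes": [
            {"id": n, "degree": g.nodes[n]["degree"], "strength": g.nodes[n]["strength"]}
            for n in sorted(g.nodes)
        ],
        "edges": [
            {"source": a, "target": b, "weight": d["weight"]}
            for a, b, d in sorted(g.edges(data=True))
        ],
    }
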