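"""Differential expression, recurrence-filtered gene signatures, and
bin-matched module scoring.

The 1q-gain signature workflow: within each patient, differential
expression between a 1q-gained subclone and its genetically closest
1q-neutral relative (a matched-clone comparison that controls for the
shared genetic background); genes upregulated in enough patients and
located on the restricted arm form the signature; single cells are then
scored against expression-matched control genes, exactly as generic
module scores (exhaustion, effector, interferon response) are computed
from user-supplied gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_expression",
    "SignatureGeneSet",
    "derive_signature",
    "ModuleScoreVector",
    "score_signature",
    "evaluate_ppv",
    "score_fraction_correlation",
]

#: Below this combined group size the Wilcoxon rank-sum p-value is computed
#: by exact enumeration instead of the tie-corrected normal approximation.
EXACT_WILCOXON_MAX_N = 20


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if sp.issparse(x) else x, dtype=float)


def differential_expression(
    norm: ad.AnnData,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    alpha: float = 0.05,
    min_logfc: float = 0.1,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression (A vs B).

    Only genes expressed (value > 0) in at least ``min_pct`` of either
    group are tested; p-values are Bonferroni-adjusted over the tested
    genes. The log fold change follows the common single-cell convention
    on log-normalized values ``v``:
    ``ln[(mean(exp(v_a) - 1) + 1) / (mean(exp(v_b) - 1) + 1)]``
    (natural log of pseudocounted de-logged means). A gene is significant
    when adjusted p < ``alpha`` and ``|logFC| > min_logfc``.
    """
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError(
            f"both groups need at least 3 cells (got {len(cells_a)} and {len(cells_b)})"
        )
    xa = _dense(norm[list(cells_a)].X)
    xb = _dense(norm[list(cells_b)].X)

    pct_a = (xa > 0).mean(axis=0)
    pct_b = (xb > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not tested.any():
        return pd.DataFrame(
            columns=["logfc", "p_value", "p_adj", "direction", "pct_a", "pct_b", "significant"]
        )
    xa_t, xb_t = xa[:, tested], xb[:, tested]

    mean_a = np.expm1(xa_t).mean(axis=0)
    mean_b = np.expm1(xb_t).mean(axis=0)
    logfc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    method = "exact" if (xa.shape[0] + xb.shape[0]) <= EXACT_WILCOXON_MAX_N else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            xa_t, xb_t, axis=0, alternative="two-sided", method=method
        )
    pvals = np.atleast_1d(res.pvalue)
    # constant genes (all ties) have an undefined rank test; report p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_adj = multipletests(pvals, method="bonferroni")[1]

    out = pd.DataFrame(
        {
            "logfc": logfc,
            "p_value": pvals,
            "p_adj": p_adj,
            "direction": np.where(logfc >= 0, "up", "down"),
            "pct_a": pct_a[tested],
            "pct_b": pct_b[tested],
        },
        index=norm.var_names[tested],
    )
    out["significant"] = (out["p_adj"] < alpha) & (out["logfc"].abs() > min_logfc)
    return out


@dataclass
class SignatureGeneSet:
    """Recurrently upregulated, arm-restricted gene list."""

    genes: list[str]
    recurrence: pd.Series  # per-gene count of patients with upregulation
    arm: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def derive_signature(
    per_patient_results: Mapping[str, pd.DataFrame],
    min_recurrence: int,
    order: pd.DataFrame,
    arm: str = "1q",
    mito_prefixes: tuple[str, ...] = ("MT-",),
) -> SignatureGeneSet:
    """Recurrence-filtered signature from matched-clone DE tables.

    Keeps genes significantly upregulated in at least ``min_recurrence``
    patients, located on ``arm`` and not mitochondrially encoded. Output
    order: descending recurrence, then gene id; invariant to patient order.
    """
    counts: dict[str, int] = {}
    for table in per_patient_results.values():
        if table.empty:
            continue
        up = table.index[table["significant"] & (table["logfc"] > 0)]
        for g in up:
            counts[g] = counts.get(g, 0) + 1
    if len(per_patient_results) < min_recurrence:
        warnings.warn(
            f"only {len(per_patient_results)} contributing patients "
            f"(< min_recurrence = {min_recurrence}); returning an empty signature"
        )
        counts = {}

    on_arm = set(order.loc[order["arm"] == arm, "gene"])
    kept = {
        g: c
        for g, c in counts.items()
        if c >= min_recurrence and g in on_arm and not g.startswith(mito_prefixes)
    }
    genes = sorted(kept, key=lambda g: (-kept[g], g))
    return SignatureGeneSet(
        genes=genes,
        recurrence=pd.Series({g: kept[g] for g in genes}, dtype=int),
        arm=arm,
        provenance={
            "min_recurrence": min_recurrence,
            "n_patients": len(per_patient_results),
        },
    )


@dataclass
class ModuleScoreVector:
    """Per-cell module score with its control parameters."""

    scores: pd.Series
    n_bins: int
    n_ctrl: int
    seed: int
    genes_used: list[str] = field(default_factory=list)


def score_signature(
    norm: ad.AnnData,
    genes: SignatureGeneSet | Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreVector:
    """Module score with expression-bin-matched control genes.

    All genes are binned into ``n_bins`` by average expression across
    cells; for each signature gene, ``n_ctrl`` control genes are sampled
    with replacement from its bin (excluding signature genes). The score
    of a cell is the mean expression of the signature genes minus the mean
    over the pooled control draws, so a random gene set scores ~0.
    """
    gene_list = list(genes)
    present = [g for g in gene_list if g in norm.var_names]
    if not present:
        raise ValueError("none of the signature genes are present in the matrix")

    x = _dense(norm.X)
    var_names = list(norm.var_names)
    avg = x.mean(axis=0)
    n_bins_eff = min(n_bins, len(var_names))
    bins = pd.qcut(
        pd.Series(avg, index=var_names).rank(method="first"),
        n_bins_eff,
        labels=False,
    )
    sig_set = set(present)
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(var_names)}

    ctrl_cols: list[np.ndarray] = []
    for g in present:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(sig_set)]
        if len(pool) == 0:
            # degenerate bin: every member is a signature gene; fall back to
            # sampling within the bin itself (scores then collapse to ~0)
            pool = bins.index[bins == bins[g]]
        draw = rng.choice(len(pool), size=n_ctrl, replace=True)
        ctrl_cols.append(np.array([pos[pool[i]] for i in draw]))

    sig_mean = x[:, [pos[g] for g in present]].mean(axis=1)
    ctrl_idx = np.concatenate(ctrl_cols)
    ctrl_mean = x[:, ctrl_idx].mean(axis=1)
    scores = pd.Series(sig_mean - ctrl_mean, index=norm.obs_names, name="module_score")
    return ModuleScoreVector(
        scores=scores, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, genes_used=present
    )


def evaluate_ppv(
    scores: ModuleScoreVector | pd.Series,
    truth: pd.Series,
    threshold: float,
) -> dict:
    """Positive predictive value of ``score >= threshold`` against a per-cell
    boolean truth; with zero positives the PPV is reported as NaN."""
    s = scores.scores if isinstance(scores, ModuleScoreVector) else scores
    truth = truth.reindex(s.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some scored cells")
    positive = s >= threshold
    tp = int((positive & truth.astype(bool)).sum())
    fp = int((positive & ~truth.astype(bool)).sum())
    n_pos = int(positive.sum())
    ppv = tp / n_pos if n_pos else float("nan")
    return {"ppv": ppv, "tp": tp, "fp": fp, "n_positive": n_pos}


def score_fraction_correlation(
    sample_scores: pd.Series, sample_fractions: pd.Series
) -> float:
    """Pearson correlation of per-sample mean signature score against the
    per-sample aberrant-cell fraction."""
    joined = pd.concat(
        [sample_scores.rename("score"), sample_fractions.rename("fraction")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError(f"need at least 3 samples, got {len(joined)}")
    if joined["score"].std() == 0 or joined["fraction"].std() == 0:
        raise ValueError("zero variance in scores or fractions")
    return float(stats.pearsonr(joined["score"], joined["fraction"]).statistic)
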