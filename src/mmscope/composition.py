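"""Cell-type composition tables and group comparisons."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compute_fractions", "compare_fractions"]


def compute_fractions(
    cell_types: pd.Series,
    sample_ids: pd.Series,
    min_cells: int = 5,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Per-sample cell-type fractions with a low-abundance floor.

    Within each sample, cell types represented by fewer than ``min_cells``
    cells are dropped (their fraction is set to 0); by default the
    remaining fractions are renormalized to sum to 1. Samples left without
    any retained cells are dropped with a warning.
    """
    counts = pd.crosstab(sample_ids, cell_types)
    counts = counts.where(counts >= min_cells, 0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} samples with no cell type reaching "
            f"{min_cells} cells: {list(counts.index[empty])}"
        )
        counts = counts[~empty]
        totals = totals[~empty]
    if renormalize:
        return counts.div(totals, axis=0)
    return counts.div(sample_ids.value_counts().reindex(counts.index), axis=0)


def compare_fractions(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of cell-type fractions between
    two sample groups, Bonferroni-adjusted over the tested cell types.

    Cell types present (fraction > 0) in only one group are reported with
    NaN p-values and ``one_group_only = True``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError(
            f"need at least 3 samples per group (got {len(group_a)} and {len(group_b)})"
        )
    missing = set(group_a + group_b) - set(table.index)
    if missing:
        raise KeyError(f"samples absent from the fraction table: {sorted(missing)}")

    fa = table.loc[group_a]
    fb = table.loc[group_b]
    rows = []
    for ct in table.columns:
        a, b = fa[ct].to_numpy(), fb[ct].to_numpy()
        present_a, present_b = (a > 0).any(), (b > 0).any()
        if present_a != present_b:
            rows.append(
                {"cell_type": ct, "p_value": np.nan, "direction": "", "one_group_only": True}
            )
            continue
        if not present_a and not present_b:
            rows.append(
                {"cell_type": ct, "p_value": np.nan, "direction": "", "one_group_only": True}
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            )
        direction = "up" if a.mean() > b.mean() else ("down" if a.mean() < b.mean() else "equal")
        rows.append(
            {"cell_type": ct, "p_value": p, "direction": direction, "one_group_only": False}
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    tested = ~out["p_value"].isna()
    out["p_bonferroni"] = np.nan
    if tested.any():
        out.loc[tested, "p_bonferroni"] = multipletests(
            out.loc[tested, "p_value"], method="bonferroni"
        )[1]
    return out
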