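"""Fatty-acid composition profiles: mol% normalization and sexed comparisons.

Total fatty-acid data (e.g. FAME GC-MS) are analysed as molar percentage
of the per-sample total, separately for each lipid fraction (PL vs TG) and
tissue.  Group summaries carry a propagated error bar and a nonparametric
two-group p-value annotated with significance tiers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = ["normalize_mol_percent", "group_fa_summary"]


def normalize_mol_percent(amounts: pd.DataFrame) -> pd.DataFrame:
    """Convert per-sample fatty-acid amounts to mol% of the per-sample total.

    Rows are samples, columns FA species; missing amounts count as zero.
    Samples whose total is zero are dropped with a warning.  Each returned
    row sums to 100.
    """
    values = amounts.fillna(0.0).astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError("negative fatty-acid amounts")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"dropping samples with zero total: {list(values.index[zero])}")
        values = values.loc[~zero]
        totals = totals.loc[~zero]
    return values.div(totals, axis=0) * 100.0


def _propagated_error(block: pd.DataFrame, mode: str) -> pd.Series:
    """Error bar of the group-mean mol% for each species.

    ``"sem"``: standard error of the per-sample mol% (default).
    ``"quotient"``: quotient-rule propagation of the normalization - the
    relative errors of the species mean and of the per-sample total mean
    added in quadrature, scaled to the mean mol%.
    """
    n = len(block)
    if mode == "sem":
        return block.std(ddof=1) / np.sqrt(n)
    if mode == "quotient":
        totals = block.sum(axis=1)
        mean_pct = block.mean()
        rel_species = block.std(ddof=1) / block.mean() / np.sqrt(n)
        rel_total = totals.std(ddof=1) / totals.mean() / np.sqrt(n)
        return mean_pct * np.sqrt(rel_species**2 + rel_total**2)
    raise ValueError(f"unknown error mode {mode!r}")


def group_fa_summary(
    composition: pd.DataFrame,
    groups: pd.Series,
    error: str = "sem",
) -> pd.DataFrame:
    """Per-species two-group summary of a mol% composition table.

    ``groups`` maps sample id -> group label (exactly two labels, >= 3
    samples each).  Returns per species: group means, propagated error
    bars, rank-test p-value and its significance tier.  Species entirely
    absent from one group are reported with mean 0 and no test.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1, g2 = labels
    b1 = composition.loc[groups.index[groups == g1].intersection(composition.index)]
    b2 = composition.loc[groups.index[groups == g2].intersection(composition.index)]
    if len(b1) < 3 or len(b2) < 3:
        raise ValueError("need >= 3 samples per group")
    err1 = _propagated_error(b1, error)
    err2 = _propagated_error(b2, error)
    rows = []
    for sp in composition.columns:
        x1, x2 = b1[sp], b2[sp]
        row = {
            "species": sp,
            f"mean_{g1}": float(x1.mean()),
            f"mean_{g2}": float(x2.mean()),
            f"error_{g1}": float(err1[sp]),
            f"error_{g2}": float(err2[sp]),
            "n_" + g1: len(x1),
            "n_" + g2: len(x2),
        }
        if (x1 == 0).all() or (x2 == 0).all():
            row["pvalue"] = np.nan
            row["tier"] = ""
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = _stats.group_test(x1, x2)
            row["pvalue"] = p
            row["tier"] = _stats.significance_tier(p)
        rows.append(row)
    return pd.DataFrame(rows)
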