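"""Statistical kernel: Jaccard-Tanimoto similarity with significance,
error-normalized fold change, coefficient-of-variation summaries and the
nonparametric two-group abundance test.

Jaccard-Tanimoto null model
---------------------------
Two presence lists over a universe of N variables, with k1 and k2 present
entries, are compared by J = |A n B| / |A u B|.  Under the null each
list's present labels are reassigned uniformly at random across the
universe, preserving the totals k1 and k2; the intersection size m is then
hypergeometric, m ~ Hypergeom(N, k1, k2), and J = m / (k1 + k2 - m) is a
monotone increasing function of m.  The default p-value is the
dissimilarity tail P(J <= J_obs) = P(m <= m_obs): small when the two lists
overlap less than chance.

Because the test statistic is discrete, the exact p-value takes finitely
many values; for small universes the attainable significance levels can
sit well below nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "P_FLOOR",
    "BinaryListPair",
    "JtcResult",
    "EnfcRecord",
    "jaccard",
    "jtc_pvalue",
    "jtc_pvalue_sets",
    "enfc",
    "enfc_table",
    "cv_summary",
    "group_test",
    "significance_tier",
    "floor_pvalue",
    "format_pvalue",
    "bh_adjust",
]

#: Reporting floor for p-values: anything smaller prints as "<2.2e-16".
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class BinaryListPair:
    """Two aligned boolean presence vectors over an ordered variable universe."""

    universe: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=bool)
        b = np.asarray(self.b, dtype=bool)
        if a.shape != (len(self.universe),) or b.shape != (len(self.universe),):
            raise ValueError("presence vectors must align with the universe")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @classmethod
    def from_sets(
        cls, set_a: set, set_b: set, universe: list | tuple
    ) -> "BinaryListPair":
        uni = tuple(universe)
        a = np.array([u in set_a for u in uni])
        b = np.array([u in set_b for u in uni])
        return cls(uni, a, b)


@dataclass(frozen=True)
class JtcResult:
    """Jaccard-Tanimoto coefficient with its significance."""

    j: float
    pvalue: float
    method: str  # "exact" | "monte-carlo"
    n_null: int | None = None
    tail: str = "dissimilarity"


def _jaccard_counts(m: int, k1: int, k2: int) -> float:
    union = k1 + k2 - m
    if union == 0:
        return 1.0
    return m / union


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """J = |A n B| / |A u B|; defined as 1 when both vectors are all-false."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must be aligned")
    m = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("both lists empty; J defined as 1")
        return 1.0
    return m / union


def jtc_pvalue(
    pair: BinaryListPair,
    method: str = "exact",
    n_null: int = 9999,
    seed: int | None = None,
    two_sided: bool = False,
) -> JtcResult:
    """Jaccard-Tanimoto coefficient with p-value under the fixed-totals null.

    ``method="exact"`` sums hypergeometric mass over intersection sizes with
    J at least as extreme as observed; ``"monte-carlo"`` resamples the null
    with the given seed and reports (count_at_or_beyond + 1) / (n_null + 1).
    Default tail is dissimilarity-oriented: p is small when the lists share
    less than expected by chance.
    """
    a, b = pair.a, pair.b
    n = len(pair.universe)
    k1 = int(a.sum())
    k2 = int(b.sum())
    m_obs = int(np.count_nonzero(a & b))
    j_obs = _jaccard_counts(m_obs, k1, k2)
    if k1 + k2 == 0:
        warnings.warn("both lists empty; J = 1 and p = 1 by convention")
        return JtcResult(1.0, 1.0, "exact", tail="dissimilarity")

    if method == "exact":
        rv = sps.hypergeom(n, k1, k2)
        p_low = float(rv.cdf(m_obs))          # P(J <= J_obs)
        p_high = float(rv.sf(m_obs - 1))      # P(J >= J_obs)
        if two_sided:
            p = min(1.0, 2.0 * min(p_low, p_high))
            tail = "two-sided"
        else:
            p = p_low
            tail = "dissimilarity"
        p = min(max(p, np.finfo(float).tiny), 1.0)
        return JtcResult(j_obs, p, "exact", tail=tail)

    if method == "monte-carlo":
        if n_null < 100:
            raise ValueError("monte-carlo requires n_null >= 100")
        rng = np.random.default_rng(seed)
        # Reassigning each list's present labels uniformly at random and
        # intersecting is distributionally identical to drawing the
        # intersection size directly from Hypergeom(N, k1, k2).
        m_null = rng.hypergeometric(k1, n - k1, k2, size=n_null)
        j_null = m_null / (k1 + k2 - m_null)
        if two_sided:
            below = np.count_nonzero(j_null <= j_obs)
            above = np.count_nonzero(j_null >= j_obs)
            p = min(1.0, 2.0 * (min(below, above) + 1) / (n_null + 1))
            tail = "two-sided"
        else:
            p = (np.count_nonzero(j_null <= j_obs) + 1) / (n_null + 1)
            tail = "dissimilarity"
        return JtcResult(j_obs, float(p), "monte-carlo", n_null, tail)

    raise ValueError(f"unknown method {method!r}; use 'exact' or 'monte-carlo'")


def jtc_pvalue_sets(
    set_a: set,
    set_b: set,
    universe_size: int,
    method: str = "exact",
    n_null: int = 9999,
    seed: int | None = None,
) -> JtcResult:
    """Convenience wrapper taking sets plus the universe size directly."""
    k1, k2 = len(set_a), len(set_b)
    m = len(set_a & set_b)
    if max(k1, k2) > universe_size:
        raise ValueError("list totals exceed the universe size")
    # Build a minimal aligned pair with the same (n, k1, k2, m) counts.
    a = np.zeros(universe_size, dtype=bool)
    b = np.zeros(universe_size, dtype=bool)
    a[:k1] = True
    b[:m] = True
    b[k1: k1 + (k2 - m)] = True
    pair = BinaryListPair(tuple(map(str, range(universe_size))), a, b)
    return jtc_pvalue(pair, method=method, n_null=n_null, seed=seed)


@dataclass(frozen=True)
class EnfcRecord:
    """Error-normalized fold change of one variable in one compartment.

    FC = mu1 / mu0 and ENFC = ln(FC) / sqrt((s1/mu1)^2 + (s0/mu0)^2):
    the log fold change scaled by the propagated relative error of the two
    group means, so a unit of ENFC is "one combined relative-error width".
    """

    variable: str
    compartment: str
    mu1: float
    mu0: float
    sigma1: float
    sigma0: float
    n1: int
    n0: int
    fold_change: float = float("nan")
    enfc: float = float("nan")
    incalculable: bool = False


def enfc(
    variable: str,
    compartment: str,
    mu1: float,
    sigma1: float,
    n1: int,
    mu0: float,
    sigma0: float,
    n0: int,
) -> EnfcRecord:
    """Compute one error-normalized fold change record.

    Flagged incalculable when either group mean is non-positive (fold
    change undefined) or both spreads are zero (no error to normalise by).
    """
    if mu1 <= 0 or mu0 <= 0 or not np.isfinite(mu1) or not np.isfinite(mu0):
        return EnfcRecord(variable, compartment, mu1, mu0, sigma1, sigma0, n1, n0,
                          incalculable=True)
    if sigma1 == 0 and sigma0 == 0:
        return EnfcRecord(variable, compartment, mu1, mu0, sigma1, sigma0, n1, n0,
                          fold_change=mu1 / mu0, incalculable=True)
    fc = mu1 / mu0
    rel = np.sqrt((sigma1 / mu1) ** 2 + (sigma0 / mu0) ** 2)
    return EnfcRecord(
        variable, compartment, mu1, mu0, sigma1, sigma0, n1, n0,
        fold_change=fc, enfc=float(np.log(fc) / rel),
    )


def enfc_table(table, design, phenotype_1: str, phenotype_0: str) -> pd.DataFrame:
    """Per-variable, per-compartment ENFC between two phenotypes.

    Group means/SDs use detected (strictly positive) values only.  Returns
    a tidy frame with one row per (variable, compartment), incalculable
    rows flagged, plus the count of detected samples entering each mean.
    """
    values = table.quantitative()
    rows = []
    for comp in design.compartments:
        s1 = design.samples_in(phenotype_1, comp)
        s0 = design.samples_in(phenotype_0, comp)
        if not s1 or not s0:
            continue
        v1 = values.loc[[s for s in s1 if s in values.index]]
        v0 = values.loc[[s for s in s0 if s in values.index]]
        for var in values.columns:
            x1 = v1[var].dropna()
            x0 = v0[var].dropna()
            if len(x1) == 0 or len(x0) == 0:
                rows.append(
                    EnfcRecord(var, comp, np.nan, np.nan, np.nan, np.nan,
                               len(x1), len(x0), incalculable=True)
                )
                continue
            rows.append(
                enfc(
                    var, comp,
                    float(x1.mean()), float(x1.std(ddof=1)) if len(x1) > 1 else 0.0,
                    len(x1),
                    float(x0.mean()), float(x0.std(ddof=1)) if len(x0) > 1 else 0.0,
                    len(x0),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def cv_summary(table, design, phenotype: str) -> dict:
    """Per-variable coefficient of variation within one phenotype.

    CV = sample SD / mean x 100, over detected values (>= 2 required per
    variable; all-constant variables get CV 0).  Returns the per-variable
    series and the mean CV across variables.
    """
    values = table.quantitative()
    samples = design.frame.index[design.frame["phenotype"] == phenotype]
    sub = values.loc[[s for s in samples if s in values.index]]
    n_det = sub.notna().sum(axis=0)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    cv = (sd / mean * 100.0).mask(sd == 0, 0.0).where(n_det >= 2)
    return {
        "phenotype": phenotype,
        "per_variable_cv": cv,
        "mean_cv": float(cv.dropna().mean()) if cv.notna().any() else float("nan"),
    }


def mean_phenotype_difference(table, design, phenotype_1: str, phenotype_0: str) -> float:
    """Mean absolute between-phenotype difference of per-variable means, in
    percent of the midpoint of the two group means."""
    values = table.quantitative()
    f = design.frame
    m1 = values.loc[[s for s in f.index[f["phenotype"] == phenotype_1] if s in values.index]].mean()
    m0 = values.loc[[s for s in f.index[f["phenotype"] == phenotype_0] if s in values.index]].mean()
    mid = (m1 + m0) / 2
    pct = ((m1 - m0).abs() / mid * 100.0).replace([np.inf, -np.inf], np.nan)
    return float(pct.dropna().mean())


def group_test(values1, values2) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value for two abundance groups.

    Lipidomic abundances are unequally distributed and heteroscedastic, so
    a rank-based test is used throughout: exact when the combined sample is
    small and untied, normal approximation with tie correction otherwise.
    All-tied inputs return p = 1 with a warning.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("group_test needs >= 3 values per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1")
        return 1.0
    small = len(x) + len(y) < 20
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


#: Significance tiers, strongest first: p < 0.0001 -> "****", < 0.001 ->
#: "***", < 0.01 -> "**", < 0.05 -> "+", < 0.1 -> "*".
_TIERS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "+"), (1e-1, "*")]


def significance_tier(p: float) -> str:
    for cut, mark in _TIERS:
        if p < cut:
            return mark
    return ""


def floor_pvalue(p: float) -> float:
    """Floor tiny p-values at the reporting limit."""
    return max(float(p), P_FLOOR)


def format_pvalue(p: float) -> str:
    if p < P_FLOOR:
        return "<2.2e-16"
    return f"{p:.3g}"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw values)."""
    p = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
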