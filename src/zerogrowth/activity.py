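"""Activity-correlation screening and the zero-growth population call.

Each gene's FPKM profile is rank-correlated (Spearman) against the
focal genome's total mRNA across all treatments and replicates; BH-FDR
controls the screen. Category summaries contrast activity markers
(ribosomal proteins, energy metabolism, sulfate reduction) with growth
machinery (cell division, DNA replication, envelope biogenesis): a
population whose total transcription surges while growth-gene
correlations stay low, and whose qPCR abundance stays flat, is called
transcriptionally active at (near-) zero growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

ACTIVITY_CATEGORIES: tuple[str, ...] = ("sulfate_reduction", "ribosomal", "central_energy")
GROWTH_CATEGORIES: tuple[str, ...] = (
    "growth_division",
    "growth_replication",
    "growth_envelope",
)


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations (n < 10)."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    xc = rx - rx.mean()
    yc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    rhos = (yc @ xc) / denom
    hits = np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12)
    return hits / factorial(n)


def spearman_rho(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    p-value: exact permutation enumeration for n < ``exact_below``,
    t-approximation otherwise. Raises on length mismatch, n < 3, or a
    constant vector (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rho = _pearson(rx, ry)
    if n < exact_below:
        p = _exact_perm_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return rho, p


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved.

    p_adj(i) = min over j >= rank(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def activity_correlations(
    fpkm: pd.DataFrame,
    totals: pd.Series,
    catalog: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Spearman rho of FPKM vs total mRNA, BH-adjusted.

    All treatments and replicates are pooled. Constant-expression genes
    get rho = NaN and are excluded from the BH family. Returns a
    DataFrame (gene_id, category, rho, p_raw, p_adj, n_pairs,
    significant).
    """
    if fpkm.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    t = totals.reindex(fpkm.columns).to_numpy(float)
    if np.isnan(t).any():
        raise KeyError("totals missing for some samples")
    x = fpkm.to_numpy(float)
    n = x.shape[1]
    nonconst = np.ptp(x, axis=1) > 0
    if np.ptp(t) == 0:
        raise ValueError("total mRNA is constant across samples")

    rho = np.full(len(x), np.nan)
    p_raw = np.full(len(x), np.nan)
    if nonconst.any():
        xr = np.apply_along_axis(_rank, 1, x[nonconst])
        tr = _rank(t)
        xc = xr - xr.mean(axis=1, keepdims=True)
        tc = tr - tr.mean()
        r = (xc @ tc) / np.sqrt((xc * xc).sum(axis=1) * (tc @ tc))
        rho[nonconst] = r
        if n < 10:
            p_raw[nonconst] = [
                _exact_perm_p(xr[i], _rank(t), r[i]) for i in range(len(r))
            ]
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
            p = 2.0 * stats.t.sf(np.abs(tt), df=n - 2)
            p[np.abs(r) >= 1.0] = 0.0
            p_raw[nonconst] = p

    p_adj = np.full(len(x), np.nan)
    p_adj[nonconst] = benjamini_hochberg(p_raw[nonconst]) if nonconst.any() else []
    categories = (
        catalog.set_index("gene_id")["category"].reindex(fpkm.index).to_numpy(object)
    )
    out = pd.DataFrame(
        {
            "gene_id": fpkm.index,
            "category": categories,
            "rho": rho,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "n_pairs": n,
        }
    )
    out["significant"] = out["p_adj"] < alpha
    return out


def category_summary(
    records: pd.DataFrame,
    categories=None,
    alpha: float = 0.05,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD of rho per functional category.

    By default only genes with p_adj < alpha enter the mean (the
    convention behind reporting e.g. "0.79 +/- 0.07 (n = 72, FDR-adjusted
    P < 0.05)"); ``significant_only=False`` includes all genes with a
    defined rho. SD is the sample SD (ddof=1), 0 for n = 1.
    """
    present = set(records["category"].dropna())
    if categories is None:
        categories = sorted(present)
    else:
        unknown = set(categories) - present
        if unknown:
            raise KeyError(f"unknown category labels: {sorted(unknown)}")
    rows = []
    for cat in categories:
        sub = records[(records["category"] == cat) & records["rho"].notna()]
        n_total = len(sub)
        sig = sub[sub["p_adj"] < alpha]
        pool = sig if significant_only else sub
        rho = pool["rho"].to_numpy(float)
        rows.append(
            {
                "category": cat,
                "mean_rho": rho.mean() if len(rho) else np.nan,
                "sd_rho": (rho.std(ddof=1) if len(rho) > 1 else (0.0 if len(rho) else np.nan)),
                "n_significant": len(sig),
                "n_total": n_total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PopulationState:
    """Outcome of the zero-growth assessment with its evidence tuple."""

    state: str  # active_zero_growth | growth | baseline
    population_trend_slope: float
    slope_ci: tuple[float, float]
    activity_fold: float
    rho_gap: float


def population_trend(series: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """OLS slope of log10 copies vs day with a t-based 95% CI."""
    days = series["day"].to_numpy(float)
    copies = series["copies_per_cm3"].to_numpy(float)
    if len(np.unique(days)) < 3:
        raise ValueError("population series must span at least 3 time points")
    if (copies <= 0).any():
        raise ValueError("copies_per_cm3 must be positive")
    res = stats.linregress(days, np.log10(copies))
    tcrit = stats.t.ppf(0.975, df=len(days) - 2)
    half = tcrit * res.stderr
    return res.slope, (res.slope - half, res.slope + half)


def classify_population_state(
    population_series: pd.DataFrame,
    fold_changes: pd.DataFrame,
    summaries: pd.DataFrame,
    activity_categories=ACTIVITY_CATEGORIES,
    growth_categories=GROWTH_CATEGORIES,
    fold_min: float = 10.0,
    gap_min: float = 0.2,
) -> PopulationState:
    """Call the population state from trend, activity fold, and rho gap.

    growth: the 95% CI of the log10-copies-vs-day slope lies above 0.
    active_zero_growth: the CI contains 0, the strongest treatment's
    total-mRNA fold change is >= fold_min, and the mean category rho of
    activity categories exceeds that of growth categories by >= gap_min.
    baseline otherwise.
    """
    slope, ci = population_trend(population_series)
    fold = float(fold_changes["fold_change"].max())
    s = summaries.set_index("category")["mean_rho"]
    act = [c for c in activity_categories if c in s.index and np.isfinite(s[c])]
    grow = [c for c in growth_categories if c in s.index and np.isfinite(s[c])]
    if not act or not grow:
        raise ValueError("need at least one activity and one growth category summary")
    gap = float(s[act].mean() - s[grow].mean())

    if ci[0] > 0:
        state = "growth"
    elif ci[0] <= 0 <= ci[1] and fold >= fold_min and gap >= gap_min:
        state = "active_zero_growth"
    else:
        state = "baseline"
    return PopulationState(
        state=state,
        population_trend_slope=float(slope),
        slope_ci=(float(ci[0]), float(ci[1])),
        activity_fold=fold,
        rho_gap=gap,
    )
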