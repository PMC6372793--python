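"""Normalization and total-activity summaries for gene x sample counts.

FPKM (fragments per kilobase per million total fragments) is the
length- and depth-normalized unit used for per-gene comparisons; the
depth denominator is either the focal genome's own fragment totals
(default; within-genome comparisons) or explicit whole-library totals
(required for "% of all transcripts" summaries and cross-treatment
fold changes of the focal genome's total mRNA).

Median-of-ratios size factors and a shifted-log variance-stabilizing
transform feed the differential-expression and clustering stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def compute_fpkm(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    total_fragments: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM_ij = K_ij / ((length_i/1000) * (N_j/1e6)).

    ``total_fragments`` gives the per-sample depth denominator N_j
    (whole-library totals); when omitted, per-sample sums of ``counts``
    (the focal genome's own totals) are used. Raises on zero-depth
    samples and on genes missing from the catalog.
    """
    lengths = catalog.set_index("gene_id")["length_nt"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes missing from catalog: {list(missing[:5])}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if total_fragments is None:
        depth = counts.sum(axis=0).astype(float)
    else:
        depth = total_fragments.reindex(counts.columns).astype(float)
        if depth.isna().any():
            raise KeyError("total_fragments missing for some samples")
    if (depth <= 0).any():
        bad = list(depth.index[depth <= 0][:5])
        raise ValueError(f"zero or negative sequencing depth for samples: {bad}")
    return counts.div(lengths / 1000.0, axis=0).div(depth / 1e6, axis=1)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over reference genes of K_ij / geomean_i(K_i.), where
    the reference set is the genes with no zero count in any sample. If
    no such gene exists, a +1 pseudo-reference is used (logged warning).
    """
    x = counts.to_numpy(float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        logger.warning(
            "no gene positive in all samples; using +1 pseudo-reference for size factors"
        )
        x = x + 1.0
        positive = np.ones(len(x), dtype=bool)
    ref = x[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=counts.columns, name="size_factor")


def variance_stabilize(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Shifted-log transform v_ij = log2(K_ij / s_j + pseudocount).

    A simple variance-stabilizing transform for NB counts, strictly
    increasing in the count at fixed size factor.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    s = size_factors.reindex(counts.columns).astype(float)
    if (s <= 0).any() or s.isna().any():
        raise ValueError("size factors must be positive for all samples")
    return np.log2(counts.div(s, axis=1) + pseudocount)


def scale_unit_interval(values) -> np.ndarray:
    """Scale a vector to [0, 1] via [x - min(x)] / max[x - min(x)].

    Constant input maps to all zeros (defined convention).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    shifted = x - x.min()
    m = shifted.max()
    if m == 0:
        return np.zeros_like(x)
    return shifted / m


def total_mrna(values: pd.DataFrame, gene_subset=None) -> pd.Series:
    """Per-sample totals of normalized counts over a gene subset.

    Default subset = all genes of the matrix (all CDS of the focal
    genome); raises on an empty subset or on genes absent from the
    matrix.
    """
    if gene_subset is None:
        sub = values
    else:
        gene_subset = list(gene_subset)
        if len(gene_subset) == 0:
            raise ValueError("empty gene subset")
        missing = set(gene_subset) - set(values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        sub = values.loc[gene_subset]
    totals = sub.sum(axis=0)
    totals.name = "total_mrna"
    return totals


def fold_change_vs_control(
    totals: pd.Series,
    design: pd.DataFrame,
    day: int,
    control: tuple[str, str] = ("none", "plusS"),
) -> pd.DataFrame:
    """Per-treatment fold change of mean totals vs the control condition.

    fold(treatment) = mean over replicates of T_j(treatment, day)
    divided by the mean over replicates of T_j(control, day). Returns one
    row per (substrate, sulfate) treatment present at ``day`` other than
    the control.
    """
    d = design.set_index("sample_id")
    at_day = d[d["day"] == day]
    ctrl_ids = at_day[
        (at_day["substrate"] == control[0]) & (at_day["sulfate"] == control[1])
    ].index
    if len(ctrl_ids) == 0:
        raise ValueError(f"control condition {control} absent at day {day}")
    ctrl_mean = totals.reindex(ctrl_ids).mean()
    if ctrl_mean == 0:
        raise ZeroDivisionError("control mean total is zero")
    rows = []
    for (substrate, sulfate), grp in at_day.groupby(["substrate", "sulfate"], sort=True):
        if (substrate, sulfate) == control:
            continue
        t = totals.reindex(grp.index)
        rows.append(
            {
                "substrate": substrate,
                "sulfate": sulfate,
                "day": day,
                "n_replicates": len(grp),
                "mean_total": t.mean(),
                "fold_change": t.mean() / ctrl_mean,
            }
        )
    return pd.DataFrame(rows)
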