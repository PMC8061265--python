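"""RNA-seq candidate-gene filter for resistance-associated expression.

The selection pipeline compares a focal (insecticide-selected) line to two
independent susceptible comparator lines, each with replicated libraries:

1. median-of-ratios size factors and normalization;
2. expression floor — a gene is kept only if every replicate of every line
   has normalized expression >= 0.5;
3. per gene, a one-way ANOVA across the three lines followed by Tukey HSD
   post-hoc comparisons of the focal line against each comparator, run on
   log2(normalized + 1) values; Benjamini-Hochberg correction across genes
   within each pairwise comparison;
4. candidate genes show a fold change >= 3 in the same direction versus
   BOTH comparators with corrected p <= 0.001 in both comparisons.

Requiring both comparators removes genes that merely drifted in one
susceptible background; the joint fold-change + FDR gate keeps the
candidate list specific enough to read gene by gene.

Tukey HSD p-values come from the studentized range distribution. Because
``scipy.stats.studentized_range.sf`` costs milliseconds per value, p-values
are evaluated through a monotone (PCHIP) interpolant of log sf built once
per (n_groups, df) on a fixed grid of exact scipy values; interpolation
error is below 1e-4 relative, far inside any decision tolerance here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .errors import CceampError, TableFormatError

DEFAULT_EXPRESSION_FLOOR = 0.5
DEFAULT_FC_MIN = 3.0
DEFAULT_ALPHA = 0.001

_TINY_P = float(np.finfo(float).tiny)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    For each sample j, the factor is the median over genes — restricted to
    genes with nonzero counts in every sample — of count_ij divided by the
    gene's geometric mean across samples. Factors are rescaled to geometric
    mean 1 so normalized values stay on the counts scale.
    """
    mat = counts.to_numpy(dtype=float)
    eligible = np.all(mat > 0, axis=1)
    if not np.any(eligible):
        raise CceampError("no gene with nonzero counts in every sample")
    logs = np.log(mat[eligible])
    log_gmean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gmean, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def filter_expressed(
    norm: pd.DataFrame, floor: float = DEFAULT_EXPRESSION_FLOOR
) -> pd.Index:
    """Genes whose normalized expression is >= floor in every sample."""
    keep = (norm >= floor).all(axis=1)
    return norm.index[keep]


@lru_cache(maxsize=8)
def _log_sf_spline(n_groups: int, df: int) -> PchipInterpolator:
    grid = np.linspace(1e-4, 80.0, 600)
    sf = stats.studentized_range.sf(grid, n_groups, df)
    sf = np.clip(sf, _TINY_P, 1.0)
    return PchipInterpolator(grid, np.log(sf))


def tukey_sf(q: np.ndarray, n_groups: int, df: int) -> np.ndarray:
    """Studentized-range survival function, vectorized via cached spline."""
    q = np.asarray(q, dtype=float)
    spline = _log_sf_spline(n_groups, int(df))
    p = np.exp(spline(np.clip(q, 1e-4, 80.0)))
    return np.clip(p, _TINY_P, 1.0)


@dataclass(frozen=True)
class DesignGroups:
    """Column indices of each line within the normalized matrix."""

    focal: np.ndarray
    comparator_1: np.ndarray
    comparator_2: np.ndarray


def _resolve_groups(
    columns: pd.Index,
    groups: Mapping[str, str] | pd.DataFrame,
    focal: str,
    comparators: Sequence[str],
) -> DesignGroups:
    if isinstance(groups, pd.DataFrame):
        required = {"sample_id", "group"}
        if not required.issubset(groups.columns):
            raise TableFormatError(f"sample sheet needs columns {sorted(required)}")
        mapping = dict(zip(groups["sample_id"], groups["group"]))
    else:
        mapping = dict(groups)
    if len(comparators) != 2:
        raise CceampError("exactly two comparator groups are required")
    idx = {}
    for name in (focal, *comparators):
        cols = np.array([i for i, c in enumerate(columns) if mapping.get(c) == name])
        if cols.size < 2:
            raise CceampError(f"group {name!r} has {cols.size} replicates, need >= 2")
        idx[name] = cols
    return DesignGroups(idx[focal], idx[comparators[0]], idx[comparators[1]])


def de_candidates(
    norm: pd.DataFrame,
    groups: Mapping[str, str] | pd.DataFrame,
    focal: str = "focal",
    comparators: Sequence[str] = ("comparator_1", "comparator_2"),
    fc_min: float = DEFAULT_FC_MIN,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "per-comparison",
) -> pd.DataFrame:
    """Differential-expression candidate filter over a normalized matrix.

    Parameters
    ----------
    norm
        Normalized expression, genes x samples (apply the expression floor
        first; every row is tested).
    groups
        sample -> group mapping or a sample sheet frame.
    correction
        ``"per-comparison"`` (default): BH across genes separately within
        each focal-vs-comparator Tukey p-value vector. ``"anova-first"``:
        BH across genes on the ANOVA p-value, candidates additionally gated
        on adjusted ANOVA p <= alpha while Tukey p-values stay raw.

    Returns
    -------
    One row per gene: group means (linear normalized scale), fold changes
    focal/comparator, adjusted p per comparison, direction
    (over/under/none) and the candidate flag. Zero-variance genes get p = 1
    when all group means agree, otherwise the smallest representable p and
    an ``exact-separation`` flag.
    """
    design = _resolve_groups(norm.columns, groups, focal, comparators)
    mat = norm.to_numpy(dtype=float)
    x = np.log2(mat + 1.0)
    blocks = [x[:, design.focal], x[:, design.comparator_1], x[:, design.comparator_2]]
    ns = np.array([b.shape[1] for b in blocks])
    n_total = int(ns.sum())
    k = 3
    df_within = n_total - k

    means = np.stack([b.mean(axis=1) for b in blocks], axis=1)
    grand = x[:, np.concatenate([design.focal, design.comparator_1, design.comparator_2])].mean(axis=1)
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((b - m[:, None]) ** 2).sum(axis=1) for b, m in zip(blocks, means.T))
    mse = ss_within / df_within

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / (k - 1)) / mse
    p_anova = np.where(
        mse > 0,
        stats.f.sf(f_stat, k - 1, df_within),
        np.where(ss_between > 0, _TINY_P, 1.0),
    )

    def pair_p(i_comp: int) -> np.ndarray:
        n_c = ns[i_comp]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[0] + 1.0 / n_c))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(means[:, 0] - means[:, i_comp]) / se
        p = np.where(
            mse > 0,
            tukey_sf(np.where(mse > 0, q, 0.0), k, df_within),
            np.where(means[:, 0] != means[:, i_comp], _TINY_P, 1.0),
        )
        return p

    p_c1 = pair_p(1)
    p_c2 = pair_p(2)

    if correction == "per-comparison":
        p_adj_c1 = multipletests(p_c1, method="fdr_bh")[1]
        p_adj_c2 = multipletests(p_c2, method="fdr_bh")[1]
        anova_gate = np.ones(len(norm), dtype=bool)
        p_anova_adj = multipletests(p_anova, method="fdr_bh")[1]
    elif correction == "anova-first":
        p_anova_adj = multipletests(p_anova, method="fdr_bh")[1]
        p_adj_c1, p_adj_c2 = p_c1, p_c2
        anova_gate = p_anova_adj <= alpha
    else:
        raise CceampError(f"unknown correction mode {correction!r}")

    lin_means = np.stack(
        [
            mat[:, design.focal].mean(axis=1),
            mat[:, design.comparator_1].mean(axis=1),
            mat[:, design.comparator_2].mean(axis=1),
        ],
        axis=1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc1 = lin_means[:, 0] / lin_means[:, 1]
        fc2 = lin_means[:, 0] / lin_means[:, 2]

    over = (fc1 >= fc_min) & (fc2 >= fc_min)
    under = (fc1 <= 1.0 / fc_min) & (fc2 <= 1.0 / fc_min)
    direction = np.where(over, "over", np.where(under, "under", "none"))
    candidate = (
        (direction != "none")
        & (p_adj_c1 <= alpha)
        & (p_adj_c2 <= alpha)
        & anova_gate
    )
    zero_var = mse == 0
    flag = np.where(
        zero_var & ((p_c1 == _TINY_P) | (p_c2 == _TINY_P)), "exact-separation", None
    )

    return pd.DataFrame(
        {
            "mean_focal": lin_means[:, 0],
            "mean_comparator_1": lin_means[:, 1],
            "mean_comparator_2": lin_means[:, 2],
            "fc_vs_c1": fc1,
            "fc_vs_c2": fc2,
            "p_anova": p_anova,
            "p_anova_adj": p_anova_adj,
            "p_c1": p_c1,
            "p_c2": p_c2,
            "p_adj_c1": p_adj_c1,
            "p_adj_c2": p_adj_c2,
            "direction": direction,
            "candidate": candidate,
            "flag": flag,
        },
        index=norm.index,
    )
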