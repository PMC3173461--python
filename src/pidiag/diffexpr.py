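"""Time-course differential expression and downstream summaries.

A gene is called differentially expressed when (a) a two-factor
fixed-effects ANOVA of its log2 signal on treatment and day — testing
the treatment main effect and the treatment x day interaction jointly by
an extra-sum-of-squares F — yields a Benjamini-Hochberg adjusted p below
``alpha``, and (b) its treated/control fold change crosses the fold
threshold (up: fold > t; down: fold < 1/t) at the required number of
time points.  The joint test matters because a gene responding only late
in the time course has no treatment main effect to speak of but a strong
interaction.

Called genes are grouped by agglomerative clustering of their
fold-change profiles (centred correlation distance, average linkage —
the classic expression-clustering defaults) and each group's mean
profile is symbolized per day as ``↑`` / ``↓`` / ``-`` against the fold
threshold.  Term overrepresentation in a gene set is scored by the
one-sided upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, check_meta
from .errors import DataError, DegenerateAnovaError, DomainError
from .simulate import DOWN, FLAT, UP, format_pattern


@dataclass
class DEParams:
    alpha: float = 0.01
    fc_threshold: float = 1.5
    min_timepoints: int = 2
    n_groups: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise DomainError("fc_threshold must exceed 1")
        if self.min_timepoints < 1 or self.n_groups < 1:
            raise DomainError("min_timepoints and n_groups must be at least 1")


def fold_changes(matrix: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-day treated/control fold change.

    ``fc(g, t) = mean(minus_P channels at t) / mean(plus_P channels at t)``
    computed on the (median-scaled) per-channel signals.  Columns are the
    sampling days in ascending order.
    """
    check_meta(meta, ("sample_id", "treatment", "day"))
    meta = meta[meta["sample_id"].isin(matrix.samples)]
    out = {}
    for day, grp in meta.groupby("day"):
        treated = grp.loc[grp["treatment"] == "minus_P", "sample_id"]
        control = grp.loc[grp["treatment"] == "plus_P", "sample_id"]
        if treated.empty or control.empty:
            raise DataError(f"day {day!r} is missing one treatment arm")
        out[int(day)] = (
            matrix.data[list(treated)].mean(axis=1)
            / matrix.data[list(control)].mean(axis=1)
        )
    fc = pd.DataFrame(out)
    return fc[sorted(fc.columns)]


def anova_pvalues(matrix: ExpressionMatrix, meta: pd.DataFrame) -> pd.Series:
    """Raw p-values of the joint treatment-response ANOVA test, per gene.

    Fits the full treatment x day cell-means model and the day-only
    reduced model to the log2 signals and compares them by an
    extra-sum-of-squares F with (cells - days) numerator and
    (n - cells) denominator degrees of freedom.  Vectorised over genes.
    """
    check_meta(meta, ("sample_id", "treatment", "day"))
    meta = meta[meta["sample_id"].isin(matrix.samples)].set_index("sample_id")
    meta = meta.loc[matrix.samples]
    y = np.log2(np.maximum(matrix.data.to_numpy(float), 1e-300))

    cells, cell_idx = np.unique(
        meta[["treatment", "day"]].astype(str).agg("|".join, axis=1), return_inverse=True
    )
    days, day_idx = np.unique(meta["day"].astype(str), return_inverse=True)
    n = y.shape[1]
    counts = np.bincount(cell_idx)
    if (counts < 2).any():
        raise DataError("every treatment x day cell needs at least 2 replicates")

    def sse(idx: np.ndarray, k: int) -> np.ndarray:
        tot = np.zeros((y.shape[0], k))
        np.add.at(tot.T, idx, y.T)
        means = tot / np.bincount(idx, minlength=k)
        resid = y - means[:, idx]
        return (resid**2).sum(axis=1)

    sse_full = sse(cell_idx, len(cells))
    sse_red = sse(day_idx, len(days))
    df1 = len(cells) - len(days)
    df2 = n - len(cells)
    if df1 < 1 or df2 < 1:
        raise DataError("design has no residual degrees of freedom")

    diff = np.maximum(sse_red - sse_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (diff / df1) / (sse_full / df2)
    p = stats.f.sf(f, df1, df2)
    # degenerate genes: residual variance at floating-point rounding level
    tiny = 1e-20 * np.maximum((y**2).sum(axis=1), 1.0)
    zero = sse_full <= tiny
    if zero.all():
        raise DegenerateAnovaError("zero within-cell variance for every gene")
    p[zero & (diff > tiny)] = 0.0
    p[zero & (diff <= tiny)] = 1.0
    return pd.Series(p, index=matrix.genes, name="p_raw")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_de(
    fc: pd.DataFrame, p_adj: pd.Series, params: DEParams | None = None
) -> pd.DataFrame:
    """Assemble the DE table with up/down calls.

    ``up``: adjusted p < alpha and fold > threshold at >= min_timepoints
    days; ``down`` likewise with fold < 1/threshold.  A gene may carry
    both calls (at different days) but belongs to the DE set once.
    """
    params = params or DEParams()
    if not fc.index.equals(p_adj.index):
        raise DataError("fold-change table and p-values are not gene-aligned")
    sig = p_adj < params.alpha
    n_up = (fc > params.fc_threshold).sum(axis=1)
    n_down = (fc < 1.0 / params.fc_threshold).sum(axis=1)
    table = fc.copy()
    table.columns = [f"fc_d{c}" for c in fc.columns]
    table["p_adj"] = p_adj
    table["up"] = sig & (n_up >= params.min_timepoints)
    table["down"] = sig & (n_down >= params.min_timepoints)
    table["de"] = table["up"] | table["down"]
    return table


def differential_expression(
    matrix: ExpressionMatrix, meta: pd.DataFrame, params: DEParams | None = None
) -> pd.DataFrame:
    """Convenience: fold changes + ANOVA + BH + calls in one step."""
    params = params or DEParams()
    fc = fold_changes(matrix, meta)
    p_raw = anova_pvalues(matrix, meta)
    p_adj = pd.Series(bh_adjust(p_raw.to_numpy()), index=p_raw.index, name="p_adj")
    table = call_de(fc, p_adj, params)
    table.insert(len(fc.columns), "p_raw", p_raw)
    return table


def _correlation_distances(profiles: np.ndarray) -> np.ndarray:
    """Condensed centred-correlation distance with flat-profile guards.

    A zero-variance profile correlates 1 with another flat profile
    (distance 0: duplicates must co-cluster) and 0 with everything else.
    """
    centred = profiles - profiles.mean(axis=1, keepdims=True)
    norm = np.sqrt((centred**2).sum(axis=1))
    flat = norm == 0
    safe = np.where(flat, 1.0, norm)
    unit = centred / safe[:, None]
    corr = unit @ unit.T
    if flat.any():
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
        corr[np.ix_(flat, flat)] = 1.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    profiles: pd.DataFrame, n_groups: int = 8
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage tree on fold-change profiles, cut into n_groups.

    Returns group labels (1..n_groups, numbered by first appearance in
    the gene list, so the labelling is deterministic) and the linkage
    matrix.
    """
    if n_groups < 1:
        raise DomainError("n_groups must be at least 1")
    if n_groups > len(profiles):
        raise DomainError("n_groups exceeds the number of genes")
    if len(profiles) == 1:
        return pd.Series([1], index=profiles.index, name="group"), np.empty((0, 4))
    z = linkage(_correlation_distances(profiles.to_numpy(float)), method="average")
    raw = fcluster(z, t=n_groups, criterion="maxclust")
    relabel, nxt = {}, 1
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = nxt
            nxt += 1
        labels.append(relabel[r])
    return pd.Series(labels, index=profiles.index, name="group"), z


def symbolize_profile(folds: Sequence[float], fc_threshold: float = 1.5) -> str:
    """Render a per-day fold profile as an ``↑ ↓ -`` pattern string."""
    folds = np.asarray(folds, dtype=float)
    if np.any(folds <= 0) or not np.all(np.isfinite(folds)):
        raise DomainError("folds must be positive and finite")
    symbols = np.where(
        folds > fc_threshold, UP, np.where(folds < 1.0 / fc_threshold, DOWN, FLAT)
    )
    return format_pattern(symbols)


def summarize_groups(
    fc: pd.DataFrame, groups: pd.Series, fc_threshold: float = 1.5
) -> pd.DataFrame:
    """Per-group gene count and symbolized mean fold-change profile."""
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        mean_profile = fc.loc[idx].mean(axis=0)
        rows.append(
            {
                "group": g,
                "n_genes": len(idx),
                "pattern": symbolize_profile(mean_profile.to_numpy(), fc_threshold),
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def term_enrichment(
    selected: Sequence[str],
    annotation: pd.DataFrame,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of terms in a gene selection.

    ``annotation`` maps ``gene_id`` to ``term`` (long format, one row per
    assignment).  For each term with K annotated genes in the universe of
    size N, and k annotated genes among the n selected, the one-sided
    upper-tail p is ``P[X >= k]`` for X ~ Hypergeom(N, K, n); p-values
    are BH-adjusted across terms.
    """
    universe = pd.Index(universe)
    selected = pd.Index(selected)
    stray = selected.difference(universe)
    if len(stray):
        raise DataError(f"selected genes outside the universe: {list(stray)[:5]}")
    if selected.empty:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "fold_enrichment", "p", "p_adj"]
        )
    ann = annotation[annotation["gene_id"].isin(universe)]
    big_n, small_n = len(universe), len(selected)
    rows = []
    for term, grp in ann.groupby("term"):
        term_genes = pd.Index(grp["gene_id"].unique())
        big_k = len(term_genes)
        small_k = len(term_genes.intersection(selected))
        p = float(stats.hypergeom.sf(small_k - 1, big_n, big_k, small_n))
        fold = (small_k / small_n) / (big_k / big_n) if big_k else np.nan
        rows.append(
            {
                "term": term,
                "k": small_k,
                "K": big_k,
                "n": small_n,
                "N": big_n,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "term"]).reset_index(drop=True)


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def welch_ttest(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> WelchResult:
    """Two-sided Welch t-test from summary statistics.

    Accepts the mean, standard error of the mean, and sample size of each
    group (the form in which field-trial tables are published) and uses
    the Welch-Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs at least 2 observations")
    if sem1 <= 0 or sem2 <= 0:
        raise DomainError("standard errors must be positive")
    res = stats.ttest_ind_from_stats(
        mean1,
        sem1 * np.sqrt(n1),
        n1,
        mean2,
        sem2 * np.sqrt(n2),
        n2,
        equal_var=False,
    )
    v1, v2 = sem1**2, sem2**2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))
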