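"""Methylation-expression integration.

Three analyses relate feature methylation to log2 expression:

* binned-average correlation — per sample, genes are grouped into four
  methylation bands (<0.4, 0.4-0.6, 0.6-0.8, >=0.8) and the band means of
  methylation and expression are correlated (Pearson);
* over/under-expressed gene-set comparison — Mann-Whitney test of promoter
  methylation between two disjoint gene sets;
* locus-level correlation — Spearman rho between one feature's methylation
  and one gene's expression across samples, with an exact permutation p for
  small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

EXPR_BIN_EDGES = (0.4, 0.6, 0.8)
EXPR_BIN_LABELS = ("<0.4", "0.4-0.6", "0.6-0.8", ">=0.8")


def _bin_ids(meth: np.ndarray) -> np.ndarray:
    return np.digitize(meth, EXPR_BIN_EDGES)  # 0..3


@dataclass
class BinnedCorrelation:
    """Per-sample binned methylation-expression correlations."""

    per_sample: pd.DataFrame  # sample, r, p, n_bins
    bin_means: pd.DataFrame  # sample x band methylation/expression means

    @property
    def mean_r(self) -> float:
        return float(self.per_sample["r"].mean())


def binned_methylation_expression(
    meth: pd.DataFrame, expr: pd.DataFrame
) -> BinnedCorrelation:
    """Correlate band-mean methylation with band-mean expression per sample.

    ``meth`` and ``expr`` are gene x sample frames sharing gene ids and
    sample ids. For each sample, genes are banded by methylation; samples
    where all genes fall into one band raise (no correlation is defined).
    """
    genes = meth.index.intersection(expr.index)
    samples = [s for s in meth.columns if s in expr.columns]
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("no shared genes/samples between methylation and expression")
    rows, mean_rows = [], []
    for s in samples:
        m = meth.loc[genes, s].to_numpy(dtype=float)
        e = expr.loc[genes, s].to_numpy(dtype=float)
        ok = ~(np.isnan(m) | np.isnan(e))
        bins = _bin_ids(m[ok])
        used = np.unique(bins)
        if len(used) < 2:
            raise ValueError(f"sample {s}: all genes fall in one methylation band")
        bm = np.array([m[ok][bins == b].mean() for b in used])
        be = np.array([e[ok][bins == b].mean() for b in used])
        res = stats.pearsonr(bm, be)
        rows.append((s, float(res.statistic), float(res.pvalue), len(used)))
        for b, mm, ee in zip(used, bm, be):
            mean_rows.append((s, EXPR_BIN_LABELS[b], mm, ee))
    per_sample = pd.DataFrame(rows, columns=["sample", "r", "p", "n_bins"])
    bin_means = pd.DataFrame(mean_rows, columns=["sample", "band", "meth_mean", "expr_mean"])
    return BinnedCorrelation(per_sample, bin_means)


@dataclass(frozen=True)
class SetComparison:
    median_over: float
    median_under: float
    u_statistic: float
    p: float
    n_over: int
    n_under: int


def de_set_methylation_test(
    meth_per_gene: pd.Series, over_set, under_set
) -> SetComparison:
    """Mann-Whitney comparison of methylation between two gene sets.

    ``meth_per_gene`` maps gene id to (promoter) methylation; the over- and
    under-expressed sets must be disjoint with >= 3 genes each having
    methylation values.
    """
    over = [g for g in over_set if g in meth_per_gene.index and np.isfinite(meth_per_gene[g])]
    under = [g for g in under_set if g in meth_per_gene.index and np.isfinite(meth_per_gene[g])]
    if set(over) & set(under):
        raise ValueError("over- and under-expressed sets overlap")
    if len(over) < 3 or len(under) < 3:
        raise ValueError("each gene set needs >= 3 genes with methylation values")
    a = meth_per_gene[over].to_numpy(dtype=float)
    b = meth_per_gene[under].to_numpy(dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return SetComparison(
        float(np.median(a)), float(np.median(b)), float(res.statistic), float(res.pvalue),
        len(a), len(b),
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all rank pairings (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    hits = total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in permutations(range(len(ry))):
        rho = float(np.dot(rx, ry[list(perm)])) / denom
        total += 1
        if abs(rho) >= thresh:
            hits += 1
    return hits / total


def locus_correlation(meth: pd.Series | np.ndarray, expr: pd.Series | np.ndarray,
                      *, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman correlation of one locus's methylation with one gene's
    expression across samples.

    Exact permutation p for n <= ``exact_max_n`` (full enumeration of rank
    pairings), t-approximation otherwise. Constant inputs raise — the
    correlation is undefined, never silently NaN.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if len(x) != len(y):
        raise ValueError("methylation and expression must be paired")
    if len(x) < 5:
        raise ValueError("need >= 5 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_max_n:
        return rho, _spearman_exact_p(x, y, rho)
    return rho, float(res.pvalue)
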