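"""Whole-genome methylation profiles: five-score-band categorization and
exact tests for group differences.

Window scores are categorized into five bands (<0.2, 0.2-0.4, 0.4-0.6,
0.6-0.8, 0.8-1.0; left-closed, last band closed at 1.0) and group profiles
are compared with Fisher's exact test — full enumeration over tables with
fixed margins when feasible, otherwise a seeded Monte-Carlo exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd

BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
BIN_LABELS = ("<0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1.0")


@dataclass
class BinProfile:
    """Counts and percentages of scores per methylation band."""

    counts: np.ndarray
    n: int
    mean_pct: float  # mean score x 100

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": BIN_LABELS, "count": self.counts, "percent": self.percentages}
        )


def bin_methylome(scores) -> BinProfile:
    """Bin scores into the five methylation bands.

    Accepts any array of scores (a whole track, one feature class's windows,
    or a feature-matrix column); NaNs are dropped. Bands are half-open on
    the left with the last band closed, so 0.2 falls in "0.2-0.4" and 1.0 in
    "0.8-1.0".
    """
    x = np.asarray(scores, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no callable scores in scope")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    counts, _ = np.histogram(x, bins=BIN_EDGES)
    return BinProfile(counts.astype(np.int64), int(x.size), float(100.0 * x.mean()))


def group_profile(tracks_scores: np.ndarray) -> BinProfile:
    """Profile of a group: per-window scores averaged across samples first
    (the display convention for group panels), then binned."""
    arr = np.asarray(tracks_scores, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a samples x windows array")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return bin_methylome(np.nanmean(arr, axis=0))


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    lp = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    lp -= lgamma(n + 1)
    lp -= sum(lgamma(x + 1) for x in table.ravel())
    return lp


def _enumerate_2xk(col_sums, r1):
    """Yield all first rows (x_1..x_k) with 0 <= x_j <= col_j, sum = r1."""
    k = len(col_sums)

    def rec(j, remaining, prefix):
        if j == k - 1:
            if remaining <= col_sums[j]:
                yield prefix + (remaining,)
            return
        tail_cap = sum(col_sums[j + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(col_sums[j], remaining)
        for x in range(lo, hi + 1):
            yield from rec(j + 1, remaining - x, prefix + (x,))

    yield from rec(0, r1, ())


@dataclass(frozen=True)
class FisherResult:
    p: float
    mode: str  # "enumeration" or "monte-carlo"
    n_tables: int  # tables enumerated or draws used
    mc_se: float = 0.0


def fisher_exact_2xk(
    table, *, max_tables: int = 1_000_000, n_draws: int = 100_000, seed: int = 0
) -> FisherResult:
    """Fisher's exact test for a 2 x k contingency table.

    Full enumeration over tables with the observed margins when their count
    does not exceed ``max_tables`` (p sums the probabilities of tables no
    more probable than the observed one); otherwise a seeded Monte-Carlo
    exact test over ``n_draws`` tables sampled with fixed margins, flagged
    by mode.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or (row_sums == 0).any() or (col_sums == 0).all():
        raise ValueError("table margins must be positive")
    keep = col_sums > 0  # empty columns carry no information
    t = t[:, keep]
    col_sums = col_sums[keep]
    lp_obs = _log_table_prob(t, row_sums, col_sums, n)
    n_possible = int(np.prod(col_sums + 1.0)) if np.prod(col_sums + 1.0) < 2**62 else 2**62
    if n_possible <= max_tables:
        total = 0.0
        p = 0.0
        count = 0
        for first_row in _enumerate_2xk(tuple(int(c) for c in col_sums), int(row_sums[0])):
            cand = np.vstack([first_row, col_sums - np.asarray(first_row)])
            lp = _log_table_prob(cand, row_sums, col_sums, n)
            pr = np.exp(lp)
            total += pr
            if lp <= lp_obs + 1e-9:
                p += pr
            count += 1
        return FisherResult(min(p / total, 1.0), "enumeration", count)
    rng = np.random.default_rng(seed)
    from scipy.stats import random_table

    draws = random_table(row_sums, col_sums).rvs(n_draws, method="patefield", random_state=rng)
    lps = np.array([_log_table_prob(d, row_sums, col_sums, n) for d in draws])
    hits = (lps <= lp_obs + 1e-9).mean()
    se = float(np.sqrt(hits * (1 - hits) / n_draws))
    return FisherResult(float(hits), "monte-carlo", n_draws, se)


def compare_bin_profiles(
    profile_a: BinProfile, profile_b: BinProfile, seed: int = 0, *, scale: str = "percent"
) -> FisherResult:
    """Exact test of two five-band profiles (2 x 5 table).

    With ``scale="percent"`` (default) the table holds rounded band
    percentages (each row totals ~100), asking whether the *shape* of the
    two distributions differs — on raw window counts (``scale="counts"``)
    genome-scale totals make any difference significant.
    """
    if scale == "percent":
        table = np.vstack(
            [np.round(profile_a.percentages).astype(int), np.round(profile_b.percentages).astype(int)]
        )
    elif scale == "counts":
        table = np.vstack([profile_a.counts, profile_b.counts])
    else:
        raise ValueError("scale must be 'percent' or 'counts'")
    return fisher_exact_2xk(table, seed=seed)


def density_curve(scores, bandwidth: float = 0.03, grid: int = 201) -> pd.DataFrame:
    """Score-vs-frequency density (Gaussian KDE on [0, 1]) for display."""
    x = np.asarray(scores, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no scores")
    gx = np.linspace(0.0, 1.0, grid)
    dens = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    dens /= x.size * bandwidth * np.sqrt(2 * np.pi)
    return pd.DataFrame({"score": gx, "density": dens})
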