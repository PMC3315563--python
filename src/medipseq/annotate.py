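"""Feature-level aggregation of window methylation and repeat CpG statistics.

Maps per-window scores onto annotated features (promoters, gene bodies,
CGIs, CGI shores, repeat classes), classifies CGIs and repeats by genomic
context (promoter / intragenic / intergenic), and tests CpG-density
enrichment between repeat sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .track import MethylomeTrack

META_COLUMNS = ["feature_class", "chrom", "start", "end", "cpg_count", "context", "n_windows"]


@dataclass
class FeatureMatrix:
    """Features x samples methylation with per-feature metadata.

    ``values``: DataFrame indexed by feature_id, one column per sample,
    cells in [0, 1] or NaN (not enough callable windows). ``meta``: DataFrame
    on the same index with class, coordinates, CpG count, genomic context
    and the number of overlapping grid windows.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the feature index")
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation cells must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def incomplete_rows(self) -> pd.Index:
        return self.values.index[self.values.isna().any(axis=1)]

    def subset_class(self, feature_class: str) -> "FeatureMatrix":
        keep = self.meta.feature_class == feature_class
        return FeatureMatrix(self.values.loc[keep].copy(), self.meta.loc[keep].copy())

    def complete(self) -> "FeatureMatrix":
        keep = ~self.values.isna().any(axis=1)
        return FeatureMatrix(self.values.loc[keep].copy(), self.meta.loc[keep].copy())

    def to_tsv(self, path) -> None:
        joined = self.meta.join(self.values)
        with open(path, "w") as fh:
            fh.write("# medipseq FeatureMatrix; meta columns: " + ",".join(self.meta.columns) + "\n")
            joined.to_csv(fh, sep="\t", index_label="feature_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing FeatureMatrix metadata header")
            meta_cols = header.rstrip("\n").split("meta columns: ")[1].split(",")
            df = pd.read_csv(fh, sep="\t", index_col="feature_id", na_values="NA")
        return cls(df.drop(columns=meta_cols), df[meta_cols])


def _overlap_any(start: int, end: int, others: pd.DataFrame) -> bool:
    return bool(((others.start < end) & (others.end > start)).any())


def classify_context(genome: GenomeSpec, features: pd.DataFrame) -> pd.Series:
    """Genomic context per feature: promoter > intragenic > intergenic.

    A feature overlapping any promoter by >= 1 bp is ``promoter``; otherwise
    overlapping any gene body is ``intragenic``; otherwise ``intergenic``.
    """
    promoters = genome.features("promoter")
    bodies = genome.features("gene_body")
    out = {}
    for row in features.itertuples():
        proms = promoters[promoters.chrom == row.chrom]
        bods = bodies[bodies.chrom == row.chrom]
        if _overlap_any(row.start, row.end, proms):
            out[row.feature_id] = "promoter"
        elif _overlap_any(row.start, row.end, bods):
            out[row.feature_id] = "intragenic"
        else:
            out[row.feature_id] = "intergenic"
    return pd.Series(out, name="context")


def classify_cgi_context(genome: GenomeSpec) -> pd.Series:
    """Context label for every CGI (see :func:`classify_context`)."""
    return classify_context(genome, genome.features("cgi"))


def aggregate_features(
    tracks: list[MethylomeTrack],
    genome: GenomeSpec,
    min_windows: int = 1,
    *,
    statistic: str = "mean",
    feature_classes: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Aggregate window scores to feature-level methylation per sample.

    Each cell is the mean (or median, via ``statistic``) of callable window
    scores overlapping the feature by >= 1 bp; a cell is missing when fewer
    than ``min_windows`` callable windows overlap. Contexts are attached for
    CGIs and repeats.
    """
    if min_windows < 1:
        raise ValueError("min_windows must be >= 1")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if not tracks:
        raise ValueError("need at least one track")
    grid = genome.grid
    for t in tracks:
        if t.grid.chrom_lengths != grid.chrom_lengths:
            raise ValueError("tracks must share the genome's window grid")
    ann = genome.annotations
    if feature_classes is not None:
        ann = ann[ann.feature_class.isin(feature_classes)]
    agg = np.nanmean if statistic == "mean" else np.nanmedian

    ctx_features = ann[ann.feature_class.isin(("cgi", "SINE", "LINE", "LTR", "satellite"))]
    contexts = classify_context(genome, ctx_features) if len(ctx_features) else pd.Series(dtype=object)

    values, meta_rows = {}, []
    scores = np.vstack([t.score for t in tracks])  # samples x windows
    sample_ids = [t.sample_id for t in tracks]
    for row in ann.itertuples():
        if not (0 <= row.start < row.end <= genome.chrom_lengths[row.chrom]):
            raise ValueError(f"feature {row.feature_id} outside genome bounds")
        lo, hi = grid.overlapping_windows(row.chrom, row.start, row.end)
        win = grid.flat_index(row.chrom, np.arange(lo, hi))
        sub = scores[:, win]
        n_call = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            cell = np.where(n_call >= min_windows, agg(sub, axis=1), np.nan)
        values[row.feature_id] = cell
        meta_rows.append(
            (
                row.feature_id,
                row.feature_class,
                row.chrom,
                row.start,
                row.end,
                genome.cpg_count_in(row.chrom, row.start, row.end),
                contexts.get(row.feature_id, ""),
                hi - lo,
            )
        )
    meta = pd.DataFrame(meta_rows, columns=["feature_id"] + META_COLUMNS).set_index("feature_id")
    vals = pd.DataFrame(values, index=sample_ids).T
    vals.index.name = "feature_id"
    return FeatureMatrix(vals, meta)


def cpg_density(meta: pd.DataFrame) -> pd.Series:
    """CpGs per kb of feature length."""
    return 1000.0 * meta.cpg_count / (meta.end - meta.start)


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration of group assignments.

    Handles ties via average ranks; feasible for small samples (the caller
    restricts to n1 + n2 <= 20, at most C(20,10) = 184756 arrangements).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    hits = 0
    total = comb(n, n1)
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev_obs:
            hits += 1
    return float(u_obs), hits / total


def cpg_density_enrichment(
    repeats_a: pd.DataFrame, repeats_b: pd.DataFrame, *, exact_max_n: int = 20
) -> tuple[float, float]:
    """Mann-Whitney test of CpG density (CpGs/kb) between two repeat sets.

    Exact two-sided p by full enumeration when the pooled sample is small
    (<= ``exact_max_n``); otherwise the normal approximation with tie
    correction. Returns ``(U, p)``; two identical all-equal sets give p = 1.
    """
    if len(repeats_a) == 0 or len(repeats_b) == 0:
        raise ValueError("both repeat sets must be non-empty")
    a = cpg_density(repeats_a).to_numpy()
    b = cpg_density(repeats_b).to_numpy()
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    if len(a) + len(b) <= exact_max_n:
        return _exact_mannwhitney_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
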