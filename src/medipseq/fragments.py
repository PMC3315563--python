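"""Aligned MeDIP fragments and the read filter applied before quantification.

A :class:`FragmentSet` holds the inferred insert intervals of one sample's
uniquely aligned read pairs, each with a mapping quality and a PCR-duplicate
flag. Filtering removes duplicated placements (first occurrence of each
identical ``(chrom, start, end, strand)`` kept) and low-confidence alignments
(mapping quality below a threshold, default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "is_duplicate"]


@dataclass
class FragmentSet:
    """Aligned fragment intervals (0-based half-open) for one sample."""

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        rec = self.records
        if len(rec) and not (rec.start < rec.end).all():
            raise ValueError("fragments must satisfy start < end")
        if len(rec) and (rec.mapq < 0).any():
            raise ValueError("mapping quality must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, index) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.records.iloc[index].reset_index(drop=True))

    def center_coverage(self, grid) -> np.ndarray:
        """Per-window count of fragments covering the window center.

        This is the observation the quantifier models: a fragment anchored on
        a CpG at distance d covers the center with probability (L - d)/L, the
        coupling kernel, so center counts match the model's mean function.
        """
        cov = np.zeros(grid.total_windows, dtype=np.int64)
        for chrom, sub in self.records.groupby("chrom", sort=False):
            if chrom not in grid.chrom_lengths:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            n = grid.n_windows(chrom)
            centers = grid.centers(chrom)
            s = np.sort(sub.start.to_numpy())
            e = np.sort(sub.end.to_numpy())
            cov[grid.offset(chrom) : grid.offset(chrom) + n] = np.searchsorted(
                s, centers, "right"
            ) - np.searchsorted(e, centers, "right")
        return cov

    def coverage(self, grid) -> np.ndarray:
        """Per-window fragment count (overlap >= 1 bp), flat over the grid."""
        cov = np.zeros(grid.total_windows, dtype=np.int64)
        for chrom, sub in self.records.groupby("chrom", sort=False):
            if chrom not in grid.chrom_lengths:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            n = grid.n_windows(chrom)
            lo = np.minimum(np.maximum(sub.start.to_numpy() // grid.size, 0), n)
            hi = np.minimum((sub.end.to_numpy() - 1) // grid.size + 1, n)
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
            cov[grid.offset(chrom) : grid.offset(chrom) + n] = np.cumsum(diff[:-1])
        return cov


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_duplicates_removed: int
    n_lowq_removed: int
    n_kept: int


def filter_fragments(raw: FragmentSet, mapq_min: int = 10) -> tuple[FragmentSet, FilterReport]:
    """Remove duplicated placements and low-mapping-quality fragments.

    Duplicates are identical ``(chrom, start, end, strand)`` tuples; the first
    occurrence is kept. Fragments with ``mapq < mapq_min`` are then dropped.
    Returns the filtered set and a per-reason removal report.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    rec = raw.records
    n_input = len(rec)
    dedup = rec.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    n_dup = n_input - len(dedup)
    kept = dedup[dedup.mapq >= mapq_min].reset_index(drop=True)
    n_lowq = len(dedup) - len(kept)
    report = FilterReport(n_input, n_dup, n_lowq, len(kept))
    return FragmentSet(raw.sample_id, kept), report
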