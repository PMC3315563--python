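"""Fixed 100-bp window grid shared by every stage of the pipeline.

All genomic coordinates in this package are 0-based, half-open ``[start, end)``.
Window ``i`` on a chromosome covers ``[i * size, (i + 1) * size)``; a trailing
partial window (shorter than ``size``) is dropped, so every window has the full
width and the grid is identical for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WINDOW_SIZE = 100


@dataclass(frozen=True)
class WindowGrid:
    """Per-chromosome 100-bp window grid with flat (genome-wide) indexing."""

    chrom_lengths: dict[str, int]
    size: int = WINDOW_SIZE
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            if length < self.size:
                raise ValueError(f"chromosome {chrom!r} shorter than one window")
        offsets, total = {}, 0
        for chrom in self.chrom_lengths:
            offsets[chrom] = total
            total += self.n_windows(chrom)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_windows(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.size

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chroms)

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def window_of(self, chrom: str, pos) -> np.ndarray:
        """Window index (chromosome-local) containing each position; -1 if the
        position falls in the dropped partial tail."""
        idx = np.asarray(pos, dtype=np.int64) // self.size
        n = self.n_windows(chrom)
        return np.where(idx < n, idx, -1)

    def overlapping_windows(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open range of chromosome-local windows overlapping [start, end)
        by at least 1 bp, clipped to the grid."""
        if end <= start:
            raise ValueError("empty interval")
        lo = max(start // self.size, 0)
        hi = min((end - 1) // self.size + 1, self.n_windows(chrom))
        return lo, max(hi, lo)

    def flat_index(self, chrom: str, local: np.ndarray) -> np.ndarray:
        return np.asarray(local) + self._offsets[chrom]

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom), dtype=np.int64) * self.size

    def centers(self, chrom: str) -> np.ndarray:
        return self.starts(chrom) + self.size // 2
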