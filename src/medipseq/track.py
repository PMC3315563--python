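"""Per-sample methylome track: one score per callable 100-bp window."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowGrid


@dataclass
class MethylomeTrack:
    """Inferred absolute methylation per 100-bp window for one sample.

    ``score`` is the posterior median in [0, 1] (NaN where the window is not
    callable), ``ci_half`` the 80 % credible half-width, ``coverage`` the
    number of fragments overlapping the window by >= 1 bp.
    """

    sample_id: str
    grid: WindowGrid
    score: np.ndarray  # flat over grid, NaN = missing
    ci_half: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        n = self.grid.total_windows
        for name in ("score", "ci_half", "coverage"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the window grid")
        finite = self.score[~np.isnan(self.score)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def callable_mask(self) -> np.ndarray:
        return ~np.isnan(self.score)

    @property
    def n_callable(self) -> int:
        return int(self.callable_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.grid.chroms:
            n = self.grid.n_windows(chrom)
            off = self.grid.offset(chrom)
            starts = self.grid.starts(chrom)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.grid.size,
                        "score": self.score[off : off + n],
                        "ci_half": self.ci_half[off : off + n],
                        "coverage": self.coverage[off : off + n],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
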