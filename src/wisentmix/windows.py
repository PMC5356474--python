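"""Non-overlapping genomic windows indexing every blockwise computation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WindowTable:
    """Ordered, tiling, non-overlapping windows over a genome.

    The table is a DataFrame with columns ``chrom, start, end, full`` where
    coordinates are 0-based half-open and ``full`` marks windows of exactly
    the nominal size (the terminal window of each chromosome may be shorter).
    The row position is the globally unique window index.
    """

    df: pd.DataFrame
    size: int
    step: int | None = None  # != size only for sliding windows

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.size
        self._bounds_cache: dict[str, tuple[int, np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_windows(self) -> int:
        return len(self.df)

    def chrom_windows(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def chrom_bounds(self, chrom: str) -> tuple[int, np.ndarray, np.ndarray]:
        """(first global index, starts, ends) of one chromosome's windows."""
        cached = self._bounds_cache.get(chrom)
        if cached is None:
            sub = self.chrom_windows(chrom)
            if sub.empty:
                raise KeyError(f"chromosome {chrom!r} not in window table")
            cached = (
                int(sub.index[0]),
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
            )
            self._bounds_cache[chrom] = cached
        return cached

    def position_index(self, chrom: str, length: int) -> np.ndarray:
        """Global window index of every position of a chromosome."""
        if self.step != self.size:
            raise NotImplementedError("position indexing requires tiling windows")
        first, _starts, _ends = self.chrom_bounds(chrom)
        nwin = len(self.chrom_windows(chrom))
        return first + np.minimum(
            np.arange(length, dtype=np.int64) // self.size, nwin - 1
        )

    def index_of_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Global window index of selected positions (sparse counterpart of
        :meth:`position_index`)."""
        if self.step != self.size:
            raise NotImplementedError("position indexing requires tiling windows")
        first, starts, _ends = self.chrom_bounds(chrom)
        return first + np.minimum(positions // self.size, len(starts) - 1)

    def count_by_window(self, chrom: str, mask: np.ndarray, out: np.ndarray) -> None:
        """Add per-window True counts of a chromosome-length boolean mask into
        the global accumulator ``out`` (length ``n_windows``)."""
        first, starts, ends = self.chrom_bounds(chrom)
        for i, (s, e) in enumerate(zip(starts, ends)):
            out[first + i] += np.count_nonzero(mask[s:e])

    def lengths_bp(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def partition_windows(
    chrom_lengths: dict[str, int], size: int = 1_000_000, step: int | None = None
) -> WindowTable:
    """Tile each chromosome with non-overlapping windows of ``size`` bp.

    The terminal window of a chromosome holds the remainder (``L mod size``)
    when the length is not an exact multiple.  Window indices are global and
    follow the chromosome order of the input mapping.  Passing ``step``
    smaller than ``size`` yields true sliding (overlapping) windows, which
    the divergence and pattern-counting routines accept; blockwise statistics
    default to the non-overlapping tiling.
    """
    if size < 1:
        raise ValueError(f"window size must be >= 1, got {size}")
    if step is None:
        step = size
    if not 1 <= step <= size:
        raise ValueError(f"step must be in [1, size], got {step}")
    if not chrom_lengths:
        raise ValueError("empty chromosome length table")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, step, dtype=np.int64)
        if step != size:  # sliding: drop start points with no new full window
            starts = starts[(starts + size <= length) | (starts == 0)]
        ends = np.minimum(starts + size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), int(e - s) == size))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "full"])
    return WindowTable(df=df, size=size, step=step)
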