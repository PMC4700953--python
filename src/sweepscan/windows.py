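"""Overlapping genomic windows and per-window averaging.

The scan frame is a grid of fixed-width windows (default 40 kb) advancing in
fixed steps (default 5 kb), anchored at coordinate 0 of each chromosome.
Trailing partial windows are discarded so every window statistic averages the
same span. Any per-site value (allele frequency, Fst, heterozygosity, |iHS|)
is reduced to a per-window arithmetic mean over the sites falling inside the
window; because consecutive windows overlap, a site contributes to up to
``window_size / step`` windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW_SIZE = 40_000
DEFAULT_STEP = 5_000
DEFAULT_MIN_SNPS = 5


@dataclass(frozen=True)
class WindowGrid:
    """Frame of overlapping [start, start + window_size) windows on one chromosome.

    Starts are 0-based half-open and multiples of ``step``; every window lies
    fully within ``[0, chrom_length)``.
    """

    chrom: str
    chrom_length: int
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")

    @property
    def n_windows(self) -> int:
        if self.chrom_length < self.window_size:
            return 0
        return (self.chrom_length - self.window_size) // self.step + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows, dtype=np.int64) * self.step

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_size

    def centers(self) -> np.ndarray:
        return self.starts + self.window_size // 2


@dataclass
class WindowStat:
    """Per-window mean of a site-level track on a :class:`WindowGrid`.

    ``value[i]`` is NaN (missing) wherever fewer than ``min_snps`` sites with
    a defined value fall in window ``i``.
    """

    grid: WindowGrid
    value: np.ndarray
    n_snps: np.ndarray
    min_snps: int = DEFAULT_MIN_SNPS
    label: str = ""

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.value)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.starts,
                "end": self.grid.ends,
                "value": self.value,
                "n_snps": self.n_snps,
            }
        )

    def to_bedgraph(self, path, name: str | None = None) -> None:
        """Write defined windows as BEDGRAPH-style TSV (0-based half-open)."""
        df = self.to_frame()
        df = df[~np.isnan(df["value"].to_numpy())]
        with open(path, "w") as fh:
            if name:
                fh.write(f'track type=bedGraph name="{name}"\n')
            df[["chrom", "start", "end", "value"]].to_csv(
                fh, sep="\t", header=False, index=False, float_format="%.6g"
            )


def make_window_grid(
    chrom_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    chrom: str = "1",
) -> WindowGrid:
    """Build the overlapping-window frame for one chromosome."""
    return WindowGrid(chrom=chrom, chrom_length=int(chrom_length), window_size=window_size, step=step)


def window_mean(
    positions: np.ndarray,
    values: np.ndarray,
    grid: WindowGrid,
    min_snps: int = DEFAULT_MIN_SNPS,
    label: str = "",
) -> WindowStat:
    """Average a per-site track over every window of the grid.

    Parameters
    ----------
    positions
        Sorted 0-based site positions on the grid's chromosome.
    values
        Per-site values aligned with ``positions``; NaN marks a site with no
        defined value (it contributes to neither the mean nor ``n_snps``).
    min_snps
        Windows with fewer defined sites than this are reported as NaN.
    """
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must have equal length")
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")

    ok = ~np.isnan(values)
    # prefix sums over defined sites only; window membership via searchsorted
    cum_val = np.concatenate([[0.0], np.cumsum(np.where(ok, values, 0.0))])
    cum_cnt = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])

    lo = np.searchsorted(positions, grid.starts, side="left")
    hi = np.searchsorted(positions, grid.ends, side="left")
    n = cum_cnt[hi] - cum_cnt[lo]
    total = cum_val[hi] - cum_val[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
    mean[n < min_snps] = np.nan
    return WindowStat(grid=grid, value=mean, n_snps=n, min_snps=min_snps, label=label)
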