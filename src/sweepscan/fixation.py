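"""Parallel-fixation screen across replicated populations.

A window is evidence of parallel fixation when the window-mean alternate
allele frequency is high in *every* population — the decision statistic is
therefore the across-population minimum of the window means, compared
inclusively against a threshold tau (default 0.85). Flagged windows that are
adjacent on the grid merge into candidate regions, mirroring the contiguous
tracts that hitchhiking produces around a swept site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowStat

DEFAULT_TAU = 0.85


def min_af_statistic(afs) -> float:
    """Across-population minimum allele frequency — the all-populations
    decision statistic (min >= tau  <=>  every population >= tau).

    Raises on missing values: a parallel claim must never rest on an absent
    population.
    """
    arr = np.asarray(afs, dtype=float)
    if arr.size < 2:
        raise ValueError("need allele frequencies from at least 2 populations")
    if np.isnan(arr).any():
        raise ValueError("missing allele frequency; statistic undefined")
    return float(arr.min())


def flag_fixation_windows(stats: list[WindowStat], tau: float = DEFAULT_TAU) -> np.ndarray:
    """Boolean flags: window-mean AF >= tau (inclusive) in all populations.

    Windows undefined in any population are never flagged.
    """
    if len(stats) < 2:
        raise ValueError("need window stats from at least 2 populations")
    grid = stats[0].grid
    for ws in stats[1:]:
        if ws.grid != grid:
            raise ValueError("window stats must share one grid")
    values = np.vstack([ws.value for ws in stats])
    defined = ~np.isnan(values).any(axis=0)
    min_af = np.min(values, axis=0)
    return defined & (min_af >= tau)


@dataclass
class FixationRegion:
    """Maximal run of adjacent flagged windows."""

    chrom: str
    start: int  # 0-based half-open internally
    end: int
    af_by_pop: dict[str, float]  # mean window AF per population over members
    max_af_by_pop: dict[str, float]
    n_windows: int

    @property
    def min_af(self) -> float:
        return min(self.af_by_pop.values())

    def to_row(self) -> dict:
        row = {
            "chrom": self.chrom,
            "start": self.start + 1,  # 1-based inclusive for reporting
            "end": self.end,
            "n_windows": self.n_windows,
            "min_af": self.min_af,
        }
        for pop, af in self.af_by_pop.items():
            row[f"AF_{pop}"] = af
        for pop, af in self.max_af_by_pop.items():
            row[f"maxAF_{pop}"] = af
        return row


def merge_flagged_windows(
    flags: np.ndarray,
    stats: list[WindowStat],
    pop_ids: list[str] | None = None,
    gap_tolerance: int = 0,
) -> list[FixationRegion]:
    """Merge grid-adjacent flagged windows into FixationRegions.

    Adjacency means consecutive grid starts (difference = step); a
    gap_tolerance of g additionally bridges up to g unflagged windows.
    Region AF per population is the mean over member windows (the max is also
    reported).
    """
    grid = stats[0].grid
    pop_ids = pop_ids or [ws.label or f"pop{i}" for i, ws in enumerate(stats)]
    flag_idx = np.flatnonzero(np.asarray(flags, dtype=bool))
    starts = grid.starts
    regions: list[FixationRegion] = []
    if flag_idx.size == 0:
        return regions
    breaks = np.flatnonzero(np.diff(starts[flag_idx]) > (gap_tolerance + 1) * grid.step)
    for run in np.split(flag_idx, breaks + 1):
        af_by_pop = {}
        max_af_by_pop = {}
        for pid, ws in zip(pop_ids, stats):
            member = ws.value[run]
            af_by_pop[pid] = float(np.nanmean(member))
            max_af_by_pop[pid] = float(np.nanmax(member))
        regions.append(
            FixationRegion(
                chrom=grid.chrom,
                start=int(starts[run[0]]),
                end=int(starts[run[-1]] + grid.window_size),
                af_by_pop=af_by_pop,
                max_af_by_pop=max_af_by_pop,
                n_windows=int(run.size),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def regions_to_frame(regions: list[FixationRegion]) -> pd.DataFrame:
    if not regions:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "min_af"])
    return pd.DataFrame([r.to_row() for r in regions])


def regions_to_bed(regions, path, name_prefix: str = "region") -> None:
    """Write regions as BED6 (0-based half-open, score = 1000*min statistic)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            stat = getattr(r, "min_af", None)
            if stat is None:
                stat = getattr(r, "max_fst", 0.0)
            score = int(round(1000 * min(max(stat, 0.0), 1.0)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name_prefix}{i}\t{score}\t.\n")
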