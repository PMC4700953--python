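"""Windowed Fst divergence scan between two population groups.

Per-site differentiation uses the Weir & Cockerham (1984) two-population,
two-allele estimator built from allele frequencies and haplotype-equivalent
sample sizes, with the within-population heterozygosity term taken as the
Hardy–Weinberg expectation 2p(1-p) — the only form computable for pooled
data, applied to both groups for symmetry. Per-site values feed the 40 kb /
5 kb window frame; windows in the empirical top quantile (default 1%) are
merged into candidate divergence regions, each reported with its maximum
window Fst and minimum empirical percentile P.

Negative per-site estimates (expected under no differentiation) are retained
in window means; clamping, if any, is a display decision left to reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .frequency import FrequencyTrack
from .windows import WindowGrid, WindowStat


def _wc_components(p1, p2, n1, n2):
    """WC84 variance components (a, b, c) for two populations of diploids.

    n1, n2 are haplotype counts; individuals are n/2 and heterozygosity is
    the HWE expectation 2p(1-p).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 haplotypes per group")
    m1, m2 = n1 / 2.0, n2 / 2.0  # diploid individuals
    r = 2
    nbar = (m1 + m2) / r
    nc = (r * nbar - (m1**2 + m2**2) / (r * nbar)) / (r - 1)
    pbar = (m1 * p1 + m2 * p2) / (r * nbar)
    s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (m1 * 2 * p1 * (1 - p1) + m2 * 2 * p2 * (1 - p2)) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst_site(p1, p2, n1, n2):
    """Per-site Weir–Cockerham theta-hat = a / (a + b + c).

    Accepts scalars or aligned arrays. Returns NaN where all variance
    components vanish (both groups fixed for the same allele). Values can be
    slightly negative when the groups do not differ — that is a property of
    the estimator, not an error.
    """
    a, b, c = _wc_components(p1, p2, n1, n2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom == 0, np.nan, a / denom)
    return float(theta) if np.isscalar(p1) and np.ndim(theta) == 0 else theta


def hudson_fst_site(p1, p2, n1, n2):
    """Hudson-style two-population Fst with finite-sample correction.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); returns N/D, NaN where D = 0. Used as an
    independent cross-check of the WC84 route, never in its place.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 haplotypes per group")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den == 0, np.nan, num / den)
    return float(fst) if np.isscalar(p1) and np.ndim(fst) == 0 else fst


def fst_track(
    layer: FrequencyTrack,
    broiler: FrequencyTrack,
    estimator: str = "wc84",
    max_pool_n: float | None = None,
) -> pd.DataFrame:
    """Per-site Fst between two aligned group tracks.

    ``n_obs`` of each track supplies the haplotype-equivalent sample size;
    ``max_pool_n`` caps it (e.g., at 2x the number of pooled individuals) so
    deep pools do not overstate precision. Sites missing in either track, or
    with fewer than 2 observations, are skipped.
    """
    if len(layer) != len(broiler) or not np.array_equal(layer.positions, broiler.positions):
        raise ValueError("tracks are not aligned to a common site frame")
    p1, p2 = layer.freq, broiler.freq
    n1 = layer.n_obs.astype(float)
    n2 = broiler.n_obs.astype(float)
    if max_pool_n is not None:
        n2 = np.minimum(n2, max_pool_n)
    ok = ~np.isnan(p1) & ~np.isnan(p2) & (n1 >= 2) & (n2 >= 2)
    fst = np.full(len(layer), np.nan)
    fn = wc_fst_site if estimator == "wc84" else hudson_fst_site
    if estimator not in ("wc84", "hudson"):
        raise ValueError(f"unknown estimator: {estimator!r}")
    if ok.any():
        fst[ok] = fn(p1[ok], p2[ok], n1[ok], n2[ok])
    return pd.DataFrame(
        {
            "chrom": layer.chrom,
            "pos": layer.positions,
            "fst": fst,
            "p_layer": p1,
            "p_broiler": p2,
            "n_layer": n1,
            "n_broiler": n2,
        }
    )


def genome_wide_fst(p1, p2, n1, n2) -> float:
    """Multi-locus WC84 Fst: ratio of summed variance components over sites.

    This is the estimator's own prescription for combining loci and the
    standard meaning of a "genome-wide" Fst; averaging per-site ratios is
    biased downward.
    """
    a, b, c = _wc_components(p1, p2, n1, n2)
    denom = np.nansum(a + b + c)
    return float(np.nansum(a) / denom)


def expected_heterozygosity(track: FrequencyTrack) -> np.ndarray:
    """Per-site HWE heterozygosity 2p(1-p); NaN where freq is undefined."""
    return 2.0 * track.freq * (1.0 - track.freq)


def empirical_p(values: np.ndarray, obs) -> np.ndarray | float:
    """Self-inclusive upper-tail empirical percentile.

    P(obs) = #{defined values >= obs} / #{defined values}; the minimum over
    observed windows is 1/N and P is monotone non-increasing in obs.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined values")
    sorted_vals = np.sort(vals)
    obs_arr = np.asarray(obs, dtype=float)
    n_ge = vals.size - np.searchsorted(sorted_vals, obs_arr, side="left")
    p = n_ge / vals.size
    return float(p) if np.ndim(obs) == 0 else p


def top_quantile_threshold(values: np.ndarray, q: float = 0.99) -> float:
    """Nearest-rank threshold whose inclusive flag set {v >= t} has the
    target size ceil((1-q)·N) (ties at the threshold enlarge the set)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined values")
    # small guard keeps ceil exact when (1-q)*N is an integer up to float error
    k = max(1, ceil((1.0 - q) * vals.size - 1e-9))
    k = min(k, vals.size)
    return float(np.partition(vals, vals.size - k)[vals.size - k])


@dataclass
class DivergenceRegion:
    """Maximal run of adjacent windows above the scan threshold."""

    chrom: str
    start: int  # 0-based half-open internally
    end: int
    max_fst: float
    min_p: float
    n_windows: int

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start + 1,  # 1-based inclusive for reporting
            "end": self.end,
            "max_fst": self.max_fst,
            "p": self.min_p,
            "n_windows": self.n_windows,
        }


def _runs(flag_idx: np.ndarray, step: int, starts: np.ndarray, gap_tolerance: int = 0):
    """Split flagged window indices into maximal grid-adjacent runs."""
    if flag_idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(starts[flag_idx]) > (gap_tolerance + 1) * step)
    return np.split(flag_idx, breaks + 1)


def cluster_divergent_windows(
    ws: WindowStat,
    threshold: float,
    gap_tolerance: int = 0,
    p_reference: np.ndarray | None = None,
) -> list[DivergenceRegion]:
    """Merge adjacent windows with mean Fst >= threshold into regions.

    Each region carries the max member-window Fst and the min member-window
    empirical P. P is computed against ``p_reference`` (e.g., the genome-wide
    window distribution) when given, else against this chromosome's windows.
    """
    value = ws.value
    reference = value if p_reference is None else np.asarray(p_reference, dtype=float)
    defined = ~np.isnan(value)
    flagged = np.flatnonzero(defined & (value >= threshold))
    starts = ws.grid.starts
    regions = []
    for run in _runs(flagged, ws.grid.step, starts, gap_tolerance):
        vals = value[run]
        regions.append(
            DivergenceRegion(
                chrom=ws.grid.chrom,
                start=int(starts[run[0]]),
                end=int(starts[run[-1]] + ws.grid.window_size),
                max_fst=float(np.max(vals)),
                min_p=float(np.min(empirical_p(reference, vals))),
                n_windows=int(run.size),
            )
        )
    return regions


def regions_to_frame(regions: list[DivergenceRegion]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "max_fst", "p", "n_windows"]
    return pd.DataFrame([r.to_row() for r in regions], columns=cols)


CHICKEN_MACRO = {str(c) for c in range(1, 6)}
CHICKEN_INTERMEDIATE = {str(c) for c in range(6, 11)}


def classify_chicken_chrom(chrom: str) -> str:
    """Default chicken karyotype classes: GGA1-5 macro, GGA6-10 intermediate
    (excluded from the micro/macro contrast), GGA11+ micro, others 'other'."""
    name = chrom.removeprefix("chr").removeprefix("GGA")
    if name in CHICKEN_MACRO:
        return "macro"
    if name in CHICKEN_INTERMEDIATE:
        return "intermediate"
    if name.isdigit():
        return "micro"
    return "other"


def stratified_mean_fst(
    stats: dict[str, WindowStat], chrom_classes: dict[str, str] | None = None
) -> dict[str, float]:
    """Mean of defined window values per chromosome class (NaN if class empty)."""
    out: dict[str, list[np.ndarray]] = {}
    for chrom, ws in stats.items():
        cls = (
            chrom_classes[chrom] if chrom_classes is not None else classify_chicken_chrom(chrom)
        )
        out.setdefault(cls, []).append(ws.value[~np.isnan(ws.value)])
    means = {}
    for cls, chunks in out.items():
        vals = np.concatenate(chunks) if chunks else np.array([])
        means[cls] = float(vals.mean()) if vals.size else float("nan")
    return means
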