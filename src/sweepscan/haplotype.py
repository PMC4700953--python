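"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at distance x from a core site, within the chromosomes carrying a given
core allele, is the probability that two randomly drawn carriers are
identical at every site between the core and x. iHS compares the area under
the EHH curve (trapezoidal integral over physical distance, both directions)
between ancestral- and derived-allele carriers:

    iHS_raw = ln(iHH_ancestral / iHH_derived)

and is standardized to mean 0 / SD 1 within derived-allele-frequency bins,
so that extreme values mark unusually long haplotypes given the allele's
frequency. Strongly negative raw scores indicate long derived haplotypes —
the signature of an incomplete sweep.

Curves are truncated where EHH drops below a cutoff (default 0.05); a core
site whose curve reaches the chromosome edge, or crosses an inter-site gap
larger than ``max_gap``, before truncating is reported as missing, since its
integral would be censored. Physical distance stands in for genetic distance
throughout (an optional position → cM map may be supplied).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .windows import WindowGrid, WindowStat, window_mean

logger = logging.getLogger(__name__)

DEFAULT_TRUNCATION = 0.05
DEFAULT_MAF_MIN = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_N_BINS = 20

ANCESTRAL, DERIVED = 0, 1


@dataclass
class EHHCurve:
    """One-directional EHH decay from a core site for one allele class."""

    core_index: int
    allele: int
    direction: str  # "upstream" (left) or "downstream" (right)
    positions: np.ndarray  # absolute bp, starting at the core
    ehh: np.ndarray  # values in [0, 1], ehh[0] == 1
    truncated: bool  # True if the curve dropped below the cutoff before edge/gap

    def offsets(self) -> np.ndarray:
        return np.abs(self.positions - self.positions[0])


def _pair_homozygosity(counts: np.ndarray, n: int) -> float:
    """Fraction of unordered carrier pairs falling in the same identity class."""
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def _ehh_one_direction(
    hap: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    truncation: float,
    max_gap: int | None,
) -> tuple[list[int], list[float], bool, bool]:
    """Walk outward from the core refining the carrier identity partition.

    Returns (site indices, ehh values, truncated, gap_hit); the walk stops at
    the first value below ``truncation``, at the chromosome edge, or at a gap
    wider than ``max_gap``.
    """
    n = hap.shape[0]
    codes = np.zeros(n, dtype=np.int64)  # all carriers identical at the core
    idx = [core]
    ehh = [1.0]
    j = core
    truncated = False
    gap_hit = False
    while True:
        j_next = j + step
        if j_next < 0 or j_next >= positions.size:
            break
        if max_gap is not None and abs(int(positions[j_next]) - int(positions[j])) > max_gap:
            gap_hit = True
            break
        col = hap[:, j_next].astype(np.int64)
        _, codes = np.unique(codes * 2 + col, return_inverse=True)
        counts = np.bincount(codes)
        value = _pair_homozygosity(counts, n)
        idx.append(j_next)
        ehh.append(value)
        j = j_next
        if value < truncation:
            truncated = True
            break
        if value == 0.0:
            truncated = True
            break
    return idx, ehh, truncated, gap_hit


def ehh(
    panel: HaplotypePanel,
    core: int,
    allele: int,
    truncation: float = DEFAULT_TRUNCATION,
    max_gap: int | None = DEFAULT_MAX_GAP,
) -> tuple[EHHCurve, EHHCurve]:
    """EHH decay curves (upstream, downstream) for one core allele class.

    Requires at least 2 carriers of ``allele`` at the core site.
    """
    carriers = np.flatnonzero(panel.haplotypes[:, core] == allele)
    if carriers.size < 2:
        raise ValueError("EHH needs at least 2 carriers of the core allele")
    hap = panel.haplotypes[carriers]
    curves = []
    for direction, step in (("upstream", -1), ("downstream", +1)):
        idx, vals, truncated, _ = _ehh_one_direction(
            hap, panel.positions, core, step, truncation, max_gap
        )
        curves.append(
            EHHCurve(
                core_index=core,
                allele=allele,
                direction=direction,
                positions=panel.positions[np.asarray(idx)],
                ehh=np.asarray(vals),
                truncated=truncated,
            )
        )
    return curves[0], curves[1]


def _ihh_one_allele(
    hap_all: np.ndarray,
    positions: np.ndarray,
    core: int,
    allele: int,
    truncation: float,
    max_gap: int | None,
) -> float:
    """Integrated EHH (bp) for one allele class; NaN if censored at edge/gap."""
    carriers = np.flatnonzero(hap_all[:, core] == allele)
    if carriers.size < 2:
        return np.nan
    hap = hap_all[carriers]
    total = 0.0
    for step in (-1, +1):
        idx, vals, truncated, gap_hit = _ehh_one_direction(
            hap, positions, core, step, truncation, max_gap
        )
        if not truncated:  # curve censored by chromosome edge or a gap stop
            return np.nan
        x = np.abs(positions[np.asarray(idx)].astype(float) - float(positions[core]))
        total += float(np.trapezoid(np.asarray(vals), x))
    return total


def ihs(
    panel: HaplotypePanel,
    maf_min: float = DEFAULT_MAF_MIN,
    truncation: float = DEFAULT_TRUNCATION,
    max_gap: int | None = DEFAULT_MAX_GAP,
    pop: str | None = None,
) -> pd.DataFrame:
    """Unstandardized iHS per qualifying core site.

    Cores with derived-allele frequency (and its complement) below ``maf_min``
    are skipped; cores whose EHH curve is censored before truncation, or with
    fewer than 2 carriers of either allele, are reported missing. Columns:
    pos (0-based), daf, ihh_a, ihh_d, ihs_raw.
    """
    sub = panel if pop is None else panel.subset_pops([pop])
    hap = sub.haplotypes
    positions = sub.positions
    daf = hap.mean(axis=0)
    rows = []
    for core in range(positions.size):
        d = daf[core]
        if min(d, 1 - d) < maf_min:
            continue
        ihh_a = _ihh_one_allele(hap, positions, core, ANCESTRAL, truncation, max_gap)
        ihh_d = _ihh_one_allele(hap, positions, core, DERIVED, truncation, max_gap)
        if np.isnan(ihh_a) or np.isnan(ihh_d) or ihh_a <= 0 or ihh_d <= 0:
            raw = np.nan
        else:
            raw = float(np.log(ihh_a / ihh_d))
        rows.append((int(positions[core]), float(d), ihh_a, ihh_d, raw))
    return pd.DataFrame(rows, columns=["pos", "daf", "ihh_a", "ihh_d", "ihs_raw"])


def standardize_ihs(sites: pd.DataFrame, n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Standardize raw scores to mean 0 / SD 1 within equal-width DAF bins.

    Bins with fewer than 2 defined raw scores, or zero spread, leave their
    members missing (the latter with a warning). Adds an ``ihs_std`` column.
    """
    out = sites.copy()
    out["ihs_std"] = np.nan
    defined = ~out["ihs_raw"].isna()
    if not defined.any():
        return out
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(out["daf"].to_numpy(), edges) - 1, 0, n_bins - 1)
    for b in np.unique(bin_idx[defined]):
        in_bin = defined.to_numpy() & (bin_idx == b)
        raw = out.loc[in_bin, "ihs_raw"].to_numpy()
        if raw.size < 2:
            continue
        sd = raw.std(ddof=0)
        if sd == 0:
            warnings.warn(
                f"iHS bin {b}: zero spread among {raw.size} scores; left unstandardized",
                stacklevel=2,
            )
            continue
        out.loc[in_bin, "ihs_std"] = (raw - raw.mean()) / sd
    return out


def windowed_abs_ihs(sites: pd.DataFrame, grid: WindowGrid, min_snps: int = 5) -> WindowStat:
    """Window mean of |standardized iHS| (the haplotype track of the scan)."""
    pos = sites["pos"].to_numpy()
    vals = np.abs(sites["ihs_std"].to_numpy(dtype=float))
    order = np.argsort(pos, kind="stable")
    return window_mean(pos[order], vals[order], grid, min_snps=min_snps, label="abs_ihs")
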