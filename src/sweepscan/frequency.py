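"""Per-site alternate-allele frequency tracks.

All populations are expressed on the same alternate-allele orientation
(relative to the reference genome), so that "elevated frequency" always
refers to the same physical allele across populations — the premise of the
parallel-fixation screen. Group tracks (e.g., the mean of three broiler
pools) use a strict completeness rule: a site missing in any member
population is missing in the group track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, PoolCountTable


@dataclass
class FrequencyTrack:
    """Alternate-allele frequency per site for one population or group.

    freq is NaN where undefined (all genotypes missing, or pool masked);
    n_obs counts the contributing observations (haplotypes for genotype data,
    reads for pool data) and is 0 where freq is undefined.
    """

    chrom: np.ndarray
    positions: np.ndarray
    freq: np.ndarray
    n_obs: np.ndarray
    pop_id: str

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.freq) == len(self.n_obs) == len(self.chrom) == n):
            raise ValueError("track arrays must have equal length")
        defined = ~np.isnan(self.freq)
        f = self.freq[defined]
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if defined.any() and np.min(self.n_obs[defined]) < 1:
            raise ValueError("defined frequencies need n_obs >= 1")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions + 1,  # 1-based for export
                "freq": self.freq,
                "n_obs": self.n_obs,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def genotype_freq(gm: GenotypeMatrix, pop: list[str] | None = None, pop_id: str = "") -> FrequencyTrack:
    """Alternate-allele frequency from diploid dosages for a sample subset.

    freq = (sum of dosages) / (2 × non-missing samples); a site where every
    selected sample is missing gets a missing frequency.
    """
    samples = list(gm.samples) if pop is None else list(pop)
    idx = []
    for s in samples:
        try:
            idx.append(gm.samples.index(s))
        except ValueError:
            raise KeyError(f"unknown sample id: {s!r}") from None
    if not idx:
        raise ValueError("empty sample subset")
    d = gm.dosage[:, idx]
    n_called = np.sum(~np.isnan(d), axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=1) / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    return FrequencyTrack(
        chrom=gm.sites["chrom"].to_numpy(),
        positions=gm.sites["pos"].to_numpy(),
        freq=freq,
        n_obs=2 * n_called,
        pop_id=pop_id or ",".join(samples[:3]),
    )


def pool_freq(pc: PoolCountTable, pool: str) -> FrequencyTrack:
    """Alternate-allele frequency from pooled read counts for one pool."""
    try:
        j = pc.pools.index(pool)
    except ValueError:
        raise KeyError(f"unknown pool id: {pool!r}") from None
    rc = pc.ref_count[:, j].astype(float)
    ac = pc.alt_count[:, j].astype(float)
    total = rc + ac
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = ac / total
    freq[pc.masked[:, j] | (total == 0)] = np.nan
    n_obs = total.astype(np.int64)
    n_obs[np.isnan(freq)] = 0
    return FrequencyTrack(
        chrom=pc.sites["chrom"].to_numpy(),
        positions=pc.sites["pos"].to_numpy(),
        freq=freq,
        n_obs=n_obs,
        pop_id=pool,
    )


def group_mean_freq(tracks: list[FrequencyTrack], pop_id: str = "group") -> FrequencyTrack:
    """Unweighted mean frequency across aligned tracks.

    All tracks must share one site frame. A site missing in any member track
    is missing in the group track; n_obs sums the members' contributions.
    """
    if not tracks:
        raise ValueError("need at least one track")
    ref = tracks[0]
    for t in tracks[1:]:
        if len(t) != len(ref) or not np.array_equal(t.positions, ref.positions):
            raise ValueError("tracks are not aligned to a common site frame")
    freqs = np.vstack([t.freq for t in tracks])
    n_obs = np.vstack([t.n_obs for t in tracks])
    any_missing = np.isnan(freqs).any(axis=0)
    mean = freqs.mean(axis=0)
    mean[any_missing] = np.nan
    total_obs = n_obs.sum(axis=0)
    total_obs[any_missing] = 0
    return FrequencyTrack(
        chrom=ref.chrom,
        positions=ref.positions,
        freq=mean,
        n_obs=total_obs,
        pop_id=pop_id,
    )
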