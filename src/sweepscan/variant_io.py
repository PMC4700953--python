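"""Variant ingestion and site-level filtering.

Reads multi-sample VCFs (individually genotyped populations) and per-site
allele-count tables (pool-sequenced populations), applies the site filters
used throughout the scans — minimum Phred site quality and a read-depth band
of mean ± sigma·SD — and aligns tables from different sources onto a common
site frame with a single ref/alt orientation.

Coordinates are 1-based in all input and output files and 0-based half-open
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]
_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class FilterConfig:
    """Site-filter thresholds.

    min_qual: minimum Phred-scaled site quality (20 ≙ 99% call accuracy).
    depth_sigma: half-width of the accepted total-depth band in SDs of the
        dataset's depth distribution; None disables the depth filter.
    min_pool_depth: pooled sites with fewer reads than this in a pool have an
        undefined frequency there (masked, not dropped).
    """

    min_qual: float = 20.0
    depth_sigma: float | None = 2.0
    min_pool_depth: int = 4

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_pool_depth < 0:
            raise ValueError("thresholds must be non-negative")
        if self.depth_sigma is not None and self.depth_sigma < 0:
            raise ValueError("depth_sigma must be non-negative or None")


@dataclass
class GenotypeMatrix:
    """Filtered biallelic-SNP sites with per-sample diploid dosages.

    sites: DataFrame with columns chrom, pos (0-based), ref, alt, qual, depth.
    dosage: (n_sites, n_samples) float array of alternate-allele dosages in
    {0, 1, 2}, NaN where the genotype is missing.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    phased: bool = False

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage shape inconsistent with sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.iloc[rows].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[rows],
            phased=self.phased,
        )

    def flip(self, rows: np.ndarray) -> None:
        """Swap ref/alt orientation in place at the given row indices."""
        self.dosage[rows] = 2.0 - self.dosage[rows]
        cols = self.sites.columns.get_indexer(["ref", "alt"])
        vals = self.sites.iloc[rows, cols].to_numpy()
        self.sites.iloc[rows, cols] = vals[:, ::-1]


@dataclass
class PoolCountTable:
    """Per-site ref/alt read counts for one or more sequencing pools.

    masked[i, j] is True where pool j has fewer than min_pool_depth reads at
    site i: the frequency is undefined there but the site stays in the frame.
    """

    sites: pd.DataFrame
    pools: list[str]
    ref_count: np.ndarray
    alt_count: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sites), len(self.pools))
        for arr in (self.ref_count, self.alt_count, self.masked):
            if arr.shape != shape:
                raise ValueError("count array shape inconsistent with sites/pools")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take(self, rows: np.ndarray) -> "PoolCountTable":
        return PoolCountTable(
            sites=self.sites.iloc[rows].reset_index(drop=True),
            pools=list(self.pools),
            ref_count=self.ref_count[rows],
            alt_count=self.alt_count[rows],
            masked=self.masked[rows],
        )

    def flip(self, rows: np.ndarray) -> None:
        rc = self.ref_count[rows].copy()
        self.ref_count[rows] = self.alt_count[rows]
        self.alt_count[rows] = rc
        cols = self.sites.columns.get_indexer(["ref", "alt"])
        vals = self.sites.iloc[rows, cols].to_numpy()
        self.sites.iloc[rows, cols] = vals[:, ::-1]


class VcfParseError(ValueError):
    pass


def depth_band_mask(depths: np.ndarray, sigma: float) -> np.ndarray:
    """Boolean keep-mask for depths within mean ± sigma·SD of the input set.

    Mean and SD (population SD, ddof=0) are computed once over the full input
    in a single pass; the band is inclusive at both edges. With sigma=0 only
    depths exactly at the mean survive; with all depths equal the band
    degenerates to that single value and everything survives.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 2:
        raise ValueError("depth filter needs at least 2 sites to estimate mean/SD")
    mean = depths.mean()
    sd = depths.std(ddof=0)
    return (depths >= mean - sigma * sd) & (depths <= mean + sigma * sd)


def apply_depth_filter(sites: pd.DataFrame, sigma: float) -> pd.DataFrame:
    """Retain sites whose total depth lies within mean ± sigma·SD.

    ``sites`` must carry a ``depth`` column; the band is estimated from the
    input set itself (no iteration).
    """
    keep = depth_band_mask(sites["depth"].to_numpy(), sigma)
    return sites[keep].reset_index(drop=True)


def read_vcf(path, filter: FilterConfig | None = None) -> GenotypeMatrix:
    """Read a multi-sample diploid VCF into a filtered GenotypeMatrix.

    Retains biallelic SNPs with QUAL ≥ min_qual and total depth inside the
    dataset-wide mean ± depth_sigma·SD band. Multi-allelic records, indels,
    and low-quality sites are dropped and counted; the drop summary is logged.
    """
    from cyvcf2 import VCF

    filt = filter or FilterConfig()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    depths: list[float] = []
    dosage_rows: list[np.ndarray] = []
    drops = {"non_snp_or_multiallelic": 0, "low_qual": 0, "depth_band": 0}
    phased = False

    for v in vcf:
        if (not v.is_snp) or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            drops["non_snp_or_multiallelic"] += 1
            continue
        qual = v.QUAL if v.QUAL is not None else 0.0
        if qual < filt.min_qual:
            drops["low_qual"] += 1
            continue
        gts = v.genotypes  # [[a1, a2, phased], ...]
        row = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            a1, a2 = gt[0], gt[1]
            if a1 >= 0 and a2 >= 0:
                row[i] = a1 + a2
            if gt[-1]:
                phased = True
        try:
            depth = v.INFO.get("DP")
        except KeyError:  # DP absent from the header
            depth = None
        if depth is None:
            try:
                fmt_dp = v.format("DP")
            except KeyError:
                fmt_dp = None
            depth = float(np.nansum(fmt_dp)) if fmt_dp is not None else np.nan
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(float(qual))
        depths.append(float(depth))
        dosage_rows.append(row)

    sites = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "qual": quals,
            "depth": depths,
        }
    )
    dosage = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(samples)))
    )

    if filt.depth_sigma is not None and len(sites) >= 2:
        keep = depth_band_mask(sites["depth"].to_numpy(), filt.depth_sigma)
        drops["depth_band"] = int((~keep).sum())
        sites = sites[keep].reset_index(drop=True)
        dosage = dosage[keep]

    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosage = dosage[order]

    logger.info(
        "read_vcf %s: retained %d sites (dropped: %s)",
        path,
        len(sites),
        ", ".join(f"{k}={n}" for k, n in drops.items()),
    )
    if len(sites) == 0:
        logger.warning("read_vcf %s: no sites retained after filtering", path)
    gm = GenotypeMatrix(sites=sites, samples=samples, dosage=dosage, phased=phased)
    gm.drop_counts = drops  # type: ignore[attr-defined]
    return gm


def read_pool_counts(path, filter: FilterConfig | None = None) -> PoolCountTable:
    """Read a tab-separated pool allele-count table.

    Expected header: ``chrom  pos  ref  alt  <pool>_ref  <pool>_alt ...`` with
    one ref/alt count pair per pool and 1-based positions. Pools with total
    depth below min_pool_depth at a site are masked at that site.
    """
    filt = filter or FilterConfig()
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = SITE_COLUMNS
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"pool-count table must start with columns {required}, got {list(df.columns[:4])}"
        )
    count_cols = list(df.columns[4:])
    if len(count_cols) == 0 or len(count_cols) % 2 != 0:
        raise ValueError("pool-count table needs one <pool>_ref/<pool>_alt column pair per pool")
    pools = []
    for i in range(0, len(count_cols), 2):
        rc, ac = count_cols[i], count_cols[i + 1]
        if not (rc.endswith("_ref") and ac.endswith("_alt") and rc[:-4] == ac[:-4]):
            raise ValueError(f"malformed pool column pair: {rc!r}, {ac!r}")
        pools.append(rc[:-4])
    counts = df[count_cols]
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric read count in {path}: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read count")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(f"duplicated site {first['chrom']}:{first['pos']}")

    sites = df[required].copy()
    sites["pos"] = sites["pos"].astype(np.int64) - 1  # to 0-based
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    ref_count = counts.iloc[order, 0::2].to_numpy()
    alt_count = counts.iloc[order, 1::2].to_numpy()
    masked = (ref_count + alt_count) < filt.min_pool_depth
    if masked.any():
        logger.info(
            "read_pool_counts %s: masked %d site/pool cells below depth %d",
            path,
            int(masked.sum()),
            filt.min_pool_depth,
        )
    return PoolCountTable(
        sites=sites, pools=pools, ref_count=ref_count, alt_count=alt_count, masked=masked
    )


def _site_key_frame(table) -> pd.DataFrame:
    df = table.sites[SITE_COLUMNS].copy()
    df["row"] = np.arange(len(df))
    return df


def intersect_sites(tables: list) -> list:
    """Restrict GenotypeMatrix/PoolCountTable inputs to their common sites.

    Sites are matched on (chrom, pos). Tables whose ref/alt orientation is
    swapped relative to the first table are flipped (dosages complemented,
    counts exchanged) and the flips are logged; sites whose alleles cannot be
    reconciled are dropped from all outputs and counted. Output tables share
    one (chrom, pos)-sorted site order.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to intersect")
    keys = [_site_key_frame(t) for t in tables]
    merged = keys[0].rename(columns={"row": "row0", "ref": "ref0", "alt": "alt0"})
    for i, k in enumerate(keys[1:], start=1):
        merged = merged.merge(
            k.rename(columns={"row": f"row{i}", "ref": f"ref{i}", "alt": f"alt{i}"}),
            on=["chrom", "pos"],
            how="inner",
        )
    merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)

    ref0 = merged["ref0"].to_numpy()
    alt0 = merged["alt0"].to_numpy()
    keep = np.ones(len(merged), dtype=bool)
    flips: list[np.ndarray] = [np.zeros(len(merged), dtype=bool)]
    for i in range(1, len(tables)):
        ref_i = merged[f"ref{i}"].to_numpy()
        alt_i = merged[f"alt{i}"].to_numpy()
        same = (ref_i == ref0) & (alt_i == alt0)
        swapped = (ref_i == alt0) & (alt_i == ref0)
        keep &= same | swapped
        flips.append(swapped)

    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("intersect_sites: dropped %d sites with irreconcilable alleles", n_dropped)

    out = []
    for i, table in enumerate(tables):
        rows = merged.loc[keep, f"row{i}"].to_numpy()
        sub = table.take(rows)
        flip_rows = np.flatnonzero(flips[i][keep])
        if flip_rows.size:
            sub.flip(flip_rows)
            logger.info(
                "intersect_sites: flipped ref/alt orientation at %d sites of table %d",
                flip_rows.size,
                i,
            )
        out.append(sub)
    return out


def read_chrom_lengths(path) -> dict[str, int]:
    """Two-column TSV (chromosome name, length in bp) → dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_site_table(table, path) -> None:
    """Export the filtered site frame as TSV with 1-based positions."""
    df = table.sites.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False)
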