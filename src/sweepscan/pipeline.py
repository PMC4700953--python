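"""End-to-end scan orchestration: inputs → tracks → windows → regions.

Both screens share the same plumbing: read and filter the layer VCF and the
pool-count table, intersect their site frames onto one ref/alt orientation,
build per-population (or per-group) frequency tracks, average them on the
40 kb / 5 kb window grid per chromosome, and reduce flagged windows to
candidate regions. Every run can echo its resolved configuration and
per-stage counts next to its outputs so a run is reproducible from its
metadata alone.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import fixation, fst
from .config import RunConfig
from .frequency import FrequencyTrack, genotype_freq, group_mean_freq, pool_freq
from .variant_io import (
    FilterConfig,
    GenotypeMatrix,
    PoolCountTable,
    intersect_sites,
    read_pool_counts,
    read_vcf,
)
from .windows import WindowStat, make_window_grid, window_mean

logger = logging.getLogger(__name__)


def pops_from_prefixes(samples: list[str]) -> dict[str, list[str]]:
    """Group sample names into populations by their prefix before the last '_'.

    ``WL_01 … WL_25, BL_01 …`` → {"WL": [...], "BL": [...]}.
    """
    pops: dict[str, list[str]] = {}
    for s in samples:
        prefix = s.rsplit("_", 1)[0] if "_" in s else s
        pops.setdefault(prefix, []).append(s)
    return pops


def filter_config(cfg: RunConfig) -> FilterConfig:
    return FilterConfig(
        min_qual=cfg.min_qual,
        depth_sigma=cfg.depth_sigma,
        min_pool_depth=cfg.min_pool_depth,
    )


def _chrom_grids(positions_by_chrom, chrom_lengths, cfg: RunConfig):
    grids = {}
    for chrom, pos in positions_by_chrom.items():
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(pos.max()) + 1
        )
        grids[chrom] = make_window_grid(length, cfg.window_size, cfg.step, chrom=chrom)
    return grids


def _split_by_chrom(track: FrequencyTrack):
    out = {}
    chroms = np.asarray(track.chrom)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        out[str(chrom)] = (track.positions[sel], track.freq[sel])
    return out


def window_tracks(
    tracks: list[FrequencyTrack], chrom_lengths, cfg: RunConfig
) -> dict[str, list[WindowStat]]:
    """Per-chromosome window means for each track, on one shared grid."""
    by_chrom = [_split_by_chrom(t) for t in tracks]
    chrom_pos = {c: pos for split in by_chrom for c, (pos, _) in split.items()}
    grids = _chrom_grids(chrom_pos, chrom_lengths, cfg)
    out: dict[str, list[WindowStat]] = {}
    for chrom, grid in grids.items():
        stats = []
        for t, split in zip(tracks, by_chrom):
            pos, vals = split.get(chrom, (np.array([], dtype=np.int64), np.array([])))
            stats.append(
                window_mean(pos, vals, grid, min_snps=cfg.min_snps_per_window, label=t.pop_id)
            )
        out[chrom] = stats
    return out


@dataclass
class ScanInputs:
    genotypes: GenotypeMatrix
    pools: PoolCountTable
    layer_pops: dict[str, list[str]]


def load_inputs(layer_vcf, pools_path, cfg: RunConfig) -> ScanInputs:
    filt = filter_config(cfg)
    gm = read_vcf(layer_vcf, filt)
    pc = read_pool_counts(pools_path, filt)
    if gm.n_sites == 0 or pc.n_sites == 0:
        raise ValueError("no sites retained in one of the inputs")
    gm, pc = intersect_sites([gm, pc])
    if gm.n_sites == 0:
        raise ValueError("empty common site set between layer VCF and pool table")
    pops = pops_from_prefixes(gm.samples)
    if len(pops) < 2:
        raise ValueError("need at least 2 layer populations (sample-name prefixes)")
    return ScanInputs(genotypes=gm, pools=pc, layer_pops=pops)


def run_fixation_scan(
    layer_vcf,
    pools_path,
    cfg: RunConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
    out_dir=None,
):
    """Parallel-fixation screen: per-layer tracks + pooled-broiler mean track,
    windowed, flagged at tau in all populations, merged into regions.

    Returns (regions, window stats by chromosome, population ids).
    """
    cfg = cfg or RunConfig()
    inputs = load_inputs(layer_vcf, pools_path, cfg)
    tracks = [
        genotype_freq(inputs.genotypes, samples, pop_id=pop)
        for pop, samples in inputs.layer_pops.items()
    ]
    pool_tracks = [pool_freq(inputs.pools, p) for p in inputs.pools.pools]
    tracks.append(group_mean_freq(pool_tracks, pop_id="BR"))
    pop_ids = [t.pop_id for t in tracks]

    stats_by_chrom = window_tracks(tracks, chrom_lengths, cfg)
    regions = []
    n_flagged = 0
    for chrom, stats in sorted(stats_by_chrom.items()):
        flags = fixation.flag_fixation_windows(stats, tau=cfg.fixation_tau)
        n_flagged += int(flags.sum())
        regions.extend(
            fixation.merge_flagged_windows(
                flags, stats, pop_ids=pop_ids, gap_tolerance=cfg.gap_tolerance
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    logger.info(
        "fixation scan: %d windows flagged at tau=%.2f in %d populations; %d regions",
        n_flagged,
        cfg.fixation_tau,
        len(pop_ids),
        len(regions),
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        fixation.regions_to_frame(regions).to_csv(
            os.path.join(out_dir, "fixation_regions.tsv"),
            sep="\t",
            index=False,
            float_format="%.4f",
        )
        fixation.regions_to_bed(regions, os.path.join(out_dir, "fixation_regions.bed"))
        _write_metadata(out_dir, cfg, {"flagged_windows": n_flagged, "regions": len(regions)})
    return regions, stats_by_chrom, pop_ids


def run_fst_scan(
    layer_vcf,
    pools_path,
    cfg: RunConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
    out_dir=None,
):
    """Divergence screen between the layer group and the broiler group.

    Builds the two group frequency tracks, computes per-site Fst, windows it,
    thresholds at the empirical top quantile genome-wide, and merges flagged
    windows into divergence regions with empirical percentiles. Returns a
    dict with regions, threshold, window stats, per-site table, and summary
    statistics.
    """
    cfg = cfg or RunConfig()
    inputs = load_inputs(layer_vcf, pools_path, cfg)

    if cfg.layer_group_mode == "pooled":
        layer_track = genotype_freq(inputs.genotypes, pop_id="L")
    else:
        layer_tracks = [
            genotype_freq(inputs.genotypes, samples, pop_id=pop)
            for pop, samples in inputs.layer_pops.items()
        ]
        layer_track = group_mean_freq(layer_tracks, pop_id="L")
    pool_tracks = [pool_freq(inputs.pools, p) for p in inputs.pools.pools]
    broiler_track = group_mean_freq(pool_tracks, pop_id="BR")

    site_fst = fst.fst_track(
        layer_track, broiler_track, estimator=cfg.estimator, max_pool_n=cfg.max_pool_n
    )

    # window the per-site Fst and the two groups' expected heterozygosity
    chroms = np.asarray(site_fst["chrom"])
    chrom_pos = {
        str(c): site_fst["pos"].to_numpy()[chroms == c] for c in pd.unique(chroms)
    }
    grids = _chrom_grids(chrom_pos, chrom_lengths, cfg)
    fst_windows: dict[str, WindowStat] = {}
    het_windows: dict[str, dict[str, WindowStat]] = {"layer": {}, "broiler": {}}
    het_layer = fst.expected_heterozygosity(layer_track)
    het_broiler = fst.expected_heterozygosity(broiler_track)
    fst_vals = site_fst["fst"].to_numpy()
    for chrom, grid in grids.items():
        sel = chroms == chrom
        pos = site_fst["pos"].to_numpy()[sel]
        fst_windows[chrom] = window_mean(
            pos, fst_vals[sel], grid, min_snps=cfg.min_snps_per_window, label="fst"
        )
        het_windows["layer"][chrom] = window_mean(
            pos, het_layer[sel], grid, min_snps=cfg.min_snps_per_window, label="het_L"
        )
        het_windows["broiler"][chrom] = window_mean(
            pos, het_broiler[sel], grid, min_snps=cfg.min_snps_per_window, label="het_BR"
        )

    all_window_values = np.concatenate([ws.value for ws in fst_windows.values()])
    defined = all_window_values[~np.isnan(all_window_values)]
    if defined.size == 0:
        raise ValueError("no defined Fst windows; inputs too sparse for the grid")
    threshold = fst.top_quantile_threshold(all_window_values, q=cfg.fst_quantile)

    regions = []
    for chrom in sorted(fst_windows):
        regions.extend(
            fst.cluster_divergent_windows(
                fst_windows[chrom],
                threshold,
                gap_tolerance=cfg.gap_tolerance,
                p_reference=all_window_values,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))

    ok = ~np.isnan(fst_vals)
    gw_fst = fst.genome_wide_fst(
        site_fst["p_layer"].to_numpy()[ok],
        site_fst["p_broiler"].to_numpy()[ok],
        site_fst["n_layer"].to_numpy()[ok],
        site_fst["n_broiler"].to_numpy()[ok],
    )
    summary = {
        "n_sites": int(len(site_fst)),
        "n_windows_defined": int(defined.size),
        "threshold": float(threshold),
        "n_regions": len(regions),
        "genome_wide_fst": gw_fst,
        "mean_window_fst": float(defined.mean()),
        "stratified_mean_fst": fst.stratified_mean_fst(
            fst_windows, cfg.chromosome_class_map or None
        ),
    }
    logger.info(
        "fst scan: %d windows, top-%.0f%% threshold %.4f, %d regions, genome-wide Fst %.4f",
        defined.size,
        100 * (1 - cfg.fst_quantile),
        threshold,
        len(regions),
        gw_fst,
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        fst.regions_to_frame(regions).to_csv(
            os.path.join(out_dir, "divergence_regions.tsv"),
            sep="\t",
            index=False,
            float_format="%.5g",
        )
        fixation.regions_to_bed(
            regions, os.path.join(out_dir, "divergence_regions.bed"), name_prefix="div"
        )
        for chrom, ws in fst_windows.items():
            ws.to_bedgraph(os.path.join(out_dir, f"fst_windows.{chrom}.bedgraph"), name="Fst")
        for group in ("layer", "broiler"):
            for chrom, ws in het_windows[group].items():
                ws.to_bedgraph(
                    os.path.join(out_dir, f"het_{group}.{chrom}.bedgraph"), name=f"Het {group}"
                )
        _write_metadata(out_dir, cfg, summary)
    return {
        "regions": regions,
        "threshold": threshold,
        "fst_windows": fst_windows,
        "het_windows": het_windows,
        "site_fst": site_fst,
        "summary": summary,
    }


def _write_metadata(out_dir, cfg: RunConfig, counts: dict) -> None:
    meta = {"config": asdict(cfg), "counts": counts}
    with open(os.path.join(out_dir, "run_metadata.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
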