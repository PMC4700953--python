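"""Synthetic data generator: neutral differentiation plus implanted sweeps.

Emulates the study design the scans were built for — two individually
genotyped layer populations (25 diploid hens each) and three pool-sequenced
broiler populations — on a single synthetic chromosome with ~107 bp mean SNP
spacing. Neutral differentiation between populations follows the
Balding–Nichols model: each population's allele frequency at a site is a Beta
draw around a shared ancestral frequency with drift parameter F
(``baseline_fst``, default 0.18, the genome-wide differentiation level of the
commercial layer/broiler contrast). Hard sweeps are implanted on top as a
deterministic hitchhiking profile

    p(d) = p_bg + (p_sweep - p_bg) * exp(-d / L)

around a sweep center, optionally forcing the swept chromosomes to share one
core haplotype so that extended haplotype homozygosity is present for iHS.

Sites are independent outside swept tracts; there is no background linkage
disequilibrium and no recombination map. Output is a phased multi-sample VCF
(layers) and a pool-count TSV (broilers), which round-trip exactly through
:mod:`sweepscan.variant_io`.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .panel import HaplotypePanel
from .variant_io import FilterConfig, PoolCountTable, read_pool_counts

# excess below this fraction of (p_sweep - p_bg) is treated as outside the
# swept tract; bounds the region where haplotypes are rewritten
_TRACT_MIN_EXCESS = 0.01


@dataclass(frozen=True)
class SweepSpec:
    """One implanted hard sweep.

    center: sweep position (bp). target_pops: populations carrying the sweep.
    p_sweep: derived-allele frequency forced at the center. decay_length: the
    hitchhiking scale L in bp. core_haplotype: if True, swept chromosomes
    share a single haplotype across the tract (long-range homozygosity).
    """

    center: int
    target_pops: tuple[str, ...]
    p_sweep: float = 0.95
    decay_length: float = 100_000.0
    core_haplotype: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_sweep <= 1.0:
            raise ValueError("p_sweep must be in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if len(self.target_pops) == 0:
            raise ValueError("sweep needs at least one target population")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults mirror the scanned populations: two layer populations of 25
    diploids each, three broiler pools, 107 bp mean SNP spacing, and
    drift-level differentiation F = 0.18.
    """

    seed: int = 0
    chrom: str = "1"
    chrom_length: int = 1_000_000
    mean_spacing: float = 107.0
    n_layers: int = 25
    layer_pops: tuple[str, ...] = ("WL", "BL")
    n_pools: int = 3
    pool_prefix: str = "BR"
    pool_depth: float = 30.0
    baseline_fst: float = 0.18
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    sweeps: tuple[SweepSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not 0.0 < self.baseline_fst < 1.0:
            raise ValueError("baseline_fst must be in (0, 1)")
        if self.mean_spacing < 1:
            raise ValueError("mean_spacing must be >= 1 bp")
        if self.n_layers < 1 or self.n_pools < 0 or self.pool_depth <= 0:
            raise ValueError("population sizes and pool depth must be positive")
        for sw in self.sweeps:
            if not 0 <= sw.center < self.chrom_length:
                raise ValueError("sweep center outside chromosome")

    @property
    def pool_names(self) -> tuple[str, ...]:
        return tuple(f"{self.pool_prefix}{i + 1}" for i in range(self.n_pools))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sweeps = tuple(
            SweepSpec(
                center=int(s["center"]),
                target_pops=tuple(s["target_pops"]),
                p_sweep=float(s.get("p_sweep", 0.95)),
                decay_length=float(s.get("decay_length", 100_000.0)),
                core_haplotype=bool(s.get("core_haplotype", True)),
            )
            for s in raw.pop("sweeps", [])
        )
        for key in ("layer_pops",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sweeps=sweeps, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["sweeps"] = [asdict(s) | {"target_pops": list(s.target_pops)} for s in self.sweeps]
        raw["layer_pops"] = list(self.layer_pops)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimulatedData:
    panel: HaplotypePanel
    pools: PoolCountTable
    pool_freqs: np.ndarray  # (n_sites, n_pools) generative per-pool frequencies
    config: SimulationConfig


def _draw_positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    n_guess = int(2 * length / spacing) + 10
    gaps = np.maximum(1, np.round(rng.exponential(spacing, n_guess))).astype(np.int64)
    pos = np.cumsum(gaps) - 1
    return pos[pos < length]


def _rng_streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_neutral_panel(cfg: SimulationConfig) -> tuple[HaplotypePanel, PoolCountTable]:
    """Neutral Balding–Nichols panel plus pool counts (no sweeps applied)."""
    data = simulate(replace(cfg, sweeps=()) if cfg.sweeps else cfg)
    return data.panel, data.pools


def simulate(cfg: SimulationConfig) -> SimulatedData:
    """Generate the full synthetic dataset described by the config.

    Identical configs (including seed) produce identical output.
    """
    streams = _rng_streams(
        cfg.seed,
        ["positions", "ancestral", "popfreq", "haplotypes", "pools", "sweep"],
    )
    positions = _draw_positions(streams["positions"], cfg.chrom_length, cfg.mean_spacing)
    n_sites = positions.size
    if n_sites == 0:
        raise ValueError("no sites generated; increase chrom_length or lower mean_spacing")
    anc = streams["ancestral"].uniform(cfg.ancestral_low, cfg.ancestral_high, n_sites)

    F = cfg.baseline_fst
    alpha = anc * (1 - F) / F
    beta = (1 - anc) * (1 - F) / F
    rng_pf = streams["popfreq"]

    layer_freqs = {pop: rng_pf.beta(alpha, beta) for pop in cfg.layer_pops}
    pool_freqs = np.column_stack([rng_pf.beta(alpha, beta) for _ in range(cfg.n_pools)]) \
        if cfg.n_pools else np.empty((n_sites, 0))

    # sweeps adjust the generative frequencies before any sampling
    for sw in cfg.sweeps:
        d = np.abs(positions - sw.center)
        decay = np.exp(-d / sw.decay_length)
        for pop in sw.target_pops:
            if pop in layer_freqs:
                p_bg = layer_freqs[pop]
                layer_freqs[pop] = p_bg + (sw.p_sweep - p_bg) * decay
        for j, pool in enumerate(cfg.pool_names):
            if pool in sw.target_pops:
                p_bg = pool_freqs[:, j]
                pool_freqs[:, j] = p_bg + (sw.p_sweep - p_bg) * decay

    # phased haplotypes: site-independent Bernoulli draws per population
    rng_h = streams["haplotypes"]
    hap_blocks = []
    pop_labels = []
    for pop in cfg.layer_pops:
        n_hap = 2 * cfg.n_layers
        block = (rng_h.random((n_hap, n_sites)) < layer_freqs[pop]).astype(np.uint8)
        hap_blocks.append(block)
        pop_labels.extend([pop] * n_hap)
    panel = HaplotypePanel(
        chrom=cfg.chrom,
        chrom_length=cfg.chrom_length,
        positions=positions,
        haplotypes=np.vstack(hap_blocks),
        pop_labels=np.array(pop_labels),
    )

    # core-haplotype structure is a property of the sampled chromosomes, not
    # of the generative frequencies, so it is implanted on the panel
    for sw in cfg.sweeps:
        layer_targets = [p for p in sw.target_pops if p in cfg.layer_pops]
        if layer_targets and sw.core_haplotype:
            panel = implant_sweep(
                panel,
                SweepSpec(
                    center=sw.center,
                    target_pops=tuple(layer_targets),
                    p_sweep=sw.p_sweep,
                    decay_length=sw.decay_length,
                    core_haplotype=True,
                ),
                rng=streams["sweep"],
            )

    # pooled read counts: Poisson depth, binomial allele sampling
    rng_p = streams["pools"]
    depth = rng_p.poisson(cfg.pool_depth, size=(n_sites, cfg.n_pools))
    alt = rng_p.binomial(depth, pool_freqs)
    ref = depth - alt
    sites = _sites_frame(cfg, positions)
    pools = PoolCountTable(
        sites=sites,
        pools=list(cfg.pool_names),
        ref_count=ref,
        alt_count=alt,
        masked=(depth < FilterConfig().min_pool_depth),
    )
    return SimulatedData(panel=panel, pools=pools, pool_freqs=pool_freqs, config=cfg)


def _sites_frame(cfg: SimulationConfig, positions: np.ndarray):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions,
            "ref": "A",  # ancestral allele is the reference allele in fixtures
            "alt": "G",
        }
    )


def implant_sweep(
    panel: HaplotypePanel, spec: SweepSpec, rng: np.random.Generator | None = None
) -> HaplotypePanel:
    """Raise derived-allele frequencies around a sweep center in target pops.

    Within the swept tract (where the hitchhiking excess exceeds 1% of the
    center excess) the per-site target frequency is
    ``p(d) = p_bg + (p_sweep - p_bg)·exp(-d/L)`` with ``p_bg`` the population's
    current frequency. Without ``core_haplotype`` every target chromosome's
    allele is redrawn independently at ``p(d)``; with it, a carrier subset of
    ``round(p_sweep · n)`` chromosomes shares one allele draw per site, so all
    carriers are identical across the tract (one long core haplotype) while
    the expected frequency still follows ``p(d)``. Non-target populations are
    untouched.
    """
    if len(spec.target_pops) == 0:
        raise ValueError("sweep needs at least one target population")
    rng = rng or np.random.default_rng(0)
    out = panel.copy()
    d = np.abs(out.positions - spec.center)
    decay = np.exp(-d / spec.decay_length)
    in_tract = decay >= _TRACT_MIN_EXCESS
    if not in_tract.any():
        return out
    tract = np.flatnonzero(in_tract)

    for pop in spec.target_pops:
        rows = out.rows_of(pop)
        sub = out.haplotypes[np.ix_(rows, tract)].astype(float)
        p_bg = sub.mean(axis=0)
        p_target = p_bg + (spec.p_sweep - p_bg) * decay[tract]
        if spec.core_haplotype:
            n = rows.size
            k = int(round(spec.p_sweep * n))
            k = max(2, min(n, k))
            carriers = rng.choice(n, size=k, replace=False)
            f = k / n
            with np.errstate(invalid="ignore", divide="ignore"):
                w = (p_target - (1 - f) * p_bg) / f
            w = np.clip(w, 0.0, 1.0)
            shared = (rng.random(tract.size) < w).astype(np.uint8)
            block = out.haplotypes[np.ix_(rows, tract)]
            block[carriers, :] = shared[None, :]
            out.haplotypes[np.ix_(rows, tract)] = block
        else:
            draws = (rng.random((rows.size, tract.size)) < p_target).astype(np.uint8)
            out.haplotypes[np.ix_(rows, tract)] = draws
    return out


def emit_fixtures(panel: HaplotypePanel, pools: PoolCountTable, out_dir) -> dict[str, str]:
    """Write the panel as a phased multi-sample VCF and the pools as TSV.

    Returns the paths written: ``vcf``, ``pools``, ``chrom_lengths``. Reading
    them back through variant_io reproduces dosages and counts exactly.
    """
    if panel.n_sites == 0:
        raise ValueError("cannot emit an empty panel")
    if panel.n_chromosomes % 2 != 0:
        raise ValueError("panel must hold an even number of chromosomes (phased diploids)")
    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "layers.vcf")
    pools_path = os.path.join(out_dir, "pools.tsv")
    lengths_path = os.path.join(out_dir, "chrom_lengths.tsv")

    sample_names = []
    pair_rows = []
    counters: dict[str, int] = {}
    for i in range(0, panel.n_chromosomes, 2):
        pop = str(panel.pop_labels[i])
        if panel.pop_labels[i + 1] != panel.pop_labels[i]:
            raise ValueError("chromosome pairs must belong to one population")
        counters[pop] = counters.get(pop, 0) + 1
        sample_names.append(f"{pop}_{counters[pop]:02d}")
        pair_rows.append((i, i + 1))

    depth = 10 * len(sample_names)  # uniform coverage: the depth band keeps all sites
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={panel.chrom_length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        H = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(f"{H[a, j]}|{H[b, j]}" for a, b in pair_rows)
            fh.write(
                f"{panel.chrom}\t{panel.positions[j] + 1}\t.\tA\tG\t100\t.\tDP={depth}\tGT\t{gts}\n"
            )

    df = pools.sites.copy()
    df["pos"] = df["pos"] + 1
    for j, pool in enumerate(pools.pools):
        df[f"{pool}_ref"] = pools.ref_count[:, j]
        df[f"{pool}_alt"] = pools.alt_count[:, j]
    df.to_csv(pools_path, sep="\t", index=False)

    with open(lengths_path, "w") as fh:
        fh.write(f"{panel.chrom}\t{panel.chrom_length}\n")
    return {"vcf": vcf_path, "pools": pools_path, "chrom_lengths": lengths_path}
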