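import numpy as np
import pytest

import sweepscan as ss


@pytest.fixture(scope="session")
def neutral_sim():
    """Small neutral dataset: 2 layer pops + 3 pools, ~2800 sites on 300 kb."""
    cfg = ss.SimulationConfig(seed=11, chrom_length=300_000)
    return ss.simulate(cfg)


@pytest.fixture(scope="session")
def neutral_fixture_dir(neutral_sim, tmp_path_factory):
    """The neutral dataset written out as VCF + pool TSV + lengths."""
    out = tmp_path_factory.mktemp("neutral")
    paths = ss.emit_fixtures(neutral_sim.panel, neutral_sim.pools, out)
    paths["config"] = neutral_sim.config
    return paths


@pytest.fixture(scope="session")
def sweep_fixture_dir(tmp_path_factory):
    """Dataset with one all-population hard sweep at 300 kb of a 600 kb chromosome."""
    cfg = ss.SimulationConfig(
        seed=21,
        chrom_length=600_000,
        sweeps=(
            ss.SweepSpec(
                center=300_000,
                target_pops=("WL", "BL", "BR1", "BR2", "BR3"),
                p_sweep=0.95,
                decay_length=100_000,
            ),
        ),
    )
    data = ss.simulate(cfg)
    out = tmp_path_factory.mktemp("sweep")
    paths = ss.emit_fixtures(data.panel, data.pools, out)
    paths["config"] = cfg
    return paths


@pytest.fixture
def toy_panel():
    """4-haplotype panel, fully enumerable by hand; core site at index 3.

    Both allele classes at the core truncate (EHH hits 0) before either
    chromosome edge, so the integrals are uncensored.
    """
    hap = np.array(
        [
            [0, 1, 1, 1, 1, 1, 0],
            [1, 1, 1, 1, 1, 0, 1],
            [0, 0, 1, 0, 1, 0, 0],
            [1, 0, 0, 0, 1, 1, 0],
        ],
        dtype=np.uint8,
    )
    return ss.HaplotypePanel(
        chrom="1",
        chrom_length=700,
        positions=np.array([0, 100, 200, 300, 400, 500, 600]),
        haplotypes=hap,
        pop_labels=np.array(["P"] * 4),
    )


def write_vcf(path, rows, samples, phased=True):
    """Minimal VCF writer for handcrafted test inputs.

    rows: (chrom, pos_1based, ref, alt, qual, depth, genotypes) where
    genotypes is a list of (a, b) allele pairs or None for missing.
    """
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, depth, gts in rows:
            cells = []
            for gt in gts:
                cells.append("." + sep + "." if gt is None else f"{gt[0]}{sep}{gt[1]}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\tDP={depth}\tGT\t"
                + "\t".join(cells)
                + "\n"
            )
    return path
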