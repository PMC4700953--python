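"""Published candidate regions from the commercial chicken layer/broiler scans.

Two small reference tables of reported candidate regions, used as regression
inputs for the decision logic: the parallel-fixation candidates carry the
window-mean alternate-allele frequency of each region in the white-layer
(WL), brown-layer (BL) and pooled-broiler (BR) populations; the divergence
candidates carry each region's maximum window Fst and empirical percentile P.
Coordinates are 1-based inclusive on the Galgal4 assembly.
"""

from __future__ import annotations

import pandas as pd

# chrom, start, end, AF_WL, AF_BL, AF_BR, gene/region label
_PARALLEL_FIXATION_ROWS = [
    ("1", 46162081, 46327076, 0.90, 0.87, 0.86, "gene desert"),
    ("1", 117000428, 117030951, 0.98, 0.86, 0.91, "gene desert"),
    ("1", 149367651, 149494049, 0.95, 0.88, 0.95, "LOC101748868"),
    ("2", 81956167, 82594173, 0.99, 0.89, 0.90, "VSTM2A"),
    ("2", 94091060, 94204500, 0.92, 0.97, 0.96, "CCDC102B"),
    ("2", 146767959, 146879733, 0.93, 0.91, 0.97, "TSNARE1"),
    ("3", 50672559, 50816899, 0.97, 0.95, 0.91, "C7ORF10"),
    ("3", 84015975, 84072368, 0.89, 0.87, 0.86, "gene desert"),
    ("5", 31562907, 31623166, 0.90, 0.98, 0.91, "GJD2"),
    ("5", 40044067, 40104591, 0.95, 0.91, 0.89, "TSHR"),
    ("8", 9411058, 9463004, 0.86, 0.88, 0.87, "gene desert"),
    ("9", 11798419, 11901393, 0.98, 0.98, 0.86, "AGTR1"),
    ("10", 5316513, 5444763, 0.95, 0.99, 0.90, "APBA2"),
    ("11", 35837, 98851, 0.98, 0.98, 0.85, "LTB4R"),
    ("24", 6113460, 6173359, 0.88, 0.97, 0.90, "BCDO2"),
    ("28", 579151, 594628, 0.94, 0.90, 0.86, "SPPL2B"),
]

# chrom, start, end, max Fst, empirical P, gene label
_PARALLEL_DIVERGENCE_ROWS = [
    ("1", 66066955, 66119201, 0.55, 0.00429, "SOX5"),
    ("2", 122495794, 123015968, 0.50, 0.00525, "WWP1"),
    ("2", 135771154, 136193827, 0.74, 0.00071, "TNFRSF11B/EXT1/EXT1L"),
    ("5", 48161309, 49265282, 0.91, 0.00004, "DLK1"),
    ("9", 19104947, 19552350, 0.64, 0.00132, "CLDNS11"),
    ("11", 15942, 476726, 0.95, 0.00001, "SMPD3"),
]

# headline scale of the original scan, for documentation and sanity checks
ORIGINAL_SCALE = {
    "genome_wide_fst": 0.18,
    "genome_wide_fst_sd": 0.08,
    "n_windows": 139_005,
    "top1pct_fst_threshold": 0.46,
    "n_divergence_regions": 170,
    "mean_fst_microchromosomes": 0.186,
    "mean_fst_macrochromosomes": 0.184,
    "mean_snp_spacing_bp": 107,
}


def parallel_fixation_candidates() -> pd.DataFrame:
    """Reported parallel-fixation candidate regions with per-population AF."""
    return pd.DataFrame(
        _PARALLEL_FIXATION_ROWS,
        columns=["chrom", "start", "end", "AF_WL", "AF_BL", "AF_BR", "gene"],
    )


def parallel_divergence_candidates() -> pd.DataFrame:
    """Reported divergence candidate regions with max Fst and empirical P."""
    return pd.DataFrame(
        _PARALLEL_DIVERGENCE_ROWS,
        columns=["chrom", "start", "end", "max_fst", "p", "gene"],
    )
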