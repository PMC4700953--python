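"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from first principles (explicit loops,
pair enumeration, set arithmetic) and never calls the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def wc84_oracle(ps, ns_hap) -> float:
    """Weir & Cockerham (1984) theta-hat for r populations, scalar loops.

    ps: allele frequencies per population; ns_hap: haplotype counts per
    population (diploid individuals = n/2, heterozygosity = HWE 2p(1-p)).
    """
    r = len(ps)
    n = [x / 2.0 for x in ns_hap]
    p = list(ps)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    h = [2.0 * pi * (1.0 - pi) for pi in p]
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    return math.nan if denom == 0 else a / denom


def windows_containing(position: int, starts, window_size: int) -> list[int]:
    """Indices of all grid windows covering a position (brute force)."""
    return [i for i, s in enumerate(starts) if s <= position < s + window_size]


def window_mean_oracle(positions, values, starts, window_size, min_snps):
    """Per-window mean by explicit membership scan."""
    out = []
    counts = []
    for s in starts:
        member = [
            v
            for p, v in zip(positions, values)
            if s <= p < s + window_size and not math.isnan(v)
        ]
        counts.append(len(member))
        out.append(sum(member) / len(member) if len(member) >= min_snps else math.nan)
    return np.array(out), np.array(counts)


def intersection_oracle(site_lists) -> set:
    """Common (chrom, pos) keys across tables, allowing a ref/alt swap."""
    def keyed(sites):
        return {(c, p): (r, a) for c, p, r, a in sites}

    maps = [keyed(s) for s in site_lists]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    ok = set()
    for key in common:
        r0, a0 = maps[0][key]
        if all(m[key] == (r0, a0) or m[key] == (a0, r0) for m in maps[1:]):
            ok.add(key)
    return ok


def ehh_oracle(hap, positions, core, allele, x_index) -> float:
    """EHH at site x for the carriers of an allele, by pair enumeration.

    Fraction of unordered carrier pairs identical at every site between the
    core and x (inclusive).
    """
    carriers = [i for i in range(hap.shape[0]) if hap[i, core] == allele]
    n = len(carriers)
    if n < 2:
        raise ValueError("need >= 2 carriers")
    lo, hi = min(core, x_index), max(core, x_index)
    same = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if all(hap[carriers[i], k] == hap[carriers[j], k] for k in range(lo, hi + 1)):
                same += 1
    return same / total


def ihh_oracle(hap, positions, core, allele, truncation=0.05) -> float:
    """Integrated EHH by pair enumeration + trapezoid, both directions.

    Walks outward site by site, stops after the first EHH value below the
    truncation cutoff; returns NaN if an edge is reached first (censored).
    """
    total = 0.0
    for step in (-1, 1):
        xs = [0.0]
        ys = [1.0]
        j = core
        truncated = False
        while True:
            j_next = j + step
            if j_next < 0 or j_next >= len(positions):
                break
            e = ehh_oracle(hap, positions, core, allele, j_next)
            xs.append(abs(float(positions[j_next]) - float(positions[core])))
            ys.append(e)
            j = j_next
            if e < truncation:
                truncated = True
                break
        if not truncated:
            return math.nan
        for k in range(1, len(xs)):
            total += (ys[k] + ys[k - 1]) / 2.0 * (xs[k] - xs[k - 1])
    return total


def ihs_oracle(hap, positions, core, truncation=0.05) -> float:
    ihh_a = ihh_oracle(hap, positions, core, 0, truncation)
    ihh_d = ihh_oracle(hap, positions, core, 1, truncation)
    if math.isnan(ihh_a) or math.isnan(ihh_d) or ihh_a <= 0 or ihh_d <= 0:
        return math.nan
    return math.log(ihh_a / ihh_d)
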