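"""Phased haplotype panel with ancestral/derived polarization.

The panel is the in-memory meeting point of the synthetic-data generator and
the haplotype statistics: rows are phased chromosomes (two per diploid
individual, consecutive), columns are sorted SNP positions, entries are 0 for
the ancestral and 1 for the derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HaplotypePanel:
    chrom: str
    chrom_length: int
    positions: np.ndarray  # sorted 0-based bp
    haplotypes: np.ndarray  # (n_chromosomes, n_sites) in {0, 1}
    pop_labels: np.ndarray  # population of each chromosome row

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix does not align with positions")
        if self.pop_labels.size != self.haplotypes.shape[0]:
            raise ValueError("pop_labels does not align with haplotype rows")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0 (ancestral) or 1 (derived)")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pop_labels:
            if p not in seen:
                seen.append(str(p))
        return seen

    def rows_of(self, pop: str) -> np.ndarray:
        rows = np.flatnonzero(self.pop_labels == pop)
        if rows.size == 0:
            raise KeyError(f"unknown population: {pop!r}")
        return rows

    def derived_freq(self, pop: str | None = None) -> np.ndarray:
        """Per-site derived-allele frequency, optionally within one population."""
        h = self.haplotypes if pop is None else self.haplotypes[self.rows_of(pop)]
        return h.mean(axis=0)

    def subset_pops(self, pops: list[str]) -> "HaplotypePanel":
        rows = np.flatnonzero(np.isin(self.pop_labels, pops))
        return HaplotypePanel(
            chrom=self.chrom,
            chrom_length=self.chrom_length,
            positions=self.positions.copy(),
            haplotypes=self.haplotypes[rows].copy(),
            pop_labels=self.pop_labels[rows].copy(),
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom=self.chrom,
            chrom_length=self.chrom_length,
            positions=self.positions.copy(),
            haplotypes=self.haplotypes.copy(),
            pop_labels=self.pop_labels.copy(),
        )
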