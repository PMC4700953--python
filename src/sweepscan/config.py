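"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Scan parameters; defaults are the published scan's stated constants.

    window_size/step: the overlapping-window frame (40 kb / 5 kb).
    fixation_tau: all-populations window-AF threshold (0.85, inclusive).
    fst_quantile: empirical quantile defining divergence outliers (top 1%).
    min_snps_per_window: windows with fewer defined sites are missing.
    maf_min / ehh_truncation / max_gap: iHS parameters.
    estimator: per-site Fst estimator, "wc84" (default) or "hudson".
    layer_group_mode: "mean" averages per-layer frequency tracks; "pooled"
    treats all layer samples as one genotype pool.
    max_pool_n: cap on the haplotype-equivalent sample size of pooled data.
    """

    window_size: int = 40_000
    step: int = 5_000
    fixation_tau: float = 0.85
    fst_quantile: float = 0.99
    min_snps_per_window: int = 5
    maf_min: float = 0.05
    ehh_truncation: float = 0.05
    max_gap: int = 200_000
    n_ihs_bins: int = 20
    seed: int = 0
    estimator: str = "wc84"
    layer_group_mode: str = "mean"
    max_pool_n: float | None = 50.0
    gap_tolerance: int = 0
    min_qual: float = 20.0
    depth_sigma: float | None = 2.0
    min_pool_depth: int = 4
    chromosome_class_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimator not in ("wc84", "hudson"):
            raise ValueError("estimator must be 'wc84' or 'hudson'")
        if self.layer_group_mode not in ("mean", "pooled"):
            raise ValueError("layer_group_mode must be 'mean' or 'pooled'")
        if not 0 < self.fst_quantile < 1:
            raise ValueError("fst_quantile must be in (0, 1)")
        if not 0 <= self.fixation_tau <= 1:
            raise ValueError("fixation_tau must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
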