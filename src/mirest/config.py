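"""Pipeline configuration: one flat key-value document.

Defaults reproduce the pipeline's published operating point (5 mismatches,
~100 nt windows, dG <= -20 kcal/mol precursor threshold, dG < -20 kcal/mol
duplex threshold).  Values can be loaded from a flat YAML file and
overridden per key; the configuration hash is logged by every subcommand
for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml

from .precursor import FilterThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    max_mm: int = 5                      # mismatch bound for homology hits
    window_len: int = 100                # precursor window length, nt
    precursor_dg_max: float = -20.0      # kcal/mol, pass iff dG <= this
    duplex_dg_max: float = -20.0         # kcal/mol, pass iff dG < this
    min_stem: int = 14                   # minimum stem pairs
    min_mature_paired: float = 0.6
    gc_min: float = 0.20
    gc_max: float = 0.80
    min_ch_ratio: float = 0.8
    max_loop_overlap: int = 4            # nt of mature outside its arm
    max_spacer: int = 1000               # nt between clustered matures
    cluster_method: str = "average"
    cluster_metric: str = "correlation"
    expression_control: str = "U6snRNA"
    expression_reference: str = "max"    # "max" or a sample column name
    class2_mode: str = "fragment"        # or "full"
    seed: int = 0

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            dg_max=self.precursor_dg_max,
            min_stem=self.min_stem,
            max_loop_overlap=self.max_loop_overlap,
            min_mature_paired=self.min_mature_paired,
            gc_min=self.gc_min,
            gc_max=self.gc_max,
            min_ch_ratio=self.min_ch_ratio,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        data.update(overrides)
        return cls(**data)
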