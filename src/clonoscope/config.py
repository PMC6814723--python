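"""Analysis configuration: every threshold of the clonal-analysis pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and options of the clone-calling and spatial analysis.

    Attributes
    ----------
    rarity_threshold :
        Displays occurring in strictly less than this fraction of labeled
        cells qualify as clonal identity keys (default 2%).
    rarity_scope :
        ``'pooled'`` (default): rarity computed over all animals of a
        dataset; ``'per_animal'``: within each animal.
    linkage_um :
        Sister cells must be strictly closer than this (600 µm) to be
        linked into one clone.
    section_thickness_um :
        Conversion for section-indexed z coordinates (default 80 µm).
    disconnect_um :
        Per-stage disconnection distance (astrocyte mean diameter + s.d.);
        implementation defaults, not measured values.
    doublet_um :
        Doublet threshold, the mean astrocyte nuclear size (6 µm).
    n_depth_bins :
        Number of equal cortical-depth bins (6, bin 1 at the pial surface).
    depth_tol :
        Tolerated overshoot of normalized depth outside [0, 1] (2%).
    """

    rarity_threshold: float = 0.02
    rarity_scope: str = "pooled"
    linkage_um: float = 600.0
    section_thickness_um: float = 80.0
    disconnect_um: dict = field(default_factory=lambda: {"P7": 60.0, "P21": 70.0})
    disconnect_default_um: float = 60.0
    doublet_um: float = 6.0
    n_depth_bins: int = 6
    depth_tol: float = 0.02
    dunn_adjust: str = "bonferroni"
    seed: int = 0

    def disconnect_for(self, stage: str) -> float:
        return float(self.disconnect_um.get(stage, self.disconnect_default_um))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
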