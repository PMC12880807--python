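"""Pipeline configuration.

All numeric thresholds used anywhere in the pipeline live here; no stage
hard-codes a cutoff. Defaults follow the published analysis this package
re-implements (peak-to-gene r > 0.25, 500 kb cis windows, motif p 5e-5,
footprint delta 0.05, importance 0.1, edge correlation +/-0.05, histone
signal 2.5, key-TF p 1e-6 and coverage 0.2, DEG lfc 0.35 at p 1e-6,
k-means k = 8, local-alignment gaps -2/-1, conserved-pair p 0.05,
chromVAR-style avg_diff 2 at adjusted p 0.01).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # peak-to-gene linking
    ptog_r_min: float = 0.25
    ptog_fdr_grn: float = 0.05
    ptog_fdr_deg: float = 0.01
    cis_window_bp: int = 500_000
    tss_window_bp: int = 1_000
    pseudocell_min_size: int = 20
    pseudocell_groups: int = 100
    n_pcs: int = 30
    # TF-binding-site prediction
    tf_expr_min: float = 0.1
    motif_p: float = 5e-5
    footprint_delta: float = 0.05
    flank_multiple: int = 3
    # edge classification
    importance_min: float = 0.1
    edge_r_pos: float = 0.05
    edge_r_neg: float = -0.05
    # element annotation
    histone_signal_min: float = 2.5
    # cone-specific genes / key activator TFs
    cone_de_lfc: float = 0.3
    cone_de_padj: float = 0.01
    key_tf_p: float = 1e-6
    key_tf_coverage: float = 0.2
    key_tf_top_n: int = 30
    # cross-species DEGs
    deg_p: float = 1e-6
    deg_lfc: float = 0.35
    kmeans_k: int = 8
    # conservation calling
    gap_open: float = -2.0
    gap_extend: float = -1.0
    align_match: float = 1.0
    align_mismatch: float = -1.0
    conserved_p: float = 0.05
    # motif activity
    motif_avg_diff: float = 2.0
    motif_padj: float = 0.01
    n_background: int = 50
    gc_bins: int = 10
    # shared numerics
    pseudocount: float = 1.0
    normalize_scale: float = 10_000.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
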