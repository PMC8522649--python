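"""Flat key-value run configuration (YAML) with validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs: paths, switches, thresholds, seed.

    Leave ``simulate`` true to generate all inputs synthetically (the
    ``sim`` mapping overrides :class:`~mstrans.simulate.SimulationConfig`
    fields); otherwise the ``*_path`` entries must point at existing files.
    """

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)

    # ingest paths (required when simulate is false)
    features_path: str | None = None
    meta_path: str | None = None
    atlas_path: str | None = None
    expression_path: str | None = None
    de_path: str | None = None
    de_groups_path: str | None = None
    celltype_path: str | None = None
    gmt_path: str | None = None

    # stage switches / thresholds
    harmonize: bool = True
    combat_covariates: list = field(
        default_factory=lambda: ["group", "age", "sex", "education"]
    )
    model_covariates: list = field(
        default_factory=lambda: ["age", "sex", "education"]
    )
    zscore_axis: str = "within_subject"
    scale_genes: bool = True
    alpha: float = 0.05
    z_crit: float | None = None  # None -> derived from n_genes
    B: int = 1000
    B_perm: int = 1000
    p_thresh: float = 0.01
    fc_thresh: float = 1.0
    psi_thresh: float = 0.05
    fisher_alternative: str = "greater"
    fdr_q: float = 0.05
    write_ms_matrices: bool = False

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha", 0, 1),
            ("p_thresh", 0, 1),
            ("psi_thresh", 0, 1),
            ("fdr_q", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.fc_thresh < 0:
            raise ValueError("fc_thresh must be non-negative")
        if self.B < 100 or self.B_perm < 1:
            raise ValueError("B must be >=100 and B_perm >=1")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ValueError("fisher_alternative: 'greater' or 'two-sided'")
        if self.zscore_axis not in ("within_subject", "across_subjects"):
            raise ValueError(
                "zscore_axis: 'within_subject' or 'across_subjects'"
            )
        if not self.simulate:
            required = ["features_path", "meta_path", "atlas_path"]
            for name in required:
                v = getattr(self, name)
                if v is None:
                    raise ValueError(f"{name} required when simulate is false")
                if not Path(v).exists():
                    raise ValueError(f"{name}: no such file {v!r}")
            for name in (
                "expression_path",
                "de_path",
                "de_groups_path",
                "celltype_path",
                "gmt_path",
            ):
                v = getattr(self, name)
                if v is not None and not Path(v).exists():
                    raise ValueError(f"{name}: no such file {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
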