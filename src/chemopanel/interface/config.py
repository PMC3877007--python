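"""Pipeline configuration: defaults, YAML loading and a stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


def _default_groups() -> dict[str, list[str]]:
    return {
        "group1": ["CPD1", "CPD2", "CPD3"],
        "group2": ["CPD4", "CPD5"],
    }


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Every random operation derives its seed from ``seed`` via independent
    per-stage seed sequences, so toggling one stage off leaves the others'
    outputs unchanged.
    """

    seed: int = 0

    # synthetic potency panel
    groups: dict[str, list[str]] = field(default_factory=_default_groups)
    n_cell_lines: int = 10
    within_group_r: float = 0.95
    between_group_r: float = 0.2
    n_experiments: int = 2

    # plate design / noise
    n_conc: int = 10
    dilution_factor: float = 10.0 ** 0.5
    n_replicates: int = 2
    n_controls: int = 6
    control_mean_signal: float = 10000.0
    noise_cv: float = 0.1

    # combination stage (first two compounds, constant equipotent ratio)
    combo_psi: float = 0.5
    combo_m: float = 1.0
    fa_grid: list[float] = field(default_factory=lambda: [0.5, 0.75, 0.9])
    band_epsilon: float = 0.0

    # clustering
    cluster_log10: bool = True
    censor_policy: str = "impute_at_bound"

    # expression screen
    n_genes: int = 300
    planted_per_compound: int = 2
    planted_abs_r: float = 0.9
    min_signal: float = 500.0
    p_cutoff: float = 5e-4
    potency_log10: bool = False

    # GO summarization
    n_terms: int = 20
    mean_terms_per_gene: float = 3.0
    go_top_k: int = 30

    # PK contextualization (demo values applied to every compound)
    pk_cmax_ng_ml: float = 1000.0
    pk_mw_g_mol: float = 500.0

    # stage toggles
    run_synergy: bool = True
    run_cluster: bool = True
    run_expression: bool = True
    run_go: bool = True
    run_pk: bool = True

    def __post_init__(self) -> None:
        compounds = [c for members in self.groups.values() for c in members]
        if len(compounds) < 2:
            raise ValueError("need at least two compounds")
        if len(set(compounds)) != len(compounds):
            raise ValueError("compound ids must be unique")
        if self.run_go and not self.run_expression:
            raise ValueError("GO stage requires the expression stage")

    @property
    def compounds(self) -> list[str]:
        return [c for members in self.groups.values() for c in members]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # stage toggles select outputs but do not parameterize the data,
        # so they stay out of the hash
        d = {k: v for k, v in self.to_dict().items() if not k.startswith("run_")}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
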