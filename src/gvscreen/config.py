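"""Pipeline configuration with YAML round-trip.

Collects every tunable decision from the other modules (band edges, burst
rule, PAC bins, LASSO settings, MCDA normalization, BH thresholds, cohort
layout, seeds) in one serializable object.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .features import BiomarkerConfig, CENTRAL_CHANNELS
from .simulate import CohortConfig, DEFAULT_MONTAGE


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    biomarkers: BiomarkerConfig = field(default_factory=BiomarkerConfig)
    central_channels: tuple[str, ...] = CENTRAL_CHANNELS
    lasso_n_lambdas: int = 30
    lasso_inner_folds: int = 5
    mcda_normalization: str = "vector"  # vector | minmax | sum
    epsilon: float = 1e-9
    category_q_threshold: float = 0.1
    channelmap_q_threshold: float = 0.05

    def validate(self) -> list[str]:
        problems = []
        if self.mcda_normalization not in ("vector", "minmax", "sum"):
            problems.append(
                f"unknown mcda_normalization: {self.mcda_normalization!r}")
        if not 0 < self.category_q_threshold < 1:
            problems.append("category_q_threshold must be in (0, 1)")
        if not 0 < self.channelmap_q_threshold < 1:
            problems.append("channelmap_q_threshold must be in (0, 1)")
        if self.epsilon <= 0:
            problems.append("epsilon must be positive")
        if self.lasso_n_lambdas < 2:
            problems.append("lasso_n_lambdas must be at least 2")
        missing = [c for c in self.central_channels
                   if c not in self.cohort.channel_names]
        if missing:
            problems.append(f"central channels not in montage: {missing}")
        return problems

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohort"]["channel_names"] = list(self.cohort.channel_names)
        d["cohort"]["trial_layout"] = list(self.cohort.trial_layout)
        d["central_channels"] = list(self.central_channels)
        for key in ("beta_band", "gamma_band", "total_band",
                    "aperiodic_fit_range"):
            d["biomarkers"][key] = list(d["biomarkers"][key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cohort_d = d.pop("cohort", {})
        cohort_d["channel_names"] = tuple(
            cohort_d.get("channel_names", DEFAULT_MONTAGE))
        cohort_d["trial_layout"] = tuple(
            cohort_d.get("trial_layout", (2.0, 2.0, 5.0)))
        if "effect_map" in cohort_d:
            cohort_d["effect_map"] = {int(k): float(v) for k, v in
                                      cohort_d["effect_map"].items()}
        bio_d = d.pop("biomarkers", {})
        for key in ("beta_band", "gamma_band", "total_band",
                    "aperiodic_fit_range"):
            if key in bio_d:
                bio_d[key] = tuple(bio_d[key])
        d["central_channels"] = tuple(d.get("central_channels",
                                            CENTRAL_CHANNELS))
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig(**cohort_d),
                   biomarkers=BiomarkerConfig(**bio_d), **d)
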