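"""Run configuration: label vocabularies, epsilon and operating-point
policies, and the augmentation list (declared in config, applied only when a
training loop requests it)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .car import EpsilonPolicy

#: the 15 abnormal retinal findings covered by the screening system
DEFAULT_FINDINGS = [
    "hemorrhage",
    "hard_exudate",
    "cotton_wool_patch",
    "drusen",
    "membrane",
    "macular_hole",
    "myelinated_nerve_fiber",
    "chorioretinal_atrophy",
    "vascular_abnormality",
    "rnfl_defect",
    "glaucomatous_disc_change",
    "non_glaucomatous_disc_change",
    "fluid_accumulation",
    "retinal_pigmentary_change",
    "choroidal_lesion",
]

#: the 8 diagnosed diseases
DEFAULT_DISEASES = [
    "dry_amd",
    "wet_amd",
    "any_dr",
    "referable_dr",
    "crvo",
    "brvo_hemi_crvo",
    "epiretinal_membrane",
    "glaucoma_suspect",
]

KNOWN_AUGMENTATIONS = [
    "rotation", "flip", "affine", "color", "contrast", "brightness",
    "noise", "resize", "elastic", "downsample",
]


@dataclass
class RunConfig:
    findings: list[str] = field(default_factory=lambda: list(DEFAULT_FINDINGS))
    diseases: list[str] = field(default_factory=lambda: list(DEFAULT_DISEASES))
    epsilon_mode: str = "fixed"
    epsilon_value: float = 0.005
    epsilon_percentile: float = 5.0
    operating_point_policy: str = "max_harmonic_mean"
    target_sensitivity: float = 0.9
    augmentations: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for group, names in (("findings", self.findings), ("diseases", self.diseases)):
            if len(set(names)) != len(names):
                raise ValueError(f"{group} names must be unique")
        unknown = set(self.augmentations) - set(KNOWN_AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")

    def epsilon_policy(self) -> EpsilonPolicy:
        return EpsilonPolicy(mode=self.epsilon_mode, value=self.epsilon_value,
                             percentile=self.epsilon_percentile)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls(**data)
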