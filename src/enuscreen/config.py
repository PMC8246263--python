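"""Simulation and mapping configuration.

Defaults define the study conditions emulated by the synthetic-data engine:
a 60-allele panel per G1 sire, 6 G2 dams with litters of 6-8 G3 pups (about
42 screened G3 mice per pedigree, the scale of a 54,497-mouse /
1275-pedigree screen), a 0.5% background affected rate, and causal pedigrees
(10% of the screen) carrying one recessive (95%) or dominant (5%) allele
with penetrance uniform on [0.3, 1.0].  See docs/methods.md for the
reasoning behind each default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome import GeneticMap, default_mouse_map

__all__ = ["SimulationConfig"]

_MODEL_NAMES = ("recessive", "dominant", "additive")


@dataclass
class SimulationConfig:
    # genome / panel
    map_file: str | None = None  # None -> packaged default mouse autosome map
    n_alleles: int = 60
    #: aligned with simulate.EFFECT_CLASSES: (probably_damaging,
    #: possibly_damaging, benign, putative_null, synonymous)
    effect_weights: tuple[float, ...] = (0.25, 0.15, 0.40, 0.05, 0.15)
    # pedigree structure
    n_g2_dams: int = 6
    litter_size_min: int = 6
    litter_size_max: int = 8
    # phenotype model
    causal_fraction: float = 0.10
    dominant_fraction: float = 0.05
    penetrance_min: float = 0.3
    penetrance_max: float = 1.0
    background_rate: float = 0.005
    hom_lethality: float = 0.0
    # mapping
    alpha: float = 0.05
    models: tuple[str, ...] = ("recessive", "dominant")
    per_model_bonferroni: bool = False
    mapping_window_cM: float = 5.0
    # reproducibility
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("causal_fraction", "dominant_fraction", "penetrance_min",
                     "penetrance_max", "background_rate", "hom_lethality"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.penetrance_min > self.penetrance_max:
            raise ValueError("penetrance_min must not exceed penetrance_max")
        if self.n_alleles < 1 or self.n_g2_dams < 1:
            raise ValueError("n_alleles and n_g2_dams must be >= 1")
        if not (1 <= self.litter_size_min <= self.litter_size_max):
            raise ValueError("need 1 <= litter_size_min <= litter_size_max")
        self.models = tuple(self.models)
        for m in self.models:
            if m not in _MODEL_NAMES:
                raise ValueError(f"unknown inheritance model {m!r}")
        self.effect_weights = tuple(float(w) for w in self.effect_weights)

    def genetic_map(self) -> GeneticMap:
        if self.map_file is None:
            return default_mouse_map()
        return GeneticMap.from_tsv(self.map_file)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_weights"] = list(self.effect_weights)
        d["models"] = list(self.models)
        return d

    def digest(self) -> str:
        """Stable sha256 of the configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8-sig") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
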