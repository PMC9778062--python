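"""Pipeline configuration: one YAML-serializable object for a whole run.

``PipelineConfig`` nests the generator, preprocessing, network and
split parameters together with the master seed and output directory, and
round-trips losslessly through YAML so every run can log the exact
resolved configuration it used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bpann import NetworkConfig
from .calibration import SplitSpec
from .preprocess import PreprocessConfig
from .synthetic import (
    DEFAULT_CONCENTRATIONS,
    DEFAULT_N_PER_GROUP,
    ColorModel,
    DoseResponseParams,
    RenderParams,
)

__all__ = ["GeneratorConfig", "PipelineConfig"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-dataset recipe: design levels, replicates and models."""

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_per_group: int = DEFAULT_N_PER_GROUP
    dose: DoseResponseParams = field(default_factory=DoseResponseParams)
    colors: ColorModel = field(default_factory=ColorModel)
    render: RenderParams = field(default_factory=RenderParams)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    master_seed: int = 0
    output_dir: str = "amoxquant_out"

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        doc = yaml.safe_load(p.read_text()) if p.exists() else yaml.safe_load(str(source))
        return cls.from_dict(doc or {})

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        gen = dict(doc.get("generator", {}))
        for key, typ in (("dose", DoseResponseParams), ("colors", ColorModel),
                         ("render", RenderParams)):
            sub = gen.get(key)
            if isinstance(sub, dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
                gen[key] = typ(**sub)
        if "concentrations" in gen:
            gen["concentrations"] = tuple(gen["concentrations"])
        return cls(
            generator=GeneratorConfig(**gen),
            preprocess=PreprocessConfig(**doc.get("preprocess", {})),
            network=NetworkConfig(**doc.get("network", {})),
            split=SplitSpec(**doc.get("split", {})),
            master_seed=int(doc.get("master_seed", 0)),
            output_dir=str(doc.get("output_dir", "amoxquant_out")),
        )
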