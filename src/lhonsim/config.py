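"""Run configuration: one YAML document holding every model constant.

A :class:`RunConfig` round-trips losslessly through YAML and carries the
four sections a complete run needs: nerve geometry (scale, resolution,
clearance, per-quadrant mixture coefficients, seed), simulation constants
(all rate constants of the superoxide model), the injury specification,
and output settings (directory, snapshot cadence).  Every field has a
documented default, so an empty file is a valid configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .axon_population import MixtureParams, default_quadrant_params
from .diffusion_engine import SimulationParams
from .injury_zones import InjurySpec


@dataclass
class OutputConfig:
    directory: str = "results"
    snapshot_cadence: int = 0  # iterations between PNG frames; 0 = none
    save_axon_table: bool = True
    save_history: bool = True


@dataclass
class NerveConfig:
    scale: float = 0.1
    resolution: float = 10.0
    clearance: float = 0.05
    seed: int = 0
    blockwise_regions: bool = False
    quadrant_params: dict = field(default_factory=default_quadrant_params)


@dataclass
class RunConfig:
    nerve: NerveConfig = field(default_factory=NerveConfig)
    params: SimulationParams = field(default_factory=SimulationParams)
    injury: InjurySpec = field(default_factory=InjurySpec)
    output: OutputConfig = field(default_factory=OutputConfig)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "nerve": dataclasses.asdict(self.nerve),
            "params": dataclasses.asdict(self.params),
            "injury": dataclasses.asdict(self.injury),
            "output": dataclasses.asdict(self.output),
        }
        d["nerve"]["quadrant_params"] = {
            tag: {"components": [list(c) for c in mp.components]}
            for tag, mp in self.nerve.quadrant_params.items()
        }
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d or {})
        nerve_d = dict(d.get("nerve") or {})
        qp_d = nerve_d.pop("quadrant_params", None)
        nerve = NerveConfig(**nerve_d)
        if qp_d:
            nerve.quadrant_params = {
                tag: MixtureParams(
                    components=tuple(tuple(c) for c in spec["components"]),
                    region_tag=tag,
                )
                for tag, spec in qp_d.items()
            }
        params = SimulationParams(**(d.get("params") or {}))
        injury = InjurySpec(**(d.get("injury") or {}))
        output = OutputConfig(**(d.get("output") or {}))
        return RunConfig(nerve=nerve, params=params, injury=injury, output=output)

    @staticmethod
    def from_yaml(path_or_text: str | Path) -> "RunConfig":
        text = str(path_or_text)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        return RunConfig.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # --- execution helpers ---------------------------------------------
    def build_nerve(self, seed: int | None = None):
        from .nerve_geometry import build_nerve

        return build_nerve(
            scale=self.nerve.scale,
            resolution=self.nerve.resolution,
            clearance=self.nerve.clearance,
            quadrant_params=self.nerve.quadrant_params,
            rng_seed=self.nerve.seed if seed is None else seed,
            blockwise=self.nerve.blockwise_regions,
        )

    def manifest(self, seeds) -> dict:
        from . import __version__

        return {
            "config_hash": self.config_hash(),
            "seeds": list(map(int, seeds)),
            "version": __version__,
        }
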