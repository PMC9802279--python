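"""Run configuration: acquisition/analysis constants and stage parameters."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .spurious import DetectorParams
from .synthetic import Coupling, MotionArtifact, SimulationConfig, VolumeGeometry


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``volume_rate_hz`` is the acquisition rate, ``analysis_rate_hz`` the
    rate after downsampling; the former must be an integer multiple of the
    latter.
    """

    seed: int = 0
    n_males: int = 5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    geometry: VolumeGeometry = field(default_factory=VolumeGeometry)
    volume_rate_hz: float = 10.0
    analysis_rate_hz: float = 5.0
    roi_um: tuple[float, float, float] = (2.25, 2.25, 3.5)
    window_s: tuple[float, float] = (-7.0, 13.0)
    max_lag_samples: int = 5
    sg_window: int = 13
    sg_order: int = 1
    camera_offset: float = 0.0
    detector: DetectorParams = field(default_factory=DetectorParams)
    # (neuron, motif) pairs for lagged-correlation analysis
    correlation_pairs: tuple[tuple[str, str], ...] = (
        ("PCA", "backward_slide"),
        ("PCB", "vulva_contact"),
        ("PVV", "turn_success"),
    )
    render_demo_volumes: bool = True
    demo_duration_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("volume_rate_hz", "analysis_rate_hz", "sg_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.volume_rate_hz / self.analysis_rate_hz
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"analysis_rate_hz ({self.analysis_rate_hz}) must divide "
                f"volume_rate_hz ({self.volume_rate_hz})"
            )
        if self.n_males < 1:
            raise ValueError("n_males must be >= 1")

    @property
    def downsample_factor(self) -> int:
        return int(round(self.volume_rate_hz / self.analysis_rate_hz))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["neuron_couplings"] = {
            k: asdict(v) for k, v in self.simulation.neuron_couplings.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            sim = dict(d["simulation"])
            if "neuron_couplings" in sim:
                sim["neuron_couplings"] = {
                    k: Coupling(**v) for k, v in sim["neuron_couplings"].items()
                }
            if "motion_artifact" in sim and isinstance(sim["motion_artifact"], dict):
                sim["motion_artifact"] = MotionArtifact(**sim["motion_artifact"])
            if "spurious_neurons" in sim:
                sim["spurious_neurons"] = tuple(sim["spurious_neurons"])
            d["simulation"] = SimulationConfig(**sim)
        if "geometry" in d and isinstance(d["geometry"], dict):
            g = dict(d["geometry"])
            if "blob_sigma_um" in g:
                g["blob_sigma_um"] = tuple(g["blob_sigma_um"])
            d["geometry"] = VolumeGeometry(**g)
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = DetectorParams(**d["detector"])
        for key in ("roi_um", "window_s"):
            if key in d:
                d[key] = tuple(d[key])
        if "correlation_pairs" in d:
            d["correlation_pairs"] = tuple(
                (str(a), str(b)) for a, b in d["correlation_pairs"]
            )
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)
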