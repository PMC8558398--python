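"""YAML run configuration: cohort, feature, and integrator sections."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detector import IntegratorConfig
from .features import FeatureConfig
from .simulate import CohortSpec


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "cohort": asdict(self.cohort),
            "features": asdict(self.features),
            "integrator": asdict(self.integrator),
            "seed": self.seed,
        }
        d["integrator"]["threshold_grid"] = [
            float(x) for x in self.integrator.threshold_grid
        ]
        d["cohort"]["seizures_per_subject"] = {
            int(k): float(v) for k, v in self.cohort.seizures_per_subject.items()
        }
        for key in ("stay_hours", "seizure_duration_s"):
            d["cohort"][key] = list(d["cohort"][key])
        d["features"]["band_edges_hz"] = {
            k: list(v) for k, v in self.features.band_edges_hz.items()
        }
        return d


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v
            for k, v in d.items()}


def load_config(path: str | Path | None = None,
                seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; omitted sections take defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cohort_raw = _tupled(raw.get("cohort", {}),
                         ("stay_hours", "seizure_duration_s"))
    if "seizures_per_subject" in cohort_raw:
        cohort_raw["seizures_per_subject"] = {
            int(k): float(v)
            for k, v in cohort_raw["seizures_per_subject"].items()
        }
    feat_raw = dict(raw.get("features", {}))
    if "band_edges_hz" in feat_raw:
        feat_raw["band_edges_hz"] = {
            k: tuple(v) for k, v in feat_raw["band_edges_hz"].items()
        }
    integ_raw = dict(raw.get("integrator", {}))
    if "threshold_grid" in integ_raw:
        integ_raw["threshold_grid"] = np.asarray(integ_raw["threshold_grid"],
                                                 dtype=float)
    cfg = RunConfig(
        cohort=CohortSpec(**cohort_raw),
        features=FeatureConfig(**feat_raw),
        integrator=IntegratorConfig(**integ_raw),
        seed=int(raw.get("seed", 0)),
    )
    if seed is not None:
        cfg.seed = int(seed)
        cfg.cohort.seed = int(seed)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return Path(path)
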