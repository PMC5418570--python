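"""Run configuration: YAML round-trip, defaults and seed fan-out.

A :class:`RunConfig` bundles everything a full pipeline run needs — payoff
calibration conditions, the synthetic-experiment design, analysis settings
(phase cutoffs, WCLR coding variant, boundary filter, test unit) and the
master seed.  Every field has a default, so an empty config file is a valid
run.  The master seed fans out to named child streams (one per pipeline
stage) via :func:`child_seed`, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .game import ContestParams, PayoffAnchor, calibrate
from .synth import SyntheticConfig

__all__ = ["RunConfig", "child_seed", "child_seed_sequence"]


def child_seed_sequence(master_seed: int, stream: str) -> np.random.SeedSequence:
    """Named child stream of a master seed (stable across runs and platforms)."""
    digest = hashlib.sha256(stream.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.SeedSequence(entropy=[int(master_seed), key])


def child_seed(master_seed: int, stream: str) -> int:
    """A plain integer seed (< 2**31) derived from a named child stream."""
    return int(child_seed_sequence(master_seed, stream).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All knobs of a pipeline run, each defaulted."""

    anchors: list[list[float]] = field(
        default_factory=lambda: [[0.1, 3.45], [3.0, 2.0], [6.0, 0.5]]
    )
    nash_action: float | None = None
    points_per_euro: float = 2000.0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    phase_cutoffs: tuple[int, int] = (25, 300)
    wclr_mode: str = "const1"
    drop_boundary: bool = False
    test_unit: str = "pair"
    seed: int = 0

    def game_params(self) -> ContestParams:
        return calibrate(
            [PayoffAnchor(*a) for a in self.anchors],
            nash_action=self.nash_action,
            points_per_euro=self.points_per_euro,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_cutoffs"] = list(self.phase_cutoffs)
        s = d["synthetic"]
        for key in ("adherence_range", "inertia_range", "step_range", "tremble_range"):
            s[key] = list(s[key])
        for key in ("noinfo_naive_mixture", "noinfo_adapted_mixture", "info_mixture"):
            s[key] = dict(s[key])
        return d

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "synthetic" in data and data["synthetic"] is not None:
            syn = dict(data["synthetic"])
            unknown_syn = set(syn) - set(SyntheticConfig.__dataclass_fields__)
            if unknown_syn:
                raise ConfigError(f"unknown synthetic field(s): {sorted(unknown_syn)}")
            for key in ("adherence_range", "inertia_range", "step_range", "tremble_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            data["synthetic"] = SyntheticConfig(**syn)
        if "phase_cutoffs" in data:
            data["phase_cutoffs"] = tuple(data["phase_cutoffs"])
        if "anchors" in data:
            data["anchors"] = [list(map(float, a)) for a in data["anchors"]]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw or {})

    def digest(self) -> str:
        """Stable short hash of the full configuration (stamped on artifacts)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:12]
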