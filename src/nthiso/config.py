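"""Run configuration: every tunable of the pipeline in one validated record.

A :class:`RunConfig` collects the knobs of the TM scanner, the motif
scanner, the isoform classifier, the distance/grouping machinery and the
simulators.  Configs load from a YAML file (unknown keys are rejected so a
typo cannot silently fall back to a default) and command-line flags
override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class RunConfig:
    # -- TM scan (hydropathy units are the dimensionless Kyte-Doolittle scale)
    window: int = 19              # sliding-window width (residues), odd
    threshold: float = 1.6        # mean hydropathy cut-off for a TM residue
    min_helix_len: int = 15       # residues
    max_helix_len: int = 30       # residues
    min_loop_len: int = 4         # runs separated by less than this merge
    max_gap: int = 80             # residues; larger inter-helix gaps split stretches

    # -- domain scan
    motif_threshold_frac: float = 0.6   # acceptance threshold as fraction of max score
    max_hits_per_kind: int = 2

    # -- isoform classification
    helix_tolerance: int = 2      # allowed |observed - template| helices per stretch

    # -- pairwise distances / paralogue grouping
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    distance_mode: str = "poisson"      # "p_distance" | "poisson"
    max_distance: float = 10.0          # cap for the Poisson correction as p -> 1
    min_margin: float = 0.02            # expected substitutions/site; below -> UNASSIGNED

    # -- randomness
    seed: int = 1

    # -- topology comparison
    topologies: tuple[str, ...] = ("janouskovec", "mathur", "salomaki")

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 5, got {self.window}")
        for name in ("min_helix_len", "max_helix_len", "min_loop_len", "max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_helix_len > self.max_helix_len:
            raise ValueError("min_helix_len > max_helix_len")
        if not 0.0 < self.motif_threshold_frac <= 1.0:
            raise ValueError("motif_threshold_frac must be in (0, 1]")
        if self.helix_tolerance < 0:
            raise ValueError("helix_tolerance must be >= 0")
        if self.distance_mode not in ("p_distance", "poisson"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.min_margin < 0:
            raise ValueError("min_margin must be >= 0")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config from YAML; keyword overrides win over file values.

        Unknown keys in either source raise ``ValueError``.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        if "topologies" in data and data["topologies"] is not None:
            data = dict(data, topologies=tuple(data["topologies"]))
        return cls(**data)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["topologies"] = list(d["topologies"])
        return d


DEFAULT_CONFIG = RunConfig()
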