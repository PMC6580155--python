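"""Run configuration: YAML/JSON loading for the CLI.

A config file may carry any of the sections ``contest:``, ``cohort:``,
``analysis:`` and ``io:`` plus top-level ``seed`` and ``log_level``;
missing pieces fall back to the package defaults (the calibrated
three-condition design).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import (
    CohortConfig,
    ConditionParams,
    DemographicsParams,
    default_config,
)
from .contest import ContestSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    contest: ContestSpec = field(default_factory=ContestSpec)
    cohort: CohortConfig = field(default_factory=default_config)
    analysis: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    seed: int = 20190611
    log_level: str = "INFO"

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        return replace(self, seed=seed, cohort=replace(self.cohort, seed=seed))


def _build_cohort(section: dict, seed: int) -> CohortConfig:
    base = default_config(seed=seed)
    kwargs: dict = {}
    for key in ("participants_per_condition", "periods", "integer_bids", "seed"):
        if key in section:
            kwargs[key] = section[key]
    if "conditions" in section:
        kwargs["conditions"] = tuple(
            ConditionParams(**c) for c in section["conditions"]
        )
    if "demographics" in section:
        kwargs["demographics"] = tuple(
            (label, DemographicsParams(**d))
            for label, d in section["demographics"].items()
        )
    return replace(base, **kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML or JSON run configuration; ``seed`` overrides the file."""
    if path is None:
        cfg = RunConfig()
        return cfg.with_seed(seed)
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    top_seed = int(data.get("seed", 20190611))
    contest = ContestSpec(**data.get("contest", {}))
    cohort = _build_cohort(data.get("cohort", {}), seed=top_seed)
    cfg = RunConfig(
        contest=contest,
        cohort=cohort,
        analysis=dict(data.get("analysis", {})),
        io=dict(data.get("io", {})),
        seed=top_seed,
        log_level=str(data.get("log_level", "INFO")),
    )
    return cfg.with_seed(seed)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration, for run metadata."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
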