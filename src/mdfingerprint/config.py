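"""YAML run configuration: schema, defaults, validation.

A run config wires the comparative two-temperature workflow: for each
analysis stage it names a topology (PDB), a cold and a hot trajectory
(DCD/XTC) and, for the binding stage, a nonbonded parameter table.  Stages
without an explicit entry fall back to the ``default`` input block.
Validation collects *all* problems before reporting, so a broken config
fails with the complete list rather than the first error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "STAGES", "config_hash"]

STAGES = ("flex", "gbsa", "lipids", "dccm", "ctd")

_DEFAULT_THRESHOLDS = {
    "lipid_cutoff": 5.0,
    "scd_shell": 6.0,
    "dcc_pos_threshold": 0.5,
    "dcc_neg_threshold": -0.5,
    "hbond_max_da": 3.5,
    "hbond_min_angle": 150.0,
}

_DEFAULT_GBSA = {
    "eps_in": 1.0,
    "eps_out": 80.0,
    "salt_molar": 0.4,
    "gamma": 0.0072,
    "last_ns": 100.0,
    "interval_ns": 2.0,
}

_DEFAULT_SELECTIONS = {
    "receptor_segment": "protein",
    "ligand_segment": "ligand",
    "ctd_range": [660, 670],
    "trs_range": [660, 670],
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    stages: list[str]
    inputs: dict[str, dict[str, Path]]   # stage -> {topology, ...}
    selections: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    gbsa: dict = field(default_factory=dict)
    dcc_sign: str = "cold-hot"
    segment_rules: dict[str, str] = field(default_factory=dict)

    def stage_inputs(self, stage: str) -> dict[str, Path]:
        return self.inputs.get(stage) or self.inputs.get("default") or {}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "stages": list(self.stages),
            "inputs": {k: {kk: str(vv) for kk, vv in v.items()}
                       for k, v in self.inputs.items()},
            "selections": dict(self.selections),
            "thresholds": dict(self.thresholds),
            "gbsa": dict(self.gbsa),
            "dcc_sign": self.dcc_sign,
            "segment_rules": dict(self.segment_rules),
        }


def config_hash(cfg: RunConfig) -> str:
    """Reproducible hash of the canonical config serialization."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


_REQUIRED_STAGE_FILES = {
    "flex": ("topology", "trajectory_cold", "trajectory_hot"),
    "dccm": ("topology", "trajectory_cold", "trajectory_hot"),
    "lipids": ("topology", "trajectory_cold", "trajectory_hot"),
    "ctd": ("topology", "trajectory_cold", "trajectory_hot"),
    "gbsa": ("topology", "trajectory_cold", "trajectory_hot", "parameters"),
}


def validate_config(path: str | Path,
                    ) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML config; returns (config, errors).

    On any error the config is None and ``errors`` holds every problem
    found, each naming the offending field.
    """
    errors: list[str] = []
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"]

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0
    stages = raw.get("stages", list(STAGES))
    if not isinstance(stages, list) or not stages:
        errors.append("stages: must be a non-empty list")
        stages = list(STAGES)
    for s in stages:
        if s not in STAGES:
            errors.append(f"stages: unknown stage {s!r} "
                          f"(choose from {list(STAGES)})")
    out_dir = Path(raw.get("output_dir", "fingerprint_out"))

    inputs_raw = raw.get("inputs", {})
    if not isinstance(inputs_raw, dict):
        errors.append("inputs: must be a mapping of stage -> file paths")
        inputs_raw = {}
    inputs: dict[str, dict[str, Path]] = {}
    base = path.parent
    for stage, files in inputs_raw.items():
        if stage not in STAGES + ("default",):
            errors.append(f"inputs.{stage}: unknown stage")
            continue
        if not isinstance(files, dict):
            errors.append(f"inputs.{stage}: must be a mapping")
            continue
        resolved = {}
        for key, p in files.items():
            fp = Path(p)
            if not fp.is_absolute():
                fp = base / fp
            if not fp.exists():
                errors.append(f"inputs.{stage}.{key}: file not found: {fp}")
            resolved[key] = fp
        inputs[stage] = resolved
    for stage in stages:
        if stage not in STAGES:
            continue
        files = inputs.get(stage) or inputs.get("default") or {}
        for key in _REQUIRED_STAGE_FILES[stage]:
            if key not in files:
                errors.append(f"inputs: stage {stage!r} missing {key!r}")

    thresholds = {**_DEFAULT_THRESHOLDS, **(raw.get("thresholds") or {})}
    if thresholds["lipid_cutoff"] <= 0:
        errors.append("thresholds.lipid_cutoff: must be positive")
    if thresholds["scd_shell"] <= 0:
        errors.append("thresholds.scd_shell: must be positive")
    if not (thresholds["dcc_pos_threshold"] > 0
            > thresholds["dcc_neg_threshold"]):
        errors.append("thresholds.dcc_*_threshold: need pos > 0 > neg")
    if thresholds["hbond_max_da"] <= 0:
        errors.append("thresholds.hbond_max_da: must be positive")
    if not 0 < thresholds["hbond_min_angle"] <= 180:
        errors.append("thresholds.hbond_min_angle: must lie in (0, 180]")

    gbsa = {**_DEFAULT_GBSA, **(raw.get("gbsa") or {})}
    if gbsa["salt_molar"] < 0:
        errors.append("gbsa.salt_molar: must be non-negative")
    if gbsa["interval_ns"] <= 0 or gbsa["last_ns"] <= 0:
        errors.append("gbsa.last_ns / interval_ns: must be positive")

    selections = {**_DEFAULT_SELECTIONS, **(raw.get("selections") or {})}
    for key in ("ctd_range", "trs_range"):
        rng = selections[key]
        if (not isinstance(rng, (list, tuple)) or len(rng) != 2
                or rng[0] > rng[1]):
            errors.append(f"selections.{key}: must be [lo, hi] with "
                          "lo <= hi")

    dcc_sign = raw.get("dcc_sign", "cold-hot")
    if dcc_sign not in ("cold-hot", "hot-cold"):
        errors.append("dcc_sign: must be 'cold-hot' or 'hot-cold'")

    segment_rules = raw.get("segment_rules") or {}
    valid_tags = {"protein", "lipid", "solvent", "ion", "ligand"}
    for resname, tag in segment_rules.items():
        if tag not in valid_tags:
            errors.append(f"segment_rules.{resname}: unknown tag {tag!r} "
                          f"(choose from {sorted(valid_tags)})")

    if errors:
        return None, errors
    return RunConfig(seed=seed, output_dir=out_dir, stages=stages,
                     inputs=inputs, selections=selections,
                     thresholds=thresholds, gbsa=gbsa,
                     dcc_sign=dcc_sign, segment_rules=segment_rules), []
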