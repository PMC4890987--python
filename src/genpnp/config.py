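"""Typed run configuration with strict validation.

A run is driven either by a ``simulation`` block (synthetic study) or by an
``inputs`` block naming cohort file prefixes and a candidate edge table —
exactly one of the two.  Significance levels default to 0.05 throughout and
the projection energy to 0.85; core thresholds are given per cohort as
(th1, th2, th3) or replaced by a quantile rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Union

import yaml

_TOP_KEYS = {
    "simulation", "inputs", "alphas", "energy", "thresholds",
    "threshold_quantile", "seed", "output_dir",
}
_ALPHA_KEYS = {"pool", "prune", "methylation", "de"}
_INPUT_KEYS = {"cohorts", "edges"}


@dataclass
class Alphas:
    pool: float = 0.05
    prune: float = 0.05
    methylation: float = 0.05
    de: float = 0.05


@dataclass
class RunConfig:
    """Validated, defaulted configuration of one pipeline run."""

    simulation: Optional[dict[str, Any]] = None
    inputs: Optional[dict[str, Any]] = None
    alphas: Alphas = field(default_factory=Alphas)
    energy: float = 0.85
    #: per-group (th1, th2, th3); ignored when threshold_quantile is set
    thresholds: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    #: quantile of nonzero D per row class used when no explicit thresholds
    threshold_quantile: Optional[float] = 0.9
    seed: int = 0
    output_dir: str = "genpnp_run"

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of the 'simulation' and 'inputs' blocks is required"
            )
        for name in _ALPHA_KEYS:
            a = getattr(self.alphas, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha '{name}' must lie in (0, 1)")
        if not 0.0 < self.energy <= 1.0:
            raise ValueError("energy must lie in (0, 1]")
        if self.threshold_quantile is not None and not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                raise ValueError(f"unknown inputs key(s): {sorted(unknown)}")
            missing = _INPUT_KEYS - set(self.inputs)
            if missing:
                raise ValueError(f"missing inputs key(s): {sorted(missing)}")
        for group, ths in self.thresholds.items():
            if len(ths) != 3 or any(t < 0 for t in ths):
                raise ValueError(
                    f"thresholds for {group!r} must be three nonnegative values"
                )

    def as_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["thresholds"] = {g: list(t) for g, t in self.thresholds.items()}
        return out


def validate_config(raw: Union[str, Mapping[str, Any]]) -> RunConfig:
    """Parse and validate a YAML string (or pre-parsed mapping) into a RunConfig.

    Unknown keys are rejected by name; exactly one of the data and
    simulation blocks must be present.
    """
    if isinstance(raw, str):
        parsed = yaml.safe_load(raw)
    else:
        parsed = dict(raw)
    if not isinstance(parsed, Mapping):
        raise ValueError("configuration must be a mapping")
    unknown = set(parsed) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    alphas_raw = parsed.get("alphas", {}) or {}
    unknown = set(alphas_raw) - _ALPHA_KEYS
    if unknown:
        raise ValueError(f"unknown alphas key(s): {sorted(unknown)}")
    thresholds = {
        g: tuple(float(x) for x in ths)
        for g, ths in (parsed.get("thresholds", {}) or {}).items()
    }
    config = RunConfig(
        simulation=parsed.get("simulation"),
        inputs=parsed.get("inputs"),
        alphas=Alphas(**alphas_raw),
        energy=float(parsed.get("energy", 0.85)),
        thresholds=thresholds,
        threshold_quantile=(
            None
            if "thresholds" in parsed and "threshold_quantile" not in parsed
            else float(parsed.get("threshold_quantile", 0.9))
        ),
        seed=int(parsed.get("seed", 0)),
        output_dir=str(parsed.get("output_dir", "genpnp_run")),
    )
    config.validate()
    return config
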