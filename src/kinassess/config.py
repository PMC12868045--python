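"""Run configuration: defaults, YAML loading, validation, provenance echo.

Configuration keys are dotted (``filter.cutoff_hz``); a YAML file supplies
them nested::

    filter:
      cutoff_hz: 6
    segment:
      threshold_frac: 0.05

Unknown keys are rejected so that typos cannot silently fall back to
defaults. The effective configuration is echoed verbatim into every output
artifact for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ValidationError

DEFAULTS: dict[str, Any] = {
    "filter.cutoff_hz": 6.0,
    "filter.order": 3,
    "filter.zero_phase": True,
    "gaps.max_gap_s": 0.2,
    "segment.threshold_frac": 0.05,
    "segment.min_duration_s": 0.2,
    "segment.multi_rep": False,
    "kin.wf_formula": "printed",
    "kin.nj_endpoint": "wrist",
    "kin.displacement_mode": "rom",
    "kin.trunk_joints": "spine_base",
    "stats.alpha": 0.05,
    "stats.ttest": "student",
    "stats.power": 0.95,
    "stats.tails": 2,
}


class RunConfig(dict):
    """Flat, validated configuration mapping with dotted keys."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        super().__init__(DEFAULTS)
        if overrides:
            unknown = set(overrides) - set(DEFAULTS)
            if unknown:
                raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
            self.update(overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls(_flatten(raw))

    def filter_spec(self):
        from .preprocessing import FilterSpec

        return FilterSpec(
            cutoff=float(self["filter.cutoff_hz"]),
            order=int(self["filter.order"]),
            zero_phase=bool(self["filter.zero_phase"]),
        )


def _flatten(nested: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in nested.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, prefix=f"{dotted}."))
        else:
            flat[dotted] = value
    return flat
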