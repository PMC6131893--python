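"""Reading subject/dose/CO records from YAML or JSON config files."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .co_reference import CORebreathingRecord
from .dilution import DoseRecord, SubjectRecord
from .relaxometry import ContrastAgentSpec

__all__ = ["load_config", "subject_from_config", "dose_from_config",
           "co_record_from_config"]


def load_config(path) -> dict:
    """Load a YAML (or JSON) mapping from disk."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def _agent_from(d: dict | None) -> ContrastAgentSpec:
    return ContrastAgentSpec(**d) if d else ContrastAgentSpec()


def subject_from_config(config: dict) -> SubjectRecord:
    """Build a SubjectRecord from the ``subject:`` block of a config."""
    d = config.get("subject", config)
    return SubjectRecord(
        weight_kg=float(d["weight_kg"]),
        hematocrit=float(d["hematocrit"]),
        hemoglobin_g_per_l=(float(d["hemoglobin_g_per_l"])
                            if "hemoglobin_g_per_l" in d else None),
    )


def dose_from_config(config: dict) -> DoseRecord:
    """Build a DoseRecord from the ``dose:`` block of a config."""
    d = config.get("dose", config)
    return DoseRecord(
        injected_volume_ml=float(d["injected_volume_ml"]),
        agent=_agent_from(d.get("agent")),
    )


def co_record_from_config(config: dict) -> CORebreathingRecord:
    """Build a CORebreathingRecord from a config mapping."""
    d = dict(config.get("co_rebreathing", config))
    d["baseline_cohb_pct"] = tuple(d["baseline_cohb_pct"])
    d["post_cohb_pct"] = tuple(d["post_cohb_pct"])
    if d.get("post_times_min") is not None:
        d["post_times_min"] = tuple(d["post_times_min"])
    return CORebreathingRecord(**d)
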