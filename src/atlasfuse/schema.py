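"""Fusion-report JSON schema: loading and a minimal structural validator.

The validator covers the subset of JSON Schema the shipped schema uses
(required keys, primitive types, numeric bounds, array items/minItems).
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_report_schema", "validate_report"]


def load_report_schema() -> dict:
    text = resources.files("atlasfuse.schemas").joinpath("fusion_report.schema.json").read_text()
    return json.loads(text)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(value, schema: dict, path: str, errors: list[str]) -> None:
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        ok = isinstance(value, py) and not (expected in ("integer", "number") and isinstance(value, bool))
        if not ok:
            errors.append(f"{path}: expected {expected}, got {type(value).__name__}")
            return
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            errors.append(f"{path}: {value} < minimum {schema['minimum']}")
        if "maximum" in schema and value > schema["maximum"]:
            errors.append(f"{path}: {value} > maximum {schema['maximum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}", errors)
    if isinstance(value, list):
        if "minItems" in schema and len(value) < schema["minItems"]:
            errors.append(f"{path}: fewer than {schema['minItems']} items")
        item_schema = schema.get("items")
        if item_schema:
            for i, item in enumerate(value):
                _check(item, item_schema, f"{path}[{i}]", errors)


def validate_report(report: dict) -> None:
    """Raise ValueError listing every violation of the fusion-report schema."""
    errors: list[str] = []
    _check(report, load_report_schema(), "$", errors)
    if errors:
        raise ValueError("fusion report fails schema validation:\n" + "\n".join(errors))
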