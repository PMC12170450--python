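"""Minimal structural schema for pipeline report JSON.

A schema node is either a python type, a dict of field -> node (all fields
required unless the name ends in '?'), or a list with a single node that
every element must satisfy. ``None`` matches anything.
"""

from __future__ import annotations

__all__ = ["REPORT_SCHEMA", "validate", "SchemaError"]


class SchemaError(ValueError):
    pass


CLUSTER_SCHEMA = {
    "n_voxels": int,
    "volume_cm3": float,
    "center_of_mass_mm": [float],
    "peak_stat": float,
}

EFFECT_SCHEMA = {
    "measure": str,
    "point": float,
    "ci_low": float,
    "ci_high": float,
    "level": float,
}

REPORT_SCHEMA = {
    "provenance": {
        "package_version": str,
        "seed": int,
        "config_sha256": str,
        "versions": dict,
    },
    "n_subjects": int,
    "vlsm": {
        "n_included_voxels": int,
        "n_excluded_rank": int,
        "critical_t": float,
        "primary_threshold_t": float,
        "cluster_extent_critical": int,
        "n_permutations": int,
        "exhaustive": bool,
        "clusters": [CLUSTER_SCHEMA],
    },
    "mlsm": {
        "n_included_voxels": int,
        "n_permutations": int,
        "n_subjects_zero_row": int,
        "clusters": [CLUSTER_SCHEMA],
    },
    "roi": {
        "n_voxels": int,
        "volume_cm3": float,
        "dice_vlsm_mlsm": float,
    },
    "cohort": {
        "contingency": {"a": int, "b": int, "c": int, "d": int},
        "n_roi_resections": int,
        "n_deficit": int,
        "relative_risk?": EFFECT_SCHEMA,
        "odds_ratio?": EFFECT_SCHEMA,
        "effect_error?": str,
    },
}


def validate(obj, schema=REPORT_SCHEMA, path="$") -> None:
    """Raise :class:`SchemaError` where ``obj`` deviates from ``schema``."""
    if schema is None:
        return
    if isinstance(schema, dict):
        if not isinstance(obj, dict):
            raise SchemaError(f"{path}: expected object, got {type(obj).__name__}")
        for key, sub in schema.items():
            optional = key.endswith("?")
            name = key.rstrip("?")
            if name not in obj:
                if optional:
                    continue
                raise SchemaError(f"{path}: missing required field {name!r}")
            validate(obj[name], sub, f"{path}.{name}")
    elif isinstance(schema, list):
        if not isinstance(obj, list):
            raise SchemaError(f"{path}: expected array, got {type(obj).__name__}")
        for i, item in enumerate(obj):
            validate(item, schema[0], f"{path}[{i}]")
    elif schema is float:
        if not isinstance(obj, (int, float)) or isinstance(obj, bool):
            raise SchemaError(f"{path}: expected number, got {type(obj).__name__}")
    elif schema is int:
        if not isinstance(obj, int) or isinstance(obj, bool):
            raise SchemaError(f"{path}: expected integer, got {type(obj).__name__}")
    else:
        if not isinstance(obj, schema):
            raise SchemaError(
                f"{path}: expected {schema.__name__}, got {type(obj).__name__}"
            )
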