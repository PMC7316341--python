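"""Configuration files, run manifests and report writers.

The YAML schema mirrors :class:`~carueq.params.ModelParams` field-for-field:
top-level scalar fields under ``model:``, channel/exchanger groups under
``model.lcc_params`` / ``model.ryr_params`` / ``model.ncx_params``, the
pacing clamp under ``model.pacing``, and the dynamic-buffer table as a list
of mappings under ``model.buffers``.  Analysis settings (grids, replicate
counts, beat counts) live under ``analysis:``.  Unknown keys are rejected
with their full field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .pacing import APClamp
from .params import Buffer, LCCParams, ModelParams, NCXParams, RyRParams

__all__ = [
    "load_config",
    "dump_config",
    "write_manifest",
    "report_equilibrium",
    "DEFAULT_ANALYSIS",
]

DEFAULT_ANALYSIS = {
    "grid_ci": [50.0, 400.0, 9],     # nM: lo, hi, n
    "grid_csr": [10.0, 80.0, 9],     # μmol/Lcyt: lo, hi, n
    "replicates": 8,
    "n_beats": 100,
    "seed": None,                    # falls back to model seed
}

_GROUP_TYPES = {
    "lcc_params": LCCParams,
    "ryr_params": RyRParams,
    "ncx_params": NCXParams,
    "pacing": APClamp,
}


class ConfigError(ValueError):
    pass


def _build_group(cls, data, path):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ConfigError(f"{path}.{key}: unknown field")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path) -> tuple[ModelParams, dict]:
    """Load and validate a YAML config; returns (ModelParams, analysis dict).

    Raises :class:`ConfigError` naming the offending field path on schema
    violations (unknown keys, wrong types, constraint violations).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    for key in raw:
        if key not in ("model", "analysis"):
            raise ConfigError(f"{key}: unknown top-level section")
    model = dict(raw.get("model") or {})
    analysis = dict(DEFAULT_ANALYSIS)
    for key, val in (raw.get("analysis") or {}).items():
        if key not in DEFAULT_ANALYSIS:
            raise ConfigError(f"analysis.{key}: unknown field")
        analysis[key] = val

    kwargs = {}
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    for key, val in model.items():
        if key in _GROUP_TYPES:
            kwargs[key] = _build_group(_GROUP_TYPES[key], val, f"model.{key}")
        elif key == "buffers":
            if not isinstance(val, list):
                raise ConfigError("model.buffers: expected a list")
            kwargs["buffer_table"] = tuple(
                _build_group(Buffer, b, f"model.buffers[{i}]")
                for i, b in enumerate(val)
            )
        elif key in valid and key not in ("buffer_table", "provenance"):
            kwargs[key] = val
        else:
            raise ConfigError(f"model.{key}: unknown field")
    try:
        params = ModelParams(**kwargs)
    except (TypeError, ValueError) as exc:
        # surface the constraint with the offending field name when possible
        raise ConfigError(f"model: {exc}") from exc
    return params, analysis


def dump_config(params: ModelParams, analysis: dict | None = None) -> dict:
    """Serialize params (and optional analysis settings) to a plain dict that
    round-trips through :func:`load_config`."""
    model = {}
    for f in dataclasses.fields(ModelParams):
        if f.name == "provenance":
            continue
        val = getattr(params, f.name)
        if f.name == "buffer_table":
            model["buffers"] = [asdict(b) for b in val]
        elif f.name in _GROUP_TYPES:
            model[f.name] = asdict(val)
        else:
            model[f.name] = val
    out = {"model": model}
    if analysis is not None:
        out["analysis"] = dict(analysis)
    return out


def save_config(params: ModelParams, path, analysis: dict | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(params, analysis), fh, sort_keys=False)


# ---------------------------------------------------------------------- #
# manifests and reports


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, params: ModelParams, seed: int, command: str,
                   extra: dict | None = None) -> Path:
    """Write a JSON run manifest: config snapshot, package version, seed and
    an inventory (with checksums) of every file in the output directory.
    Re-running the same command with the same seed reproduces all stochastic
    outputs bit-identically."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    inventory = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "command": command,
        "version": __version__,
        "seed": int(seed),
        "config": dump_config(params),
        "outputs": inventory,
    }
    if extra:
        manifest.update(extra)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest_path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_equilibrium(report, out_dir) -> list[Path]:
    """Write an equilibrium report: JSON, nullcline CSVs, and a plain-text
    summary (crossing, slopes, validation gap).  An empty nullcline is
    written as an explicit 'not found on grid' marker, never an empty file.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    payload = {
        "crossing": {
            "c_i_nM": report.crossing[0],
            "c_sr_umol_per_Lcyt": report.crossing[1],
        },
        "slopes_dci_dcsr": report.slopes,
        "validation": report.validation,
    }
    jpath = out_dir / "equilibrium.json"
    with open(jpath, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
    written.append(jpath)

    for name, pts in (("f_nullcline", report.f_nullcline),
                      ("g_nullcline", report.g_nullcline)):
        cpath = out_dir / f"{name}.csv"
        if pts is None or len(pts) == 0:
            cpath.write_text(f"# {name}: not found on grid\n")
        else:
            pd.DataFrame(
                pts, columns=["c_i_nM", "c_sr_umol_per_Lcyt"]
            ).to_csv(cpath, index=False)
        written.append(cpath)

    lines = [
        "Predicted homeostatic steady state (nullcline crossing):",
        f"  diastolic c_i  = {report.crossing[0]:.1f} nM",
        f"  diastolic c_sr = {report.crossing[1]:.2f} umol/Lcyt",
        f"  f-nullcline slope dc_i/dc_sr = {report.slopes['f']:.4f}",
        f"  g-nullcline slope dc_i/dc_sr = {report.slopes['g']:.4f}",
    ]
    if report.validation:
        v = report.validation
        lines += [
            "Validation against the long paced run:",
            f"  evolved c_i  = {v['evolved'][0]:.1f} nM "
            f"(gap {100 * v['rel_gap_ci']:.1f}%)",
            f"  evolved c_sr = {v['evolved'][1]:.2f} umol/Lcyt "
            f"(gap {100 * v['rel_gap_csr']:.1f}%)",
        ]
    tpath = out_dir / "summary.txt"
    tpath.write_text("\n".join(lines) + "\n")
    written.append(tpath)
    return written
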