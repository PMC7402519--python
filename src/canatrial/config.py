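"""Flat key-value configuration I/O and run manifests.

Parameter sets, remodelling configs and protocol specs round-trip through a
flat YAML/JSON dialect whose keys are exactly the dataclass field names.
Every CLI run writes a JSON manifest listing the resolved configuration, the
package version and the SHA-256 of every output file, so any output is
reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from canatrial import __version__
from canatrial.cell_model import CellParameters
from canatrial.remodelling import RemodellingConfig

__all__ = ["load_mapping", "dump_mapping", "load_parameters",
           "save_parameters", "load_remodelling", "condition_parameters",
           "write_manifest", "sha256_file"]


def load_mapping(path) -> dict:
    """Read a flat mapping from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dump_mapping(data: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def load_parameters(path) -> CellParameters:
    return CellParameters.from_dict(load_mapping(path))


def save_parameters(params: CellParameters, path) -> None:
    dump_mapping(params.to_dict(), path)


def load_remodelling(path) -> RemodellingConfig:
    return RemodellingConfig.from_dict(load_mapping(path))


def condition_parameters(condition: str,
                         params_file=None,
                         remodelling_file=None,
                         disable=(), scales=()) -> CellParameters:
    """Resolve a named condition into a parameter set.

    ``condition`` is ``control``, ``hf`` or ``custom`` (requires
    ``remodelling_file``); ``disable`` removes single entries from the
    remodelling (knockout variants) and ``scales`` are ``name=factor``
    overrides.
    """
    from canatrial.remodelling import apply_remodelling, hf_default_config
    base = load_parameters(params_file) if params_file else CellParameters()
    if condition == "control" and not scales:
        return base
    if condition == "control":
        cfg = RemodellingConfig()
    elif condition == "hf":
        cfg = hf_default_config()
    elif condition == "custom":
        if remodelling_file is None:
            raise ValueError("custom condition requires a remodelling file")
        cfg = load_remodelling(remodelling_file)
    else:
        raise ValueError(f"unknown condition: {condition}")
    for name in disable:
        cfg = cfg.disable(name)
    for spec in scales:
        name, _, value = spec.partition("=")
        cfg = cfg.with_scale(name.strip(), float(value))
    return apply_remodelling(base, cfg)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, resolved_config: dict,
                   outputs) -> Path:
    """Write ``manifest.json`` describing a finished run."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "version": __version__,
        "config": resolved_config,
        "outputs": {str(Path(p).name): sha256_file(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
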