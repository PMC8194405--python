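"""Output writing: tidy CSVs, YAML, a hash manifest and a structured log."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = ["write_outputs", "attach_run_log", "float_repr"]


def float_repr(x) -> str:
    """CSV float formatter with exact repr round-trip semantics."""
    return repr(float(x))

logger = logging.getLogger("gutmuscle")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    results: Mapping[str, Any], directory: str | Path
) -> dict[str, str]:
    """Write named results into ``directory`` and a manifest of hashes.

    The file extension selects the format: ``.csv`` expects a DataFrame,
    ``.yaml`` a mapping/list, ``.json`` any JSON-serializable object, and
    ``.txt`` plain text.  Returns the manifest (file name -> sha256), which
    is also written as ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in results.items():
        path = directory / name
        if name.endswith(".csv"):
            if not isinstance(obj, pd.DataFrame):
                raise TypeError(f"{name}: expected a DataFrame")
            # repr-round-trip precision for every float column
            obj.to_csv(path, index=False, float_format=float_repr)
        elif name.endswith((".yaml", ".yml")):
            with open(path, "w") as fh:
                yaml.safe_dump(obj, fh, sort_keys=False)
        elif name.endswith(".json"):
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
        elif name.endswith(".txt"):
            path.write_text(str(obj))
        else:
            raise ValueError(f"unsupported output extension for {name!r}")
        manifest[name] = _sha256(path)
        logger.info("wrote %s (%s)", path, manifest[name][:12])
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def attach_run_log(directory: str | Path) -> logging.Handler:
    """Attach a timestamped, level-tagged file log under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(directory / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gutmuscle")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler
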