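"""Run manifests: hashing and provenance so every output is reproducible.

Each pipeline stage writes ``<stage>_manifest.json`` recording its config
section (and its hash), the seed, the SHA-256 of every input and output
file, and the package version.  A downstream stage verifies that the files
it reads still hash to what the upstream manifest recorded, and refuses to
run otherwise.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional, Union

from . import __version__
from .exceptions import ConfigurationError

__all__ = ["file_sha256", "config_hash", "write_manifest", "read_manifest", "verify_inputs"]

PathLike = Union[str, Path]


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(section: dict) -> str:
    return hashlib.sha256(json.dumps(section, sort_keys=True).encode()).hexdigest()


def write_manifest(
    out_dir: PathLike,
    stage: str,
    config_section: dict,
    seed: Optional[int],
    inputs: Iterable[PathLike] = (),
    outputs: Iterable[PathLike] = (),
    extra: Optional[dict] = None,
) -> Path:
    out_dir = Path(out_dir)
    doc = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": config_section,
        "config_hash": config_hash(config_section),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": {str(p): file_sha256(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        doc.update(extra)
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_manifest(out_dir: PathLike, stage: str) -> dict:
    path = Path(out_dir) / f"{stage}_manifest.json"
    if not path.exists():
        raise ConfigurationError(f"missing manifest for stage {stage!r}: {path}")
    return json.loads(path.read_text())


def verify_inputs(manifest: dict, paths: Iterable[PathLike]) -> None:
    """Check that each path's current hash matches the manifest's record."""
    recorded = manifest.get("outputs", {})
    for p in paths:
        p = str(p)
        if p not in recorded:
            raise ConfigurationError(
                f"{p} is not an output of the {manifest.get('stage')!r} stage manifest"
            )
        if file_sha256(p) != recorded[p]:
            raise ConfigurationError(
                f"{p} has changed since the {manifest.get('stage')!r} stage ran "
                "(manifest hash mismatch)"
            )
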